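"""SIMCA class modeling for spectral authentication.

Each class gets its own PCA model (mean spectrum + n_pc orthonormal
loadings from the SVD of the centered class matrix).  A sample's distance
to a class is the ratio of its residual variance to the class's pooled
residual variance,

    s_i^2 = ||e||^2 / (J - n_pc),        e = residual after projection,
    s_0^2 = ||E||^2 / ((n - n_pc - 1)(J - n_pc)),
    d     = sqrt(s_i^2 / s_0^2),

and membership is a one-sided F test: the sample belongs to the class when
d^2 is below the upper-alpha F quantile with (J - n_pc, n - n_pc - 1)
degrees of freedom.  Because membership is tested per class, a sample may
belong to none, one, or several classes.

Two calibration choices matter when channels far outnumber samples
(J >> n).  First, s_0^2 is estimated by leave-one-out: each training
sample's residual variance is computed under a class model refit without
it (the cross-validation analogue of SECV vs SEC).  Plain training
residuals underestimate a new sample's residual because the fitted PCs
absorb training noise, which makes the nominal limit reject far more than
alpha of genuine class members.  Second, the denominator degrees of
freedom count independent samples (n - n_pc - 1), not sample x channel
products: spectral residuals are strongly correlated across wavenumbers,
so (n - n_pc - 1)(J - n_pc) wildly overstates the precision of s_0^2 and
collapses the acceptance region.  Together these give the conservative
acceptance behavior SIMCA is used for in authentication practice.

Diagnostics follow chemometric practice: the interclass distance (ICD)
aggregates cross-fitted residuals (ICD > 3 reads as "well separated"),
the discriminating power locates the wavenumbers driving the separation,
and the modeling power measures how much of each wavenumber's variance a
class model captures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import RegionSet
from .errors import (
    ConfigError,
    DegenerateClassError,
    GridError,
    LabelError,
    RankError,
)

logger = logging.getLogger(__name__)

_S0_FLOOR = 1e-12
_DP_FLOOR = 1e-12


@dataclass
class SIMCAClassModel:
    """One class's PCA subspace plus its residual-variance statistics."""

    class_label: str
    mean_spectrum: np.ndarray
    pc_loadings: np.ndarray        # n_pc x J, orthonormal rows
    n_pc: int
    explained_variance: np.ndarray  # proportion of total class variance per PC
    s0_sq: float
    alpha: float
    f_crit: float
    n_train: int
    wavenumbers: np.ndarray | None = None
    region: RegionSet | None = None

    @property
    def n_wavenumbers(self) -> int:
        return self.mean_spectrum.size

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "mean_spectrum": self.mean_spectrum.tolist(),
            "pc_loadings": self.pc_loadings.tolist(),
            "n_pc": self.n_pc,
            "explained_variance": self.explained_variance.tolist(),
            "s0_sq": self.s0_sq,
            "alpha": self.alpha,
            "f_crit": self.f_crit,
            "n_train": self.n_train,
            "wavenumbers": None
            if self.wavenumbers is None
            else self.wavenumbers.tolist(),
            "region": None if self.region is None else str(self.region),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SIMCAClassModel":
        return cls(
            class_label=d["class_label"],
            mean_spectrum=np.array(d["mean_spectrum"], float),
            pc_loadings=np.array(d["pc_loadings"], float),
            n_pc=int(d["n_pc"]),
            explained_variance=np.array(d["explained_variance"], float),
            s0_sq=float(d["s0_sq"]),
            alpha=float(d["alpha"]),
            f_crit=float(d["f_crit"]),
            n_train=int(d["n_train"]),
            wavenumbers=None
            if d.get("wavenumbers") is None
            else np.array(d["wavenumbers"], float),
            region=None if d.get("region") is None else RegionSet.parse(d["region"]),
        )


@dataclass
class SIMCAModel:
    """A set of class models on a shared grid, with pairwise diagnostics."""

    class_models: list[SIMCAClassModel]
    icd_matrix: pd.DataFrame
    discriminating_power: pd.DataFrame  # index wavenumber, one column per pair

    @property
    def labels(self) -> list[str]:
        return [m.class_label for m in self.class_models]

    def model(self, label: str) -> SIMCAClassModel:
        for m in self.class_models:
            if m.class_label == label:
                return m
        raise LabelError(f"no class model for {label!r}")

    def to_dict(self) -> dict:
        return {
            "class_models": [m.to_dict() for m in self.class_models],
            "icd_matrix": self.icd_matrix.to_dict(),
            "discriminating_power": {
                "wavenumbers": self.discriminating_power.index.tolist(),
                "columns": list(self.discriminating_power.columns),
                "values": self.discriminating_power.to_numpy().tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SIMCAModel":
        dp = d["discriminating_power"]
        return cls(
            class_models=[SIMCAClassModel.from_dict(m) for m in d["class_models"]],
            icd_matrix=pd.DataFrame(d["icd_matrix"]),
            discriminating_power=pd.DataFrame(
                np.array(dp["values"], float),
                index=pd.Index(dp["wavenumbers"], name="wavenumber"),
                columns=dp["columns"],
            ),
        )


@dataclass
class ClassificationResult:
    """Per-sample class distances and (soft) assignments."""

    distances: pd.DataFrame          # samples x classes
    assigned: list[set[str]]

    @property
    def nearest(self) -> list[str]:
        return list(self.distances.idxmin(axis=1))


@dataclass
class PerformanceStats:
    """Binary confusion-matrix summary (ratios None when undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn


# ---------------------------------------------------------------------------
# Fitting and distances
# ---------------------------------------------------------------------------

def fit_class_model(
    X_class: np.ndarray,
    n_pc: int,
    alpha: float = 0.05,
    class_label: str = "",
    wavenumbers: np.ndarray | None = None,
    region: RegionSet | None = None,
) -> SIMCAClassModel:
    """Fit one class's PCA model by SVD of the mean-centered class matrix.

    The pooled residual variance s_0^2 is a leave-one-out estimate (mean
    residual variance of each training sample under a model fit without
    it), and the critical F value uses (J - n_pc, n - n_pc - 1) degrees
    of freedom; see the module docstring for why.
    """
    X = np.asarray(X_class, dtype=float)
    n, J = X.shape
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if n_pc < 0:
        raise RankError("n_pc must be >= 0")
    if n_pc >= min(n - 1, J):
        raise RankError(
            f"n_pc={n_pc} too large for {n} training samples x {J} wavenumbers"
        )
    if n <= n_pc + 2:
        raise RankError(f"need n_train > n_pc + 2, got n={n}, n_pc={n_pc}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    loadings = Vt[:n_pc] if n_pc else np.zeros((0, J))
    explained = (s[:n_pc] ** 2 / total_var) if total_var > 0 else np.zeros(n_pc)
    s0_sq = max(_loo_residual_variance(X, n_pc), _S0_FLOOR)
    f_crit = float(stats.f.ppf(1.0 - alpha, J - n_pc, n - n_pc - 1))
    return SIMCAClassModel(
        class_label=class_label,
        mean_spectrum=mean,
        pc_loadings=loadings,
        n_pc=n_pc,
        explained_variance=np.asarray(explained, float),
        s0_sq=s0_sq,
        alpha=alpha,
        f_crit=f_crit,
        n_train=n,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        region=region,
    )


def _loo_residual_variance(X: np.ndarray, n_pc: int) -> float:
    """Leave-one-out pooled residual variance: for each sample, refit the
    class PCA without it and average the held-out residual variance
    (per J - n_pc channel dof)."""
    n, J = X.shape
    idx = np.arange(n)
    s_sq = np.empty(n)
    for i in range(n):
        Xi = X[idx != i]
        mean = Xi.mean(axis=0)
        if n_pc:
            _, _, Vt = np.linalg.svd(Xi - mean, full_matrices=False)
            P = Vt[:n_pc]
            e = (X[i] - mean) - P.T @ (P @ (X[i] - mean))
        else:
            e = X[i] - mean
        s_sq[i] = float(e @ e) / (J - n_pc)
    return float(s_sq.mean())


def _residuals(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_wavenumbers:
        raise GridError(
            f"spectra have {X.shape[1]} points but the class model grid has "
            f"{model.n_wavenumbers}"
        )
    Xc = X - model.mean_spectrum
    P = model.pc_loadings
    return Xc - (Xc @ P.T) @ P if model.n_pc else Xc


def sample_distance(model: SIMCAClassModel, x: np.ndarray) -> float:
    """Normalized residual distance d = sqrt(s_i^2 / s_0^2) of one sample."""
    e = _residuals(model, np.asarray(x, float).reshape(1, -1))[0]
    s_i_sq = float(e @ e) / (model.n_wavenumbers - model.n_pc)
    return float(np.sqrt(s_i_sq / model.s0_sq))


def _distances(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    E = _residuals(model, X)
    s_i_sq = np.sum(E**2, axis=1) / (model.n_wavenumbers - model.n_pc)
    return np.sqrt(s_i_sq / model.s0_sq)


def classify(
    model: SIMCAModel,
    X: np.ndarray,
    sample_ids=None,
) -> ClassificationResult:
    """Soft classification: a sample joins every class whose F test it passes.

    Membership: distance^2 <= f_crit of that class (the upper-alpha F
    quantile), so the result per sample is a set — empty, singleton, or
    multiple.
    """
    if not model.class_models:
        raise ConfigError("SIMCA model has no classes")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = {}
    for m in model.class_models:
        cols[m.class_label] = _distances(m, X)
    dist = pd.DataFrame(
        cols,
        index=pd.Index(
            sample_ids if sample_ids is not None else np.arange(X.shape[0]),
            name="sample_id",
        ),
    )
    assigned = [
        {
            m.class_label
            for m in model.class_models
            if dist.iloc[i][m.class_label] ** 2 <= m.f_crit
        }
        for i in range(X.shape[0])
    ]
    return ClassificationResult(distances=dist, assigned=assigned)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _mean_sq_residual(model: SIMCAClassModel, X: np.ndarray) -> float:
    E = _residuals(model, X)
    return float(np.mean(np.sum(E**2, axis=1) / (model.n_wavenumbers - model.n_pc)))


def interclass_distance(
    model_p: SIMCAClassModel,
    model_q: SIMCAClassModel,
    X_p: np.ndarray,
    X_q: np.ndarray,
) -> float:
    """Residual-based interclass distance; 0 for identical classes, > 3
    conventionally reads as substantially different."""
    s_pq = _mean_sq_residual(model_q, X_p)
    s_qp = _mean_sq_residual(model_p, X_q)
    s_pp = _mean_sq_residual(model_p, X_p)
    s_qq = _mean_sq_residual(model_q, X_q)
    denom = s_pp + s_qq
    scale = float(
        np.mean((np.asarray(X_p) - model_p.mean_spectrum) ** 2)
        + np.mean((np.asarray(X_q) - model_q.mean_spectrum) ** 2)
    )
    if denom <= 1e-12 * max(scale, 1e-30):
        raise DegenerateClassError(
            "both classes have zero self-residual; ICD undefined"
        )
    return float(np.sqrt((s_pq + s_qp) / denom) - 1.0)


def discriminating_power(
    model_p: SIMCAClassModel,
    model_q: SIMCAClassModel,
    X_p: np.ndarray,
    X_q: np.ndarray,
) -> np.ndarray:
    """Per-wavenumber ratio of cross-class to within-class residuals.

    DP ~ 1 everywhere for indistinguishable classes; peaks mark the bands
    that drive the separation.  Zero within-class denominators are floored
    at 1e-12 and logged.
    """
    e_pq = np.mean(_residuals(model_q, X_p) ** 2, axis=0)
    e_qp = np.mean(_residuals(model_p, X_q) ** 2, axis=0)
    e_pp = np.mean(_residuals(model_p, X_p) ** 2, axis=0)
    e_qq = np.mean(_residuals(model_q, X_q) ** 2, axis=0)
    denom = e_pp + e_qq
    floored = denom < _DP_FLOOR
    if floored.any():
        logger.warning(
            "discriminating power: %d wavenumbers with ~zero within-class "
            "residual floored at %g",
            int(floored.sum()),
            _DP_FLOOR,
        )
    return np.sqrt((e_pq + e_qp) / np.maximum(denom, _DP_FLOOR))


def modeling_power(model: SIMCAClassModel, X_class: np.ndarray) -> np.ndarray:
    """Per-wavenumber share of class variance captured: 1 - s_resid/s_total.

    Clipped to [0, 1]; zero-variance wavenumbers report NaN
    (not-applicable).
    """
    X = np.atleast_2d(np.asarray(X_class, dtype=float))
    n = X.shape[0]
    E = _residuals(model, X)
    resid_var = np.sum(E**2, axis=0) / max(n - model.n_pc - 1, 1)
    total_var = np.sum((X - X.mean(axis=0)) ** 2, axis=0) / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mp = 1.0 - np.sqrt(resid_var) / np.sqrt(total_var)
    mp = np.where(total_var > 0, mp, np.nan)
    return np.clip(mp, 0.0, 1.0)


def select_n_pc(
    X_class: np.ndarray, max_pc: int = 10, tolerance: float = 0.05
) -> int:
    """Choose n_pc by the leave-one-out PRESS plateau.

    Held-out residuals shrink monotonically with every extra component
    (projection always removes variance; a noise direction still removes
    roughly a 1/(J-k) share), so the raw minimum is uninformative.  The
    smallest count is returned beyond which the relative PRESS improvement
    falls under max(tolerance, twice the noise-direction share).
    """
    X = np.asarray(X_class, dtype=float)
    n, J = X.shape
    kmax = min(max_pc, n - 3, J - 1)
    if kmax < 1:
        raise RankError(f"too few samples ({n}) to cross-validate n_pc")
    press = np.zeros(kmax + 1)
    for i in range(n):
        keep = np.arange(n) != i
        Xi = X[keep]
        mean = Xi.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xi - mean, full_matrices=False)
        xc = X[i] - mean
        press[0] += float(xc @ xc)
        scores_sq = (Vt[:kmax] @ xc) ** 2
        press[1:] += float(xc @ xc) - np.cumsum(scores_sq)
    for k in range(1, kmax):
        cut = max(tolerance, 2.0 / (J - k))
        if press[k + 1] > (1.0 - cut) * press[k]:
            return k
    return kmax


# ---------------------------------------------------------------------------
# Multi-class fitting and evaluation
# ---------------------------------------------------------------------------

def fit_simca(
    X: np.ndarray,
    labels,
    n_pc: int | dict[str, int] = 4,
    alpha: float = 0.05,
    wavenumbers: np.ndarray | None = None,
    region: RegionSet | None = None,
) -> SIMCAModel:
    """Fit one class model per label and the pairwise diagnostics."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    if len(classes) < 1:
        raise ConfigError("need at least one class")
    models = []
    class_X = {}
    for cls in classes:
        Xc = X[labels == cls]
        k = n_pc[cls] if isinstance(n_pc, dict) else n_pc
        models.append(
            fit_class_model(
                Xc, k, alpha=alpha, class_label=str(cls),
                wavenumbers=wavenumbers, region=region,
            )
        )
        class_X[str(cls)] = Xc

    names = [m.class_label for m in models]
    icd = pd.DataFrame(0.0, index=names, columns=names)
    dp_cols = {}
    for i, mi in enumerate(models):
        for j, mj in enumerate(models):
            if j <= i:
                continue
            d = interclass_distance(
                mi, mj, class_X[mi.class_label], class_X[mj.class_label]
            )
            icd.loc[mi.class_label, mj.class_label] = d
            icd.loc[mj.class_label, mi.class_label] = d
            dp_cols[f"{mi.class_label}|{mj.class_label}"] = discriminating_power(
                mi, mj, class_X[mi.class_label], class_X[mj.class_label]
            )
    dp = pd.DataFrame(
        dp_cols,
        index=pd.Index(
            wavenumbers if wavenumbers is not None else np.arange(X.shape[1]),
            name="wavenumber",
        ),
    )
    return SIMCAModel(class_models=models, icd_matrix=icd, discriminating_power=dp)


def performance(
    predicted: ClassificationResult, truth, positive_class: str
) -> PerformanceStats:
    """Confusion statistics with exclusive single assignment as TP.

    A positive sample counts TP only when assigned exactly
    ``{positive_class}``; multi/none assignments of positives are FN.  A
    negative sample is TN whenever the positive class is absent from its
    assignment, FP otherwise.
    """
    truth = list(truth)
    if len(truth) != len(predicted.assigned):
        raise LabelError("truth labels and predictions differ in length")
    known = set(predicted.distances.columns)
    tp = fp = tn = fn = 0
    for t, assigned in zip(truth, predicted.assigned):
        if str(t) not in known:
            raise LabelError(f"unknown truth label {t!r}")
        if str(t) == positive_class:
            if assigned == {positive_class}:
                tp += 1
            else:
                fn += 1
        else:
            if positive_class in assigned:
                fp += 1
            else:
                tn += 1
    return PerformanceStats(tp=tp, fp=fp, tn=tn, fn=fn)


def cross_validated_misclassifications(
    X: np.ndarray,
    labels,
    n_pc: int | dict[str, int] = 4,
    alpha: float = 0.05,
) -> int:
    """Leave-one-out class-projection misclassification count.

    Each training sample is held out, its own class model refit without
    it, and the sample is misclassified when its nearest class (by
    normalized residual distance) is not its true class.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray([str(label) for label in labels])
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise ConfigError("cross-validated misclassification needs >= 2 classes")
    base_models = {}
    for cls in classes:
        k = n_pc[cls] if isinstance(n_pc, dict) else n_pc
        base_models[cls] = fit_class_model(
            X[labels == cls], k, alpha=alpha, class_label=cls
        )
    mis = 0
    for i in range(X.shape[0]):
        own = labels[i]
        keep = (np.arange(X.shape[0]) != i) & (labels == own)
        k = n_pc[own] if isinstance(n_pc, dict) else n_pc
        loo_model = fit_class_model(X[keep], k, alpha=alpha, class_label=own)
        dists = {}
        for cls in classes:
            m = loo_model if cls == own else base_models[cls]
            dists[cls] = sample_distance(m, X[i])
        if min(dists, key=dists.get) != own:
            mis += 1
    return mis
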