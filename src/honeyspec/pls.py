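"""PLS1 regression for spectral trait calibration.

Implements NIPALS partial least squares with a single response: spectra
and response are mean-centered, then for each latent variable (LV) the
weight w ~ X'y (unit norm) extracts the score t = Xw, loadings
p = X't/(t't) and q = y't/(t't), and X and y are deflated.  The regression
vector b = W (P'W)^-1 q reproduces the fitted values on the calibration
data, so prediction is simply yhat = (X - x_mean) b + y_mean.

Model quality is assessed by leave-one-out cross-validation (SECV, R2cv),
external validation (SEP, R2pre, bias), and the two unitless
application-fitness ratios used in NIR/mid-IR practice:

* RPD = SD(reference, calibration) / SEP, banded into rough screening
  (2.0-2.4), screening (2.5-2.9), quality control (3.0-3.4), process
  control (3.5-4.0) and all applications (> 4.1);
* RER = range(reference, calibration) / SEP, banded at 4 (screening),
  10 (quality control) and 15 (quantification).

SECV uses divisor n; SEP is bias-corrected with divisor n-1 (common NIRS
practice).  R2 values are squared Pearson correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import RegionSet, SpectralDataset
from .errors import (
    DegenerateTargetError,
    DomainError,
    GridError,
    InsufficientValidationError,
    RankError,
    SplitError,
)

_RANK_TOL = 1e-12


@dataclass
class CalibrationStats:
    """Summary of the calibration set behind a fitted model."""

    n_cal: int
    sd_cal: float        # SD of reference values (ddof=1), trait units
    range_cal: float     # max - min of reference values, trait units
    sec: float           # standard error of calibration (divisor n-nlv-1)
    secv: float | None = None
    r2_cv: float | None = None


@dataclass
class PLSRModel:
    """A fitted PLS1 model on a fixed wavenumber grid."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x n_lv, unit-norm columns
    x_loadings: np.ndarray    # p x n_lv
    y_loadings: np.ndarray    # n_lv
    regression_vector: np.ndarray
    n_lv: int
    calibration: CalibrationStats
    wavenumbers: np.ndarray | None = None
    region: RegionSet | None = None
    trait_name: str = ""

    def to_dict(self) -> dict:
        return {
            "trait_name": self.trait_name,
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "wavenumbers": None
            if self.wavenumbers is None
            else self.wavenumbers.tolist(),
            "region": None if self.region is None else str(self.region),
            "calibration": {
                "n_cal": self.calibration.n_cal,
                "sd_cal": self.calibration.sd_cal,
                "range_cal": self.calibration.range_cal,
                "sec": self.calibration.sec,
                "secv": self.calibration.secv,
                "r2_cv": self.calibration.r2_cv,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        cal = d["calibration"]
        return cls(
            x_mean=np.array(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"], dtype=float),
            x_loadings=np.array(d["x_loadings"], dtype=float),
            y_loadings=np.array(d["y_loadings"], dtype=float),
            regression_vector=np.array(d["regression_vector"], dtype=float),
            n_lv=int(d["n_lv"]),
            calibration=CalibrationStats(
                n_cal=int(cal["n_cal"]),
                sd_cal=float(cal["sd_cal"]),
                range_cal=float(cal["range_cal"]),
                sec=float(cal["sec"]),
                secv=cal["secv"],
                r2_cv=cal["r2_cv"],
            ),
            wavenumbers=None
            if d.get("wavenumbers") is None
            else np.array(d["wavenumbers"], dtype=float),
            region=None
            if d.get("region") is None
            else RegionSet.parse(d["region"]),
            trait_name=d.get("trait_name", ""),
        )


@dataclass
class CrossValidationResult:
    """Leave-one-out statistics for LV counts 1..max_lv."""

    lv: np.ndarray
    secv: np.ndarray
    r2_cv: np.ndarray
    press: np.ndarray


@dataclass
class ValidationReport:
    """External-validation row: the statistics reported per trait model."""

    n_val: int
    bias: float
    sep: float
    r2_pre: float
    rpd: float
    rer: float
    rpd_band: str
    rer_band: str
    range_basis: str = "calibration"  # which reference range RER used


# ---------------------------------------------------------------------------
# Core NIPALS
# ---------------------------------------------------------------------------

def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; returns (W, P, q, x_scale)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    scale = max(float(np.sum(Xc * Xc)), _RANK_TOL)
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw**2 <= _RANK_TOL * scale:
            raise RankError(
                f"requested {n_lv} latent variables but X/y are exhausted "
                f"after {a}"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * scale:
            raise RankError(
                f"requested {n_lv} latent variables but rank is {a}"
            )
        pvec = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pvec)
        y = y - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
    return W, P, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # P'W is upper triangular with unit-ish diagonal; small system
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    wavenumbers: np.ndarray | None = None,
    region: RegionSet | None = None,
    trait_name: str = "",
) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    Raises ``DegenerateTargetError`` when the response has (numerically)
    zero variance and ``RankError`` when more LVs are requested than the
    data support.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise GridError(f"X has {n} rows but y has {y.size} values")
    if n_lv < 1:
        raise RankError("n_lv must be >= 1")
    if n_lv >= n:
        raise RankError(f"n_lv={n_lv} requires more than {n} samples")
    if float(np.var(y)) <= _RANK_TOL:
        raise DegenerateTargetError(
            "response variance is below 1e-12; nothing to regress on"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_lv)
    b = _regression_vector(W, P, q)

    resid = y - (y_mean + (X - x_mean) @ b)
    dof = max(n - n_lv - 1, 1)
    cal = CalibrationStats(
        n_cal=n,
        sd_cal=float(np.std(y, ddof=1)),
        range_cal=float(y.max() - y.min()),
        sec=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
        n_lv=n_lv,
        calibration=cal,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        region=region,
        trait_name=trait_name,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict trait values: yhat = (X - x_mean) b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise GridError(
            f"spectra have {X.shape[1]} points but the model grid has "
            f"{model.x_mean.size}"
        )
    return (X - model.x_mean) @ model.regression_vector + model.y_mean


def scores(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Latent-variable scores T = (X - x_mean) W (P'W)^-1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = model.weights @ np.linalg.inv(
        model.x_loadings.T @ model.weights
    )
    return (X - model.x_mean) @ R


# ---------------------------------------------------------------------------
# Cross-validation and LV selection
# ---------------------------------------------------------------------------

def loocv(X: np.ndarray, y: np.ndarray, max_lv: int) -> CrossValidationResult:
    """Leave-one-out cross-validation for LV counts 1..max_lv.

    For each held-out sample the model is refit from scratch on the
    remaining n-1; SECV(a) = sqrt(mean squared CV residual) and R2cv(a)
    is the squared Pearson correlation of CV predictions with y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_lv >= n - 1:
        raise RankError(f"max_lv={max_lv} must be below n-1={n - 1}")
    yhat = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, yi = X[keep], y[keep]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        W, P, q = _nipals(Xi - x_mean, yi - y_mean, max_lv)
        xc = X[i] - x_mean
        PtW = P.T @ W
        for a in range(1, max_lv + 1):
            b = W[:, :a] @ np.linalg.solve(PtW[:a, :a], q[:a])
            yhat[i, a - 1] = y_mean + xc @ b
    resid = yhat - y[:, None]
    press = np.sum(resid**2, axis=0)
    secv = np.sqrt(press / n)
    r2 = np.array(
        [float(np.corrcoef(yhat[:, a], y)[0, 1]) ** 2 for a in range(max_lv)]
    )
    return CrossValidationResult(
        lv=np.arange(1, max_lv + 1), secv=secv, r2_cv=r2, press=press
    )


def select_lv(cv: CrossValidationResult, tolerance: float = 0.02) -> int:
    """Parsimonious LV choice: smallest count whose SECV is within
    (1 + tolerance) of the global minimum."""
    if cv.secv.size == 0:
        raise RankError("empty cross-validation result")
    threshold = (1.0 + tolerance) * float(cv.secv.min())
    for a, s in zip(cv.lv, cv.secv):
        if s <= threshold:
            return int(a)
    return int(cv.lv[-1])  # pragma: no cover - loop always returns


# ---------------------------------------------------------------------------
# Outlier diagnostics
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Per-sample leverage/residual diagnostics on the calibration set."""

    table: pd.DataFrame  # columns: leverage, studentized_residual, flagged, reason

    @property
    def flagged(self) -> list:
        return list(self.table.index[self.table["flagged"]])


def detect_outliers(
    model: PLSRModel,
    X: np.ndarray,
    y: np.ndarray,
    leverage_mult: float = 3.0,
    resid_cut: float = 3.0,
    sample_ids: Sequence | None = None,
) -> OutlierReport:
    """Flag high-leverage and high-residual calibration samples.

    Leverage h_i = 1/n + sum_a t_ia^2/(t't)_a from the score space; a
    sample is flagged when h_i > leverage_mult*(n_lv+1)/n or its
    studentized residual exceeds ``resid_cut`` in magnitude.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    T = scores(model, X)
    ss = np.sum(T**2, axis=0)
    ss = np.where(ss > 0, ss, np.inf)
    h = 1.0 / n + np.sum(T**2 / ss, axis=1)
    resid = y - predict(model, X)
    sec = model.calibration.sec
    denom = sec * np.sqrt(np.clip(1.0 - h, 1e-12, None))
    stud = resid / np.where(denom > 0, denom, np.inf)

    h_cut = leverage_mult * (model.n_lv + 1) / n
    lev_flag = h > h_cut
    res_flag = np.abs(stud) > resid_cut
    reasons = [
        "; ".join(
            r
            for r, on in (
                (f"leverage {hi:.3f} > {h_cut:.3f}", lf),
                (f"|studentized residual| {abs(si):.2f} > {resid_cut:g}", rf),
            )
            if on
        )
        for hi, si, lf, rf in zip(h, stud, lev_flag, res_flag)
    ]
    table = pd.DataFrame(
        {
            "leverage": h,
            "studentized_residual": stud,
            "flagged": lev_flag | res_flag,
            "reason": reasons,
        },
        index=pd.Index(
            sample_ids if sample_ids is not None else np.arange(n),
            name="sample_id",
        ),
    )
    return OutlierReport(table=table)


# ---------------------------------------------------------------------------
# External validation and application bands
# ---------------------------------------------------------------------------

RPD_BANDS = (
    (2.0, "not_usable"),
    (2.5, "rough_screening"),
    (3.0, "screening"),
    (3.5, "quality_control"),
    (4.1, "process_control"),
    (math.inf, "all_applications"),
)

RER_BANDS = (
    (4.0, "not_usable"),
    (10.0, "screening"),
    (15.0, "quality_control"),
    (math.inf, "quantification"),
)


def classify_rpd(rpd: float) -> str:
    """Application band for an RPD value (bands closed on the left)."""
    if rpd < 0:
        raise DomainError(f"RPD must be >= 0, got {rpd}")
    edges = [e for e, _ in RPD_BANDS]
    labels = [lab for _, lab in RPD_BANDS]
    for edge, label in zip(edges, labels):
        if rpd < edge:
            return label
    return labels[-1]


def classify_rer(rer: float) -> str:
    """Application band for an RER value (bands open on the left:
    RER must exceed 4/10/15 to earn screening/quality control/quantification)."""
    if rer < 0:
        raise DomainError(f"RER must be >= 0, got {rer}")
    for edge, label in RER_BANDS:
        if rer <= edge:
            return label
    return RER_BANDS[-1][1]  # pragma: no cover


def external_validate(
    model: PLSRModel, X_val: np.ndarray, y_val: np.ndarray
) -> ValidationReport:
    """Validate on held-out samples: bias, SEP, R2pre, RPD, RER and bands.

    SEP is bias-corrected (divisor n-1); RPD and RER divide the
    calibration-set reference SD and range by SEP.
    """
    y_val = np.asarray(y_val, dtype=float).ravel()
    n_val = y_val.size
    if n_val < 3:
        raise InsufficientValidationError(
            f"external validation needs >= 3 samples, got {n_val}"
        )
    yhat = predict(model, X_val)
    err = yhat - y_val
    bias = float(err.mean())
    sep = float(np.sqrt(np.sum((err - bias) ** 2) / (n_val - 1)))
    if sep == 0.0:
        return ValidationReport(
            n_val=n_val,
            bias=bias,
            sep=0.0,
            r2_pre=1.0,
            rpd=math.inf,
            rer=math.inf,
            rpd_band="all_applications",
            rer_band="quantification",
        )
    r2_pre = float(np.corrcoef(yhat, y_val)[0, 1]) ** 2
    rpd = model.calibration.sd_cal / sep
    rer = model.calibration.range_cal / sep
    return ValidationReport(
        n_val=n_val,
        bias=bias,
        sep=sep,
        r2_pre=r2_pre,
        rpd=rpd,
        rer=rer,
        rpd_band=classify_rpd(rpd),
        rer_band=classify_rer(rer),
    )


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    dataset: SpectralDataset,
    validation_fraction: float,
    seed: int,
    stratify: bool | None = None,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Seeded random train/validation split.

    Validation size is floor(n * fraction).  When class labels are present
    (and ``stratify`` is not False) the split is stratified: each class
    contributes floor(n_class * fraction) validation samples.
    """
    n = dataset.n_samples
    if not 0.0 < validation_fraction < 1.0:
        raise SplitError("validation_fraction must lie in (0, 1)")
    if n < 5:
        raise SplitError(f"need at least 5 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    if stratify is None:
        stratify = dataset.class_labels is not None
    if stratify and dataset.class_labels is None:
        raise SplitError("stratified split requested but dataset has no labels")

    val_idx: list[int] = []
    if stratify:
        labels = dataset.class_labels.to_numpy()
        for cls in pd.unique(labels):
            members = np.flatnonzero(labels == cls)
            k = int(np.floor(members.size * validation_fraction))
            val_idx.extend(rng.permutation(members)[:k].tolist())
    else:
        k = int(np.floor(n * validation_fraction))
        val_idx = rng.permutation(n)[:k].tolist()
    val_set = set(val_idx)
    train_idx = [i for i in range(n) if i not in val_set]
    return dataset.subset(train_idx), dataset.subset(sorted(val_idx))
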