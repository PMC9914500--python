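"""Config-driven end-to-end study workflow.

``run_all`` reproduces the full analysis on a synthetic (or user-supplied)
cohort: simulate/load -> regulatory screen -> per-trait PLS1 calibration
with leave-one-out LV selection, outlier passes and external validation
(one summary row per trait) -> SIMCA authentication of suspicious
samples (interclass distance, discriminating power, held-out performance).
Every stage is seeded and the persisted config + seeds reproduce the
report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import (
    RegionSet,
    SpectralDataset,
    TRAIT_NAMES,
    read_labels_csv,
    read_spectra_csv,
    read_traits_csv,
    select_region,
)
from .errors import ConfigError, HoneySpecError, MissingInputError
from .pls import (
    PLSRModel,
    external_validate,
    detect_outliers,
    fit_pls1,
    loocv,
    select_lv,
    split_dataset,
)
from .screen import RegulatoryLimits, ScreenSummary, screen_cohort
from .simca import (
    SIMCAModel,
    classify,
    cross_validated_misclassifications,
    fit_simca,
    performance,
)
from .simulate import CohortConfig, LabeledCohort, SUSPICIOUS_LABEL, generate_cohort

logger = logging.getLogger(__name__)

#: Default PLSR wavenumber regions: sugar/acid fingerprint plus the C-H and
#: O-H stretch region (the O-H stretch carries the moisture information).
DEFAULT_PLSR_REGION = RegionSet([(750.0, 1800.0), (2800.0, 3600.0)])

#: Default SIMCA authentication region (sugar fingerprint).
DEFAULT_SIMCA_REGION = RegionSet([(920.0, 1650.0)])


@dataclass(frozen=True)
class PLSRSettings:
    max_lv: int = 10
    parsimony_tol: float = 0.02
    outlier_passes: int = 2
    leverage_mult: float = 3.0
    resid_cut: float = 3.0


@dataclass(frozen=True)
class SIMCASettings:
    region: RegionSet = field(default_factory=lambda: DEFAULT_SIMCA_REGION)
    n_pc: int = 4
    alpha: float = 0.05
    positive_class: str = SUSPICIOUS_LABEL


@dataclass(frozen=True)
class SplitSettings:
    validation_fraction: float = 0.2
    seed: int = 20230124


@dataclass(frozen=True)
class InputFiles:
    """Load-mode inputs (instead of simulation)."""

    spectra: str
    traits: str | None = None
    labels: str | None = None


@dataclass
class RunConfig:
    """All knobs of the end-to-end workflow."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    inputs: InputFiles | None = None
    traits_to_model: tuple[str, ...] = TRAIT_NAMES
    regions: dict[str, RegionSet] = field(default_factory=dict)
    default_region: RegionSet = field(default_factory=lambda: DEFAULT_PLSR_REGION)
    split: SplitSettings = field(default_factory=SplitSettings)
    plsr: PLSRSettings = field(default_factory=PLSRSettings)
    simca: SIMCASettings = field(default_factory=SIMCASettings)
    limits: RegulatoryLimits = field(default_factory=RegulatoryLimits)
    output_dir: str | None = None

    def region_for(self, trait: str) -> RegionSet:
        return self.regions.get(trait, self.default_region)

    def to_dict(self) -> dict:
        return {
            "cohort": {
                "n_samples": self.cohort.n_samples,
                "n_adulterated": self.cohort.n_adulterated,
                "seed": self.cohort.seed,
                "noise_sd": self.cohort.noise_sd,
                "baseline_drift_max": self.cohort.baseline_drift_max,
                "adulterant_sucrose_range": list(
                    self.cohort.adulterant_sucrose_range
                ),
            },
            "inputs": None
            if self.inputs is None
            else {
                "spectra": self.inputs.spectra,
                "traits": self.inputs.traits,
                "labels": self.inputs.labels,
            },
            "traits_to_model": list(self.traits_to_model),
            "regions": {k: str(v) for k, v in self.regions.items()},
            "default_region": str(self.default_region),
            "split": {
                "validation_fraction": self.split.validation_fraction,
                "seed": self.split.seed,
            },
            "plsr": {
                "max_lv": self.plsr.max_lv,
                "parsimony_tol": self.plsr.parsimony_tol,
                "outlier_passes": self.plsr.outlier_passes,
                "leverage_mult": self.plsr.leverage_mult,
                "resid_cut": self.plsr.resid_cut,
            },
            "simca": {
                "region": str(self.simca.region),
                "n_pc": self.simca.n_pc,
                "alpha": self.simca.alpha,
                "positive_class": self.simca.positive_class,
            },
            "limits": {
                "sucrose_max": self.limits.sucrose_max,
                "glucose_plus_fructose_min": self.limits.glucose_plus_fructose_min,
                "hmf_max": self.limits.hmf_max,
                "moisture_max": self.limits.moisture_max,
                "free_acidity_max": self.limits.free_acidity_max,
                "water_activity_spoilage": self.limits.water_activity_spoilage,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        cfg = cls()
        cohort = {**d.get("cohort", {})}
        if "adulterant_sucrose_range" in cohort:
            cohort["adulterant_sucrose_range"] = tuple(
                cohort["adulterant_sucrose_range"]
            )
        cfg.cohort = CohortConfig(**cohort)
        if d.get("inputs"):
            cfg.inputs = InputFiles(**d["inputs"])
        if "traits_to_model" in d:
            cfg.traits_to_model = tuple(d["traits_to_model"])
        cfg.regions = {
            k: RegionSet.parse(v) for k, v in d.get("regions", {}).items()
        }
        if "default_region" in d:
            cfg.default_region = RegionSet.parse(d["default_region"])
        if "split" in d:
            cfg.split = SplitSettings(**d["split"])
        if "plsr" in d:
            cfg.plsr = PLSRSettings(**d["plsr"])
        if "simca" in d:
            s = dict(d["simca"])
            if "region" in s:
                s["region"] = RegionSet.parse(s["region"])
            cfg.simca = SIMCASettings(**s)
        if "limits" in d:
            cfg.limits = RegulatoryLimits(**d["limits"])
        cfg.output_dir = d.get("output_dir")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


CALIBRATION_COLUMNS = [
    "trait", "range_cal_min", "range_cal_max", "n_cal", "factor",
    "secv", "r2_cv", "range_val_min", "range_val_max", "n_val",
    "sep", "r2_pre", "bias", "rpd", "rer", "rpd_band", "rer_band",
    "n_outliers_removed", "region",
]


@dataclass
class StudyReport:
    """Consolidated output of one full run."""

    calibration_table: pd.DataFrame
    simca_summary: dict
    screen_summary: dict
    provenance: dict
    discriminating_power: pd.DataFrame | None = None
    plsr_models: dict[str, PLSRModel] = field(default_factory=dict)
    simca_model: SIMCAModel | None = None

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.calibration_table.to_csv(out / "calibration_table.csv", index=False, float_format="%.6g")
        with open(out / "simca_summary.json", "w") as fh:
            json.dump(self.simca_summary, fh, indent=2, sort_keys=True)
        with open(out / "screen_summary.json", "w") as fh:
            json.dump(self.screen_summary, fh, indent=2, sort_keys=True)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        if self.discriminating_power is not None:
            self.discriminating_power.to_csv(
                out / "discriminating_power.csv", float_format="%.6g"
            )


def load_or_simulate(config: RunConfig) -> SpectralDataset:
    """Load the configured input files, or simulate the default cohort.

    Load mode fails fast: all configured paths are checked before any file
    is parsed.
    """
    if config.inputs is None:
        return generate_cohort(config.cohort).dataset
    paths = {
        "spectra": config.inputs.spectra,
        "traits": config.inputs.traits,
        "labels": config.inputs.labels,
    }
    missing = [
        f"{kind}: {p}" for kind, p in paths.items()
        if p is not None and not Path(p).exists()
    ]
    if missing:
        raise MissingInputError(
            "configured input files not found -- " + "; ".join(missing)
        )
    traits = (
        read_traits_csv(config.inputs.traits)
        if config.inputs.traits
        else None
    )
    labels = (
        read_labels_csv(config.inputs.labels)
        if config.inputs.labels
        else None
    )
    return read_spectra_csv(config.inputs.spectra, traits=traits, class_labels=labels)


def quantify_trait(
    config: RunConfig, dataset: SpectralDataset, trait: str
) -> tuple[dict, PLSRModel]:
    """Calibrate and externally validate one trait model; returns the
    per-trait summary row and the final model."""
    if dataset.traits is None or trait not in dataset.traits.columns:
        raise ConfigError(f"dataset has no reference values for trait {trait!r}")
    region = config.region_for(trait)
    sub = select_region(dataset, region)
    has_y = sub.traits[trait].notna()
    sub = sub.subset(np.flatnonzero(has_y.to_numpy()))
    train, val = split_dataset(
        sub, config.split.validation_fraction, config.split.seed, stratify=False
    )

    X = train.matrix
    y = train.traits[trait].to_numpy(dtype=float)
    ids = list(train.sample_ids)
    removed: list[str] = []
    p = config.plsr
    for pass_i in range(p.outlier_passes + 1):
        max_lv = min(p.max_lv, len(y) - 2)
        cv = loocv(X, y, max_lv)
        a = select_lv(cv, p.parsimony_tol)
        model = fit_pls1(
            X, y, a, wavenumbers=train.wavenumbers, region=region,
            trait_name=trait,
        )
        model.calibration.secv = float(cv.secv[a - 1])
        model.calibration.r2_cv = float(cv.r2_cv[a - 1])
        if pass_i == p.outlier_passes:
            break
        rep = detect_outliers(
            model, X, y, p.leverage_mult, p.resid_cut, sample_ids=ids
        )
        if not rep.flagged:
            break
        logger.info("trait %s pass %d: removing outliers %s",
                    trait, pass_i + 1, rep.flagged)
        keep = [i for i, s in enumerate(ids) if s not in set(rep.flagged)]
        removed.extend(rep.flagged)
        X, y = X[keep], y[keep]
        ids = [ids[i] for i in keep]

    y_val = val.traits[trait].to_numpy(dtype=float)
    report = external_validate(model, val.matrix, y_val)
    row = {
        "trait": trait,
        "range_cal_min": float(y.min()),
        "range_cal_max": float(y.max()),
        "n_cal": len(y),
        "factor": model.n_lv,
        "secv": model.calibration.secv,
        "r2_cv": model.calibration.r2_cv,
        "range_val_min": float(y_val.min()),
        "range_val_max": float(y_val.max()),
        "n_val": report.n_val,
        "sep": report.sep,
        "r2_pre": report.r2_pre,
        "bias": report.bias,
        "rpd": report.rpd,
        "rer": report.rer,
        "rpd_band": report.rpd_band,
        "rer_band": report.rer_band,
        "n_outliers_removed": len(removed),
        "region": str(region),
    }
    return row, model


def run_quantification(
    config: RunConfig, dataset: SpectralDataset | None = None
) -> StudyReport:
    """Fit all configured trait models; one per-trait summary row per trait.

    A failing trait is logged and skipped; the others continue.
    """
    t0 = time.perf_counter()
    if dataset is None:
        dataset = load_or_simulate(config)
    rows, models = [], {}
    for trait in config.traits_to_model:
        try:
            row, model = quantify_trait(config, dataset, trait)
        except HoneySpecError as exc:
            logger.error("trait %s failed: %s", trait, exc)
            continue
        rows.append(row)
        models[trait] = model
    calibration_table = pd.DataFrame(rows, columns=CALIBRATION_COLUMNS)
    logger.info("quantification finished in %.1f s", time.perf_counter() - t0)
    return StudyReport(
        calibration_table=calibration_table,
        simca_summary={},
        screen_summary={},
        provenance=_provenance(config),
        plsr_models=models,
    )


def run_authentication(
    config: RunConfig, dataset: SpectralDataset | None = None
) -> StudyReport:
    """SIMCA authentication: stratified split, per-class PCA models,
    cross-validated training misclassification, held-out performance."""
    t0 = time.perf_counter()
    if dataset is None:
        dataset = load_or_simulate(config)
    if dataset.class_labels is None:
        raise ConfigError("authentication needs class labels")
    classes = set(dataset.class_labels)
    pos = config.simca.positive_class
    if pos not in classes:
        raise ConfigError(
            f"cohort contains no {pos!r} samples (classes present: "
            f"{sorted(classes)}); authentication needs both classes"
        )
    if len(classes) < 2:
        raise ConfigError(
            f"cohort has a single class {sorted(classes)}; authentication "
            "needs at least two"
        )

    sub = select_region(dataset, config.simca.region)
    train, val = split_dataset(
        sub, config.split.validation_fraction, config.split.seed, stratify=True
    )
    labels_train = train.class_labels.to_numpy()
    model = fit_simca(
        train.matrix,
        labels_train,
        n_pc=config.simca.n_pc,
        alpha=config.simca.alpha,
        wavenumbers=train.wavenumbers,
        region=config.simca.region,
    )
    cv_mis = cross_validated_misclassifications(
        train.matrix, labels_train, n_pc=config.simca.n_pc,
        alpha=config.simca.alpha,
    )
    result = classify(model, val.matrix, sample_ids=val.sample_ids)
    stats = performance(result, val.class_labels, positive_class=pos)

    def pct(x):
        return None if x is None else 100.0 * x

    icd = model.icd_matrix
    pair_icd = (
        float(icd.to_numpy()[np.triu_indices(len(icd), k=1)].max())
        if len(icd) > 1
        else None
    )
    summary = {
        "n_train": {c: int((labels_train == c).sum()) for c in sorted(classes)},
        "n_validation": {
            c: int((val.class_labels == c).sum()) for c in sorted(classes)
        },
        "n_pc": config.simca.n_pc,
        "alpha": config.simca.alpha,
        "region": str(config.simca.region),
        "interclass_distance": pair_icd,
        "cv_misclassifications": int(cv_mis),
        "sensitivity_pct": pct(stats.sensitivity),
        "specificity_pct": pct(stats.specificity),
        "accuracy_pct": pct(stats.accuracy),
        "precision_pct": pct(stats.precision),
        "validation_misclassified": stats.misclassified,
        "positive_class": pos,
        "explained_variance_4pc": {
            m.class_label: float(np.sum(m.explained_variance))
            for m in model.class_models
        },
    }
    logger.info("authentication finished in %.1f s", time.perf_counter() - t0)
    return StudyReport(
        calibration_table=pd.DataFrame(columns=CALIBRATION_COLUMNS),
        simca_summary=summary,
        screen_summary={},
        provenance=_provenance(config),
        discriminating_power=model.discriminating_power,
        simca_model=model,
    )


def run_all(config: RunConfig) -> StudyReport:
    """Simulate (or load), screen, quantify and authenticate; one report."""
    dataset = load_or_simulate(config)
    screen: ScreenSummary | None = None
    screen_summary: dict = {}
    if dataset.traits is not None:
        screen = screen_cohort(dataset.traits, config.limits)
        screen_summary = {
            "counts": screen.counts,
            "n_flagged_any": screen.n_flagged_any,
            "n_flagged_multiple": screen.n_flagged_multiple,
            "sucrose_hmf_overlap": screen.overlap("sucrose_max", "hmf_max"),
        }
    quant = run_quantification(config, dataset)
    auth = run_authentication(config, dataset)
    report = StudyReport(
        calibration_table=quant.calibration_table,
        simca_summary=auth.simca_summary,
        screen_summary=screen_summary,
        provenance=_provenance(config),
        discriminating_power=auth.discriminating_power,
        plsr_models=quant.plsr_models,
        simca_model=auth.simca_model,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _provenance(config: RunConfig) -> dict:
    d = config.to_dict()
    blob = json.dumps(d, sort_keys=True).encode()
    return {
        "config": d,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": {"cohort": config.cohort.seed, "split": config.split.seed},
        "version": __version__,
    }
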