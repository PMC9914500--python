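"""Synthetic ATR-FT-IR honey cohorts.

Spectra are assembled as a Beer-Lambert-style linear mixture of component
spectra, each a sum of Gaussian bands at the mid-IR assignments for honey:
O-H stretching/deformation of water at 3285/1637 cm^-1, the carbohydrate
C-H stretch at 2930 cm^-1, the sugar fingerprint (1043, 1063, 1020, 918,
1321, 1254, 1411 cm^-1), the glycosidic C-O-C band at 1110 cm^-1, and the
HMF carbonyl near 1666 cm^-1.  Pure honey shows its characteristic sugar
band at 1020 cm^-1; sweetener-adulterated ("suspicious") samples express a
sucrose-syrup component whose fingerprint band sits at 1010 cm^-1 with an
enhanced 1110 cm^-1 glycosidic band, reproducing the 1020 -> 1010 shift
seen in adulterated honey.  The shift is compositional (a different
component), not a warp of the pure-honey bands.

Trait values follow the reference distributions of the study cohort
(truncated normals on the printed min/max/mean/SD), with two physically
motivated couplings that make the trait table internally consistent:
soluble solids mirror 94.5 - moisture, water activity tracks
0.21 + 0.02*moisture, and pH tracks free acidity.  Adulterated samples
draw sucrose uniformly from the adulterant range (default 5.1-12.6 %);
pure samples stay below the 5 % regulatory limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CANONICAL_GRID, TRAIT_NAMES, SpectralDataset, Spectrum
from .errors import ConfigError, IncompleteTraitsError, UnknownComponentError

PURE_LABEL = "pure"
SUSPICIOUS_LABEL = "suspicious"


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (cm^-1), sigma (cm^-1), height
    (AU per unit concentration)."""

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0, got {self.width}")
        if self.height < 0:
            raise ConfigError(f"band height must be >= 0, got {self.height}")


# Band centers come from the honey mid-IR assignments; widths and heights
# are simulator parameters calibrated once so composite spectra look like
# averaged raw honey spectra and so downstream calibration statistics land
# in the regime reported for real cohorts.  Heights are AU per unit of the
# driving concentration (percent, meq/kg, or mg/kg*1e-3 for HMF).
COMPONENT_LIBRARY: dict[str, tuple[BandSpec, ...]] = {
    "water": (
        BandSpec(3285.0, 110.0, 0.035),   # O-H stretching
        BandSpec(1637.0, 30.0, 0.003),    # O-H deformation
    ),
    "glucose": (
        BandSpec(2930.0, 25.0, 0.004),    # C-H stretch (CH2)
        BandSpec(1411.0, 18.0, 0.003),    # O-H bending of C-OH
        BandSpec(1043.0, 14.0, 0.010),    # C-O stretch in C-OH
        BandSpec(1020.0, 10.0, 0.012),    # pure-honey sugar marker
        BandSpec(918.0, 10.0, 0.004),     # C-H bending
    ),
    "fructose": (
        BandSpec(2930.0, 25.0, 0.004),
        BandSpec(1321.0, 15.0, 0.003),    # O-H bending of C-OH
        BandSpec(1254.0, 12.0, 0.003),    # C-C stretch
        BandSpec(1063.0, 12.0, 0.008),
        BandSpec(1020.0, 10.0, 0.010),
    ),
    "sucrose_honey": (
        BandSpec(1110.0, 10.0, 0.020),    # glycosidic C-O-C (weak)
        BandSpec(1020.0, 10.0, 0.150),
    ),
    "sucrose_adulterant": (
        BandSpec(1110.0, 10.0, 0.060),    # glycosidic C-O-C (enhanced)
        BandSpec(1010.0, 10.0, 0.180),    # shifted fingerprint band
    ),
    "organic_acids": (
        BandSpec(1411.0, 15.0, 0.0025),
        BandSpec(1254.0, 12.0, 0.0015),
    ),
    "hmf": (
        BandSpec(1666.0, 12.0, 1.0),      # conjugated carbonyl
    ),
}


@dataclass(frozen=True)
class TraitDistribution:
    """Truncated-normal specification for one trait (units of the trait)."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ConfigError("trait minimum must be below maximum")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.minimum - self.mean) / self.sd
        b = (self.maximum - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(values, self.minimum, self.maximum)


#: Reference cohort distributions (min, max, mean, SD) for the nine traits.
DEFAULT_TRAIT_DISTRIBUTIONS: dict[str, TraitDistribution] = {
    "soluble_solids": TraitDistribution(78.7, 3.2, 72.4, 82.7),
    "pH": TraitDistribution(4.02, 0.2, 3.73, 4.61),
    "free_acidity": TraitDistribution(27.9, 6.8, 8.71, 38.9),
    "moisture": TraitDistribution(15.8, 0.9, 13.6, 19.7),
    "water_activity": TraitDistribution(0.53, 0.04, 0.45, 0.62),
    "glucose": TraitDistribution(30.2, 5.1, 15.3, 39.2),
    "fructose": TraitDistribution(39.4, 2.7, 31.2, 48.4),
    "sucrose": TraitDistribution(2.1, 2.1, 0.3, 12.6),
    "hmf": TraitDistribution(34.6, 7.8, 17.6, 86.9),
}

# Trait couplings (simulator configuration, not literature claims): Brix is
# the non-water fraction, water activity rises with moisture, pH falls with
# free acidity.  Noise SDs are small enough that the couplings stay
# spectrally recoverable.
BRIX_OFFSET = 94.5
BRIX_NOISE_SD = 0.2
AW_INTERCEPT = 0.21
AW_SLOPE = 0.02
AW_NOISE_SD = 0.004
PH_SLOPE = -0.028  # pH units per meq/kg of free acidity
PH_NOISE_SD = 0.03


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults reproduce the reference cohort: 147 samples of which 21 carry
    added sucrose above the 5 % limit, instrument noise 0.002 AU, and trait
    distributions from the reference table.
    """

    n_samples: int = 147
    n_adulterated: int = 21
    seed: int = 20230124
    noise_sd: float = 0.002
    baseline_drift_max: float = 0.001
    adulterant_sucrose_range: tuple[float, float] = (5.1, 12.6)
    trait_distributions: dict[str, TraitDistribution] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_DISTRIBUTIONS)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.n_adulterated <= self.n_samples:
            raise ConfigError(
                f"n_adulterated={self.n_adulterated} must lie in "
                f"[0, n_samples={self.n_samples}]"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline_drift_max < 0:
            raise ConfigError("baseline_drift_max must be >= 0")
        lo, hi = self.adulterant_sucrose_range
        if not lo < hi:
            raise ConfigError("adulterant_sucrose_range must satisfy low < high")
        missing = set(TRAIT_NAMES) - set(self.trait_distributions)
        if missing:
            raise ConfigError(f"trait_distributions missing {sorted(missing)}")


@dataclass
class LabeledCohort:
    """A generated cohort plus its generating ground truth.

    ``dataset`` carries traits and class labels; ``ground_truth`` stores the
    per-sample component concentrations actually used to build each
    spectrum.
    """

    dataset: SpectralDataset
    ground_truth: pd.DataFrame


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"H{i + 1:0{width}d}" for i in range(n)]


def sample_traits(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a trait table and class labels for one cohort.

    Independent traits (moisture, free acidity, glucose, fructose, HMF) are
    truncated normals; soluble solids, water activity and pH are coupled as
    described in the module docstring; sucrose is drawn below 5 % for pure
    samples and uniformly from the adulterant range for suspicious ones.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    dists = config.trait_distributions
    ids = _sample_ids(n)

    moisture = dists["moisture"].rvs(n, rng)
    acidity = dists["free_acidity"].rvs(n, rng)
    glucose = dists["glucose"].rvs(n, rng)
    fructose = dists["fructose"].rvs(n, rng)
    hmf = dists["hmf"].rvs(n, rng)

    brix = dists["soluble_solids"].clip(
        BRIX_OFFSET - moisture + rng.normal(0.0, BRIX_NOISE_SD, n)
    )
    aw = dists["water_activity"].clip(
        AW_INTERCEPT + AW_SLOPE * moisture + rng.normal(0.0, AW_NOISE_SD, n)
    )
    ph = dists["pH"].clip(
        dists["pH"].mean
        + PH_SLOPE * (acidity - dists["free_acidity"].mean)
        + rng.normal(0.0, PH_NOISE_SD, n)
    )

    # sucrose: pure below the 5 % limit, adulterated inside the syrup range
    suc = dists["sucrose"]
    pure_dist = TraitDistribution(suc.mean, suc.sd, suc.minimum, 5.0)
    sucrose = pure_dist.rvs(n, rng)
    labels = np.full(n, PURE_LABEL, dtype=object)
    adulterated = rng.choice(n, size=config.n_adulterated, replace=False)
    lo, hi = config.adulterant_sucrose_range
    sucrose[adulterated] = rng.uniform(lo, hi, size=config.n_adulterated)
    labels[adulterated] = SUSPICIOUS_LABEL

    traits = pd.DataFrame(
        {
            "soluble_solids": brix,
            "pH": ph,
            "free_acidity": acidity,
            "moisture": moisture,
            "water_activity": aw,
            "glucose": glucose,
            "fructose": fructose,
            "sucrose": sucrose,
            "hmf": hmf,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return traits, pd.Series(labels, index=traits.index, name="class_label")


def component_spectrum(
    component: str, grid: np.ndarray = CANONICAL_GRID
) -> Spectrum:
    """Unit-concentration spectrum of one library component on a grid."""
    try:
        bands = COMPONENT_LIBRARY[component]
    except KeyError:
        raise UnknownComponentError(
            f"unknown component {component!r}; known: "
            f"{sorted(COMPONENT_LIBRARY)}"
        ) from None
    w = np.asarray(grid, dtype=float)
    a = np.zeros_like(w)
    for b in bands:
        a += b.height * np.exp(-0.5 * ((w - b.center) / b.width) ** 2)
    return Spectrum(w, a)


def component_concentrations(traits: pd.Series, label: str) -> dict[str, float]:
    """Map one trait row onto component concentrations.

    Pure samples express their sucrose through the honey-sucrose component;
    suspicious samples through the adulterant-syrup component.  HMF is
    rescaled from mg/kg to the simulator's concentration unit.
    """
    required = ("moisture", "glucose", "fructose", "sucrose", "free_acidity", "hmf")
    missing = [t for t in required if t not in traits or pd.isna(traits[t])]
    if missing:
        raise IncompleteTraitsError(f"traits missing for spectrum: {missing}")
    suspicious = label == SUSPICIOUS_LABEL
    return {
        "water": float(traits["moisture"]),
        "glucose": float(traits["glucose"]),
        "fructose": float(traits["fructose"]),
        "sucrose_honey": 0.0 if suspicious else float(traits["sucrose"]),
        "sucrose_adulterant": float(traits["sucrose"]) if suspicious else 0.0,
        "organic_acids": float(traits["free_acidity"]),
        "hmf": float(traits["hmf"]) * 1e-3,
    }


def generate_spectrum(
    traits: pd.Series,
    label: str,
    config: CohortConfig,
    seed: int | np.random.Generator | np.random.SeedSequence,
    grid: np.ndarray = CANONICAL_GRID,
) -> Spectrum:
    """One noisy mixture spectrum for a trait row.

    absorbance = sum_c conc_c * component_c  +  linear baseline  +  noise,
    with the baseline a straight line whose end-to-end excursion is at most
    +/- ``baseline_drift_max`` and noise i.i.d. N(0, noise_sd).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = np.asarray(grid, dtype=float)
    concs = component_concentrations(traits, label)
    a = np.zeros_like(w)
    for name, conc in concs.items():
        if conc != 0.0:
            a += conc * component_spectrum(name, w).absorbances
    drift = rng.uniform(-config.baseline_drift_max, config.baseline_drift_max)
    span = w.max() - w.min()
    a += drift * (w - 0.5 * (w.max() + w.min())) / span
    a += rng.normal(0.0, config.noise_sd, size=w.size)
    return Spectrum(w, a)


def generate_cohort(config: CohortConfig) -> LabeledCohort:
    """Generate a full labeled cohort on the canonical grid.

    Deterministic under ``config.seed``: traits, adulteration membership,
    baselines and noise all derive from one seed sequence.
    """
    root = np.random.SeedSequence(config.seed)
    trait_ss, spectra_ss = root.spawn(2)
    traits, labels = sample_traits(config, np.random.default_rng(trait_ss))
    child_seeds = spectra_ss.spawn(config.n_samples)

    rows = []
    truth_rows = []
    for (sid, row), label, ss in zip(traits.iterrows(), labels, child_seeds):
        spec = generate_spectrum(row, label, config, ss)
        rows.append(spec.absorbances)
        truth = component_concentrations(row, label)
        truth["class_label"] = label
        truth_rows.append(truth)

    dataset = SpectralDataset(
        sample_ids=list(traits.index),
        matrix=np.vstack(rows),
        wavenumbers=CANONICAL_GRID.copy(),
        traits=traits,
        class_labels=labels,
    )
    ground_truth = pd.DataFrame(truth_rows, index=traits.index)
    return LabeledCohort(dataset=dataset, ground_truth=ground_truth)
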