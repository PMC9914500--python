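"""Data model and I/O for ATR-FT-IR spectra and honey trait tables.

A spectrum is an absorbance trace on a strictly descending wavenumber grid
(cm^-1).  The canonical instrument grid spans 4000 to 700 cm^-1 in 4 cm^-1
steps (826 points, both endpoints on-grid).  Cohorts are stored wide
(samples x wavenumbers) together with optional per-sample reference traits
and class labels; the primary exchange format is CSV with a numeric
wavenumber header row and a ``sample_id`` index column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptySelectionError,
    GridError,
    OutOfRangeError,
    SpectraParseError,
    TraitValidationError,
)

logger = logging.getLogger(__name__)

GRID_MAX = 4000.0
GRID_MIN = 700.0
GRID_STEP = 4.0

#: Canonical acquisition grid: 4000, 3996, ..., 700 cm^-1 (826 points).
CANONICAL_GRID = np.arange(GRID_MAX, GRID_MIN - GRID_STEP / 2, -GRID_STEP)

#: The nine reference quality traits, in conventional reporting order.
TRAIT_NAMES = (
    "soluble_solids",   # deg Brix
    "pH",               # unitless
    "free_acidity",     # meq/kg
    "moisture",         # %
    "water_activity",   # unitless
    "glucose",          # %
    "fructose",         # %
    "sucrose",          # %
    "hmf",              # mg/kg
)


def _check_grid(wavenumbers: np.ndarray) -> np.ndarray:
    """Validate a wavenumber grid, normalizing ascending input to descending."""
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError("wavenumber grid must be 1-D with at least 2 points")
    if not np.all(np.isfinite(w)):
        raise GridError("wavenumber grid contains non-finite values")
    d = np.diff(w)
    if np.all(d < 0):
        return w
    if np.all(d > 0):
        logger.info("ascending wavenumber grid normalized to descending order")
        return w[::-1]
    raise GridError("wavenumber grid is not strictly monotone")


@dataclass(frozen=True)
class Spectrum:
    """One sample's absorbance trace.

    Parameters
    ----------
    wavenumbers
        Strictly decreasing grid, cm^-1. Ascending input is reversed
        (with a log notice) so stored order is always descending.
    absorbances
        Absorbance (AU), same length as the grid, all finite.
    """

    wavenumbers: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.shape != a.shape:
            raise GridError(
                f"wavenumbers ({w.size}) and absorbances ({a.size}) differ in length"
            )
        wd = _check_grid(w)
        if wd is not w or wd[0] != w[0]:
            a = a[::-1]
        if not np.all(np.isfinite(a)):
            raise SpectraParseError("absorbances contain NaN or Inf")
        object.__setattr__(self, "wavenumbers", wd)
        object.__setattr__(self, "absorbances", a)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class RegionSet:
    """Union of closed wavenumber intervals [low, high] in cm^-1.

    Intervals may overlap; selection uses their union.  Bounds are
    inclusive and an off-grid bound simply keeps the in-range grid points
    (selection is a filter, never a resample).
    """

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Iterable[Sequence[float]]):
        ivs = []
        for iv in intervals:
            low, high = float(iv[0]), float(iv[1])
            if not low < high:
                raise GridError(f"region [{low}, {high}] must have low < high")
            ivs.append((low, high))
        if not ivs:
            raise GridError("RegionSet needs at least one interval")
        object.__setattr__(self, "intervals", tuple(ivs))

    @classmethod
    def parse(cls, text: str) -> "RegionSet":
        """Parse ``"920:1650,2800:3600"`` style region lists."""
        ivs = []
        for part in text.split(","):
            lo, _, hi = part.partition(":")
            ivs.append((float(lo), float(hi)))
        return cls(ivs)

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers, dtype=float)
        m = np.zeros(w.shape, dtype=bool)
        for low, high in self.intervals:
            m |= (w >= low) & (w <= high)
        return m

    def __str__(self) -> str:
        return ",".join(f"{lo:g}:{hi:g}" for lo, hi in self.intervals)


#: Full-grid region (identity selection on the canonical grid).
FULL_REGION = RegionSet([(GRID_MIN, GRID_MAX)])


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait table: known columns, finite non-negative values.

    Unknown columns raise; missing traits (absent columns or NaN cells) are
    allowed.  pH must additionally lie in (0, 14).
    """
    unknown = set(traits.columns) - set(TRAIT_NAMES)
    if unknown:
        raise TraitValidationError(f"unknown trait columns: {sorted(unknown)}")
    for col in traits.columns:
        vals = pd.to_numeric(traits[col], errors="coerce")
        bad = traits[col].notna() & vals.isna()
        if bad.any():
            raise SpectraParseError(
                f"non-numeric value in trait column {col!r}, sample "
                f"{traits.index[bad.argmax()]!r}"
            )
        present = vals.dropna()
        if np.isinf(present).any():
            raise TraitValidationError(f"infinite value in trait {col!r}")
        if (present < 0).any():
            raise TraitValidationError(f"negative value in trait {col!r}")
        if col == "pH" and ((present <= 0) | (present >= 14)).any():
            raise TraitValidationError("pH outside (0, 14)")
    return traits.astype(float)


@dataclass
class SpectralDataset:
    """A cohort of spectra on one shared grid.

    Attributes
    ----------
    sample_ids
        Unique text labels, one per row of ``matrix``.
    matrix
        n_samples x n_wavenumbers absorbance matrix (AU).
    wavenumbers
        Shared strictly descending grid (cm^-1).
    traits
        Optional reference trait table indexed by sample id (subset of the
        nine trait columns).
    class_labels
        Optional class label per sample (e.g. ``"pure"`` / ``"suspicious"``),
        indexed by sample id.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    wavenumbers: np.ndarray
    traits: pd.DataFrame | None = None
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise DuplicateIdError(f"duplicate sample ids: {dupes}")
        w = np.asarray(self.wavenumbers, dtype=float)
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2 or X.shape != (len(self.sample_ids), w.size):
            raise GridError(
                f"matrix shape {X.shape} does not match "
                f"{len(self.sample_ids)} samples x {w.size} wavenumbers"
            )
        wd = _check_grid(w)
        if wd[0] != w[0]:
            X = X[:, ::-1]
        if not np.all(np.isfinite(X)):
            raise SpectraParseError("spectral matrix contains NaN or Inf")
        self.wavenumbers = wd
        self.matrix = X
        if self.traits is not None:
            if set(self.traits.index) != set(self.sample_ids):
                raise TraitValidationError(
                    "trait table does not cover exactly the dataset sample ids"
                )
            self.traits = validate_traits(
                self.traits.loc[self.sample_ids]
            )
        if self.class_labels is not None:
            labels = pd.Series(self.class_labels)
            if set(labels.index) != set(self.sample_ids):
                raise TraitValidationError(
                    "class labels do not cover exactly the dataset sample ids"
                )
            self.class_labels = labels.loc[self.sample_ids].astype(str)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def spectrum(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        return Spectrum(self.wavenumbers.copy(), self.matrix[i].copy())

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        """Row subset preserving grid, traits and labels."""
        ids = [self.sample_ids[i] for i in indices]
        return SpectralDataset(
            sample_ids=ids,
            matrix=self.matrix[list(indices)].copy(),
            wavenumbers=self.wavenumbers.copy(),
            traits=None if self.traits is None else self.traits.loc[ids].copy(),
            class_labels=None
            if self.class_labels is None
            else self.class_labels.loc[ids].copy(),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(
    path: str | Path,
    traits: pd.DataFrame | None = None,
    class_labels: pd.Series | None = None,
) -> SpectralDataset:
    """Read a wide spectra CSV (header = wavenumbers, column 1 = sample id).

    An ascending wavenumber header is accepted and reversed to the canonical
    descending order (logged).  Non-monotone grids, duplicate ids and
    non-numeric cells raise.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    try:
        grid = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise GridError(f"non-numeric wavenumber header in {path}: {exc}") from None
    if df.index.has_duplicates:
        raise DuplicateIdError(
            f"duplicate sample ids in {path}: "
            f"{sorted(df.index[df.index.duplicated()].unique())}"
        )
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.any().any() or values.isna().any().any():
        mask = values.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise SpectraParseError(
            f"non-numeric cell in {path} at sample {df.index[i]!r}, "
            f"wavenumber column {df.columns[j]!r}"
        )
    return SpectralDataset(
        sample_ids=list(df.index.astype(str)),
        matrix=values.to_numpy(dtype=float),
        wavenumbers=grid,
        traits=traits,
        class_labels=class_labels,
    )


def write_spectra_csv(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset to wide CSV, preserving full float precision."""
    df = pd.DataFrame(
        dataset.matrix,
        index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=[f"{w:g}" for w in dataset.wavenumbers],
    )
    df.to_csv(path, float_format="%.17g")


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    """Read a trait table CSV (columns: sample_id + any of the nine traits)."""
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    return validate_traits(df)


def write_traits_csv(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_labels_csv(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, class_label) CSV."""
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    return df.iloc[:, 0].astype(str).rename("class_label")


def write_labels_csv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("class_label").to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def select_region(dataset: SpectralDataset, regions: RegionSet) -> SpectralDataset:
    """Keep exactly the grid points inside the union of intervals.

    Bounds are inclusive; grid order is preserved.  Raises if nothing is
    retained.
    """
    m = regions.mask(dataset.wavenumbers)
    if not m.any():
        raise EmptySelectionError(
            f"regions {regions} select no points on the dataset grid"
        )
    return SpectralDataset(
        sample_ids=list(dataset.sample_ids),
        matrix=dataset.matrix[:, m].copy(),
        wavenumbers=dataset.wavenumbers[m].copy(),
        traits=None if dataset.traits is None else dataset.traits.copy(),
        class_labels=None
        if dataset.class_labels is None
        else dataset.class_labels.copy(),
    )


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    target = _check_grid(np.asarray(grid, dtype=float))
    src_w = spectrum.wavenumbers
    if target.max() > src_w.max() or target.min() < src_w.min():
        raise OutOfRangeError(
            f"target grid [{target.min():g}, {target.max():g}] exceeds source "
            f"range [{src_w.min():g}, {src_w.max():g}]"
        )
    # np.interp needs ascending abscissae
    a = np.interp(target[::-1], src_w[::-1], spectrum.absorbances[::-1])[::-1]
    return Spectrum(target, a)
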