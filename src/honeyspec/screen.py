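"""Codex Alimentarius / EU regulatory screen for honey trait tables.

Limits (config-overridable defaults): sucrose <= 5 g/100 g,
glucose + fructose >= 60 g/100 g, HMF <= 40 mg/kg, moisture <= 20 %,
free acidity <= 50 meq/kg.  Water activity above 0.6 is reported as a
microbiological spoilage risk (osmophilic yeasts), not a legal
non-compliance.  Comparisons are strict: a value exactly at its limit is
compliant ("not exceed" semantics), and glucose + fructose exactly 60 is
tolerated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TraitValidationError

logger = logging.getLogger(__name__)

#: rule id -> (traits required, direction)
RULES = (
    "sucrose_max",
    "glucose_fructose_min",
    "hmf_max",
    "moisture_max",
    "free_acidity_max",
    "water_activity_spoilage",
)


@dataclass(frozen=True)
class RegulatoryLimits:
    """Threshold set for the screen (defaults: Codex/EU values)."""

    sucrose_max: float = 5.0              # %
    glucose_plus_fructose_min: float = 60.0  # %
    hmf_max: float = 40.0                 # mg/kg
    moisture_max: float = 20.0            # %
    free_acidity_max: float = 50.0        # meq/kg
    water_activity_spoilage: float = 0.6  # unitless

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise TraitValidationError(f"limit {name} must be positive")


@dataclass(frozen=True)
class RuleFlag:
    rule_id: str
    measured: float
    limit: float
    direction: str  # "above_max" or "below_min"


@dataclass
class RegulatoryFlags:
    """Screen outcome for one sample."""

    sample_id: str
    flags: list[RuleFlag]
    skipped: list[str]  # rules not evaluated for missing traits

    @property
    def suspicious_adulteration(self) -> bool:
        return any(f.rule_id == "sucrose_max" for f in self.flags)

    @property
    def spoilage_risk(self) -> bool:
        return any(f.rule_id == "water_activity_spoilage" for f in self.flags)

    @property
    def rule_ids(self) -> set[str]:
        return {f.rule_id for f in self.flags}


@dataclass
class ScreenSummary:
    """Cohort-level screen: per-rule counts plus the per-sample flag table."""

    counts: dict[str, int]
    flag_table: pd.DataFrame  # samples x rules, boolean
    per_sample: list[RegulatoryFlags]

    @property
    def n_flagged_any(self) -> int:
        return int(self.flag_table.any(axis=1).sum())

    @property
    def n_flagged_multiple(self) -> int:
        return int((self.flag_table.sum(axis=1) > 1).sum())

    def overlap(self, rule_a: str, rule_b: str) -> int:
        """Samples flagged by both rules (e.g. sucrose and HMF)."""
        return int((self.flag_table[rule_a] & self.flag_table[rule_b]).sum())


def _value(traits, name) -> float | None:
    if name not in traits:
        return None
    v = traits[name]
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    v = float(v)
    if v < 0:
        raise TraitValidationError(f"negative {name}: {v}")
    return v


def screen_sample(
    traits, limits: RegulatoryLimits = RegulatoryLimits(), sample_id: str = ""
) -> RegulatoryFlags:
    """Screen one trait row; missing traits skip their rule with a notice."""
    flags: list[RuleFlag] = []
    skipped: list[str] = []

    def above(rule, name, limit):
        v = _value(traits, name)
        if v is None:
            skipped.append(rule)
        elif v > limit:
            flags.append(RuleFlag(rule, v, limit, "above_max"))

    above("sucrose_max", "sucrose", limits.sucrose_max)
    above("hmf_max", "hmf", limits.hmf_max)
    above("moisture_max", "moisture", limits.moisture_max)
    above("free_acidity_max", "free_acidity", limits.free_acidity_max)
    above("water_activity_spoilage", "water_activity", limits.water_activity_spoilage)

    g, f = _value(traits, "glucose"), _value(traits, "fructose")
    if g is None or f is None:
        skipped.append("glucose_fructose_min")
    elif g + f < limits.glucose_plus_fructose_min:
        flags.append(
            RuleFlag(
                "glucose_fructose_min", g + f,
                limits.glucose_plus_fructose_min, "below_min",
            )
        )
    if skipped:
        logger.info("sample %s: rules skipped for missing traits: %s",
                    sample_id or "<unnamed>", skipped)
    return RegulatoryFlags(sample_id=str(sample_id), flags=flags, skipped=skipped)


def screen_cohort(
    traits: pd.DataFrame, limits: RegulatoryLimits = RegulatoryLimits()
) -> ScreenSummary:
    """Screen every sample; counts equal the number flagged per rule."""
    if traits.empty:
        raise TraitValidationError("empty trait table")
    per_sample = [
        screen_sample(row, limits, sample_id=str(sid))
        for sid, row in traits.iterrows()
    ]
    flag_table = pd.DataFrame(
        [[rule in fl.rule_ids for rule in RULES] for fl in per_sample],
        index=traits.index,
        columns=list(RULES),
    )
    counts = {rule: int(flag_table[rule].sum()) for rule in RULES}
    return ScreenSummary(counts=counts, flag_table=flag_table, per_sample=per_sample)
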