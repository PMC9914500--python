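import numpy as np
import pandas as pd
import pytest

import honeyspec as hs

#: Reference-table averages for the nine traits (used by screen tests).
TABLE_AVERAGES = {
    "soluble_solids": 78.7,
    "pH": 4.02,
    "free_acidity": 27.9,
    "moisture": 15.8,
    "water_activity": 0.53,
    "glucose": 30.2,
    "fructose": 39.4,
    "sucrose": 2.1,
    "hmf": 34.6,
}


@pytest.fixture(scope="session")
def default_cohort() -> hs.LabeledCohort:
    """The default study cohort: 147 samples, 21 sucrose-adulterated."""
    return hs.generate_cohort(hs.CohortConfig())


@pytest.fixture(scope="session")
def small_cohort() -> hs.LabeledCohort:
    """A fast cohort for unit tests (40 samples, 8 adulterated)."""
    return hs.generate_cohort(
        hs.CohortConfig(n_samples=40, n_adulterated=8, seed=11)
    )


@pytest.fixture(scope="session")
def study_report(default_cohort) -> hs.StudyReport:
    """One full end-to-end run on the default cohort (shared across tests)."""
    cfg = hs.RunConfig()
    dataset = default_cohort.dataset
    screen = hs.screen_cohort(dataset.traits, cfg.limits)
    quant = hs.run_quantification(cfg, dataset)
    auth = hs.run_authentication(cfg, dataset)
    return hs.StudyReport(
        calibration_table=quant.calibration_table,
        simca_summary=auth.simca_summary,
        screen_summary={"counts": screen.counts},
        provenance=quant.provenance,
        discriminating_power=auth.discriminating_power,
        plsr_models=quant.plsr_models,
        simca_model=auth.simca_model,
    )


@pytest.fixture()
def average_trait_row() -> pd.Series:
    return pd.Series(TABLE_AVERAGES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230124)
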