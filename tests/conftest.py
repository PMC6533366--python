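import numpy as np
import pandas as pd
import pytest

from dietsurv.simulate import (CohortConfig, default_jm_truth,
                               separated_jlcmm_truth, simulate_cohort,
                               simulate_latent_class_cohort)


@pytest.fixture(scope="session")
def jm_truth():
    return default_jm_truth()


@pytest.fixture(scope="session")
def small_cohort(jm_truth):
    """A small joint-model cohort shared by fast tests."""
    cfg = CohortConfig(n_subjects=300, followup_max=6.0, seed=1234)
    return simulate_cohort(cfg, jm_truth)


@pytest.fixture(scope="session")
def lc_cohort():
    """A small, well-separated two-class cohort."""
    truth = separated_jlcmm_truth()
    cfg = CohortConfig(n_subjects=400, followup_max=15.0, seed=77)
    return simulate_latent_class_cohort(cfg, truth), truth


@pytest.fixture()
def toy_long():
    """Hand-sized longitudinal table: 3 subjects, 2 observations each."""
    return pd.DataFrame({
        "subject": [1, 1, 2, 2, 3, 3],
        "age_years": [0.5, 2.0, 1.0, 4.0, 0.25, 6.0],
        "food_g_day": [3.0, 10.0, 6.0, 25.0, 0.5, 40.0],
        "energy_mj_day": [2.2, 3.4, 2.8, 4.9, 2.0, 6.1],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20190523)
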