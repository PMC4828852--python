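import numpy as np
import pytest

from dse_ischemia import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 80-patient cohort with the default ischemic effect."""
    return simulate_cohort(CohortConfig(n_patients=80, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose labels are independent of every covariate."""
    return simulate_cohort(CohortConfig(n_patients=120, effect_size=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
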