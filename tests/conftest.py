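import numpy as np
import pytest

from aptwhabitat.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve small patients, shared across tests that only need plumbing."""
    cfg = CohortConfig(n_patients=12, seed=11, grid_shape=(20, 20, 14))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0]
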