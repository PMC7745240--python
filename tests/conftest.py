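import numpy as np
import pytest

from panss_traj import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """A deterministic 400-patient cohort with no noise-free shortcuts but no
    missingness, for tests that need complete follow-up."""
    cfg = CohortConfig(n_patients=400, dropout_rate=0.0, missing_rate=0.0, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A deterministic cohort with the default dropout/missingness structure."""
    cfg = CohortConfig(n_patients=600, seed=23)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
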