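import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free, artifact-free cohort shared across tests."""
    from escco import SyntheticCohortConfig, generate_cohort

    cfg = SyntheticCohortConfig(
        n_subjects=12,
        pairs_per_subject=4,
        pwtt_noise_sd=0.0,
        ico_noise_cv=0.0,
        pp_noise_sd=0.0,
        tamponade_prob=0.0,
        cpb_prob=0.0,
        r_wave_error_prob=0.0,
    )
    return generate_cohort(cfg, seed=7)
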