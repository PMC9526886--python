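import numpy as np
import pytest

from irsflow.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic cohort: no event noise, no debris, exact grades.

    Latent slopes and half-lives still vary between patients, so index
    values differ while every empirical GM equals its generative value.
    """
    config = CohortConfig(
        n_patients=8,
        events_per_sample=50,
        event_cv=0.0,
        debris_fraction=0.0,
        grade_noise=0.0,
        seed=11,
    )
    patients, samples = simulate_cohort(config)
    return config, patients, samples


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy cohort for fast pipeline-level tests."""
    config = CohortConfig(n_patients=10, events_per_sample=1500, seed=3)
    patients, samples = simulate_cohort(config)
    return config, patients, samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
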