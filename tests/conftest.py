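import numpy as np
import pytest

from eegleak.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects, 1 min each, clear fingerprints: fast shared fixture."""
    config = CohortConfig(
        n_subjects_per_group=5,
        n_channels=19,
        fs=250.0,
        duration=60.0,
        fingerprint_strength=1.0,
        disease_effect=0.0,
        noise_level=1.0,
        seed=42,
    )
    return config, generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
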