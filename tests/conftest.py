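import numpy as np
import pytest

from myopower.config import SimConfig
from myopower.cohort import sample_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(master_seed=11, n_subjects=12)


@pytest.fixture(scope="session")
def noise_free_config(default_config):
    return default_config.noise_free()


@pytest.fixture(scope="session")
def default_subject(default_config):
    """First subject of the default cohort (all corruption layers on)."""
    return sample_cohort(default_config)[0]


@pytest.fixture(scope="session")
def clean_subject(noise_free_config):
    return sample_cohort(noise_free_config)[0]


@pytest.fixture(scope="session")
def small_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def clean_cohort(noise_free_config):
    return simulate_cohort(noise_free_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
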