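import numpy as np
import pytest

from emg_swn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort: 3 subjects, 2 blocks of 10 trials, full trial timing."""
    return CohortConfig(n_subjects=3, n_trials=20, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_pre_cohort(tiny_config):
    """Same cohort with trials already taken to the 500 Hz preprocessed stage."""
    return generate_cohort(tiny_config, preprocess=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
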