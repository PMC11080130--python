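import warnings

import numpy as np
import pytest

from myoscreen import SimulationConfig, generate_dataset
from myoscreen.pipeline import extract_feature_table

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_healthy=3, n_sarcopenic=3, n_channels=2, trial_duration=4.0,
        mvc_duration=3.5, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def feature_table(small_dataset):
    return extract_feature_table(small_dataset)
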