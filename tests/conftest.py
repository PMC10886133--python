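import numpy as np
import pytest

from gaitfuse import SimulationConfig, make_dataset, preprocess_recording


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions: 5 cycles per class, 30 dB SNR."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One trial per class at the default conditions, seed 1."""
    return make_dataset(sim_config, seed=1)


@pytest.fixture(scope="session")
def prep_dataset(dataset):
    return [preprocess_recording(r) for r in dataset]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
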