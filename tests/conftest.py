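import numpy as np
import pytest

from afnet import ECGSynthConfig, generate_dataset
from afnet.nn import DenseNetConfig, RecurrentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return ECGSynthConfig(seed=7)


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """200 default records: the separability/sanity workhorse."""
    return generate_dataset(200, default_config)


@pytest.fixture
def tiny_synth_config():
    """Short, low-rate records for fast end-to-end tests."""
    return ECGSynthConfig(fs=120.0, duration_s=4.0, seed=11)


@pytest.fixture
def tiny_model_configs():
    """A minimal architecture that still exercises every stage."""
    return (
        DenseNetConfig(k0=4, k=3, num_blocks=1, layers_per_block=2, initial_kernel=3),
        RecurrentConfig(feature_len=8),
    )
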