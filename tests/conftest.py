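import numpy as np
import pytest

from stseize.model import EncoderConfig, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small encoder for fast unit tests; respects d_k = d_v = d_model/h."""
    return EncoderConfig(d_model=6, h=2, d_k=3, d_v=3, L=2, d_ff=8, mlp_hidden=5, seed=7)


@pytest.fixture
def fast_train_config():
    return TrainConfig(max_epochs=60, patience=10, batch_size=16)
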