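import numpy as np
import pytest

import psnsleep as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_encoder_config():
    return ps.tiny_config(seed=0)


@pytest.fixture
def micro_encoder_config():
    """Very small encoder (300-sample epochs, 8-d representation) for training-loop tests."""
    return ps.EncoderConfig(
        sampling_rate=10, epoch_seconds=30, small_kernel=5, large_kernel=40,
        branch_channels=(4,), conv_strides=(10,), pool_sizes=(3,),
        gru_hidden=8, representation_dim=8, seed=0)


@pytest.fixture
def small_subject():
    """One synthetic subject: 60 epochs at 100 Hz with strong stage continuity."""
    cfg = ps.SyntheticConfig(n_epochs=60, seed=11)
    return ps.generate_subject(cfg)


@pytest.fixture
def small_dataset():
    """Six short subjects for split/CV tests."""
    cfg = ps.SyntheticConfig(n_epochs=40, seed=5)
    return ps.generate_dataset(cfg, 6)
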