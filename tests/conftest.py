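import numpy as np
import pytest

from mastsym.network import StreamConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Small stream for fast tests; 64x64 inputs give a 2x2 feature map so
    every normalization group has more than one element."""
    return StreamConfig(
        block_strides=(1, 2, 2, 2, 2, 2),
        block_widths=(3, 4, 5, 6, 7, 8),
        se_reduction=2,
        input_shape=(64, 64),
    )


@pytest.fixture
def bench_cfg():
    return StreamConfig.benchmark()
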