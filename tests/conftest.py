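import numpy as np
import pytest

from hffen.attention import AttentionConfig
from hffen.blocks import HiemConfig
from hffen.network import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A small network configuration used across the structural tests."""
    return NetworkConfig(
        channels=8,
        n_modules=1,
        scale=2,
        backbone_blocks=1,
        hiem=HiemConfig(depth=1, bottleneck=2),
        ha=AttentionConfig(channels=8, heads=2, ca_reduction=4, spatial_window=8),
    )


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an ndarray."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
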