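import numpy as np
import pytest

from sparsedyn import LinearSystem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sparse_system(seed, n=50, k=6, weights=(0.0, 2.0, 0.0, 0.0, -1.0, 0.0), sigma=0.01):
    """Random Gaussian design with a known sparse signal."""
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((n, k))
    w = np.asarray(weights, dtype=float)
    g = phi @ w + sigma * rng.standard_normal(n)
    return LinearSystem(phi, g), w


@pytest.fixture
def sparse_system():
    return make_sparse_system(3)
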