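import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of scalar f at x (float64 internally)."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x.astype(np.float32))
        x[i] = orig - eps
        fm = f(x.astype(np.float32))
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def numgrad():
    return numerical_gradient


@pytest.fixture
def random_mask_pair(rng):
    """Factory of random binary mask pairs with both classes present."""

    def make(shape=(16, 16), p=0.4):
        while True:
            a = (rng.random(shape) < p).astype(int)
            b = (rng.random(shape) < p).astype(int)
            if 0 < b.sum() < b.size:
                return a, b

    return make
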