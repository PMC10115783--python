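import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_difference(f, x0, h=1e-6):
    """Central finite-difference gradient of scalar f at ndarray x0."""
    x0 = np.asarray(x0, dtype=np.float64)
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy()
        xm = x0.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g
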