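import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n=None, p=None, q=None, lams=(0.1, 1.0, 10.0)):
    """Small random two-level problem with mildly informative meta-features."""
    n = n or int(rng.integers(10, 51))
    p = p or int(rng.integers(2, 31))
    q = q or int(rng.integers(1, 11))
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((p, q))
    gamma = rng.standard_normal(q) * 0.5
    beta = Z @ gamma + 0.3 * rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n)
    l1 = float(rng.choice(lams))
    l2 = float(rng.choice(lams))
    return X, Z, y, l1, l2
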