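import numpy as np
import pytest

from fwec.data import DataMatrix, compute_precision


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n=None, m=None, k=None, n_max=30, m_max=5, k_max=3):
    """A random data matrix plus valid U, W, C, delta blocks."""
    n = n or int(rng.integers(4, n_max + 1))
    m = m or int(rng.integers(1, m_max + 1))
    k = k or int(rng.integers(1, min(k_max, n) + 1))
    X = rng.normal(scale=rng.uniform(0.5, 3.0), size=(n, m)) + rng.normal(size=m)
    data = DataMatrix(X)
    delta = compute_precision(data).delta
    U = rng.dirichlet(np.ones(k), size=n)
    W = rng.dirichlet(np.ones(m), size=k)
    C = X[rng.choice(n, size=k, replace=False)]
    return data, U, W, C, delta


@pytest.fixture
def small_instance(rng):
    return random_instance(rng, n=6, m=3, k=2)


@pytest.fixture
def blobs3():
    from fwec.synthetic import SyntheticSpec, make_blobs

    spec = SyntheticSpec(n_per_cluster=(40, 40, 40), m_informative=4, seed=7)
    return make_blobs(spec)
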