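import numpy as np
import pytest

from vbgrad import make_icosphere, toy_graphs


@pytest.fixture(scope="session")
def graphs():
    return toy_graphs()


@pytest.fixture(scope="session")
def icosphere2():
    return make_icosphere(2)


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_affinity(rng, n, density=1.0):
    """Random symmetric non-negative affinity with zero diagonal."""
    w = rng.uniform(0, 1, size=(n, n))
    if density < 1.0:
        w *= rng.uniform(0, 1, size=(n, n)) < density
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
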