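import numpy as np
import pytest

from trsopt.geno_io import MarkerMatrix
from trsopt.kinship import KinshipMatrix, center_markers, compute_G, recode_and_filter
from trsopt.simpop import SimParams, make_scenarios, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_kinship(n: int, m: int, rng: np.random.Generator, ridge: float = 0.05) -> KinshipMatrix:
    """A well-conditioned random PSD relationship matrix for oracle tests."""
    A = rng.normal(size=(n, m))
    G = A @ A.T / m + ridge * np.eye(n)
    ids = tuple(f"g{i}" for i in range(n))
    return KinshipMatrix((G + G.T) / 2.0, ids)


def marker_fixture(n: int, m: int, rng: np.random.Generator, inbred: bool = False) -> MarkerMatrix:
    """Random polymorphic raw marker calls."""
    p = rng.uniform(0.1, 0.9, size=m)
    if inbred:
        calls = 2.0 * (rng.random((n, m)) < p)
    else:
        calls = rng.binomial(2, p, size=(n, m)).astype(float)
    return MarkerMatrix(tuple(f"i{i}" for i in range(n)), tuple(f"m{j}" for j in range(m)), calls)


@pytest.fixture
def small_markers(rng):
    return marker_fixture(12, 40, rng)


@pytest.fixture
def small_G(small_markers):
    return compute_G(center_markers(recode_and_filter(small_markers)))


@pytest.fixture(scope="session")
def strong_pop():
    """The strongly structured preset panel (shared across structure tests)."""
    return simulate_panel(make_scenarios()["strong"])


@pytest.fixture(scope="session")
def mild_pop():
    return simulate_panel(make_scenarios()["mild"])
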