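import numpy as np
import pytest

from craniomorph.landmarks import SymmetryScheme
from craniomorph.synthetic import default_scheme, make_template


@pytest.fixture(scope="session")
def cranium_scheme() -> SymmetryScheme:
    return default_scheme("cranium")


@pytest.fixture(scope="session")
def mandible_scheme() -> SymmetryScheme:
    return default_scheme("mandible")


@pytest.fixture(scope="session")
def small_scheme() -> SymmetryScheme:
    """Tiny scheme (4 midline + 4 pairs, k=12) for simulation-heavy tests."""
    return SymmetryScheme(
        paired=[(4, 5), (6, 7), (8, 9), (10, 11)], midline=[0, 1, 2, 3]
    )


@pytest.fixture(scope="session")
def cranium_template(cranium_scheme):
    return make_template(cranium_scheme, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_configs(rng, n, k):
    """Well-spread random configurations for Procrustes tests."""
    base = rng.normal(scale=10.0, size=(k, 3))
    return base + rng.normal(scale=1.0, size=(n, k, 3))


def random_rotation(rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
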