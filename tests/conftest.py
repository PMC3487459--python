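import numpy as np
import pytest

from lfgscape import (
    FitnessTopography,
    GenotypeSpace,
    build_landscape,
)


@pytest.fixture(scope="session")
def space2():
    return GenotypeSpace(2)


@pytest.fixture(scope="session")
def space4():
    return GenotypeSpace(4)


@pytest.fixture(scope="session")
def smooth2(space2):
    """Two-locus landscape without LFGs, additive (s=0.05)."""
    return build_landscape(space2, 0.05, 1.0)


@pytest.fixture(scope="session")
def valley2(space2):
    """Two-locus reciprocal-sign-epistasis valley: both intermediates LFG."""
    return build_landscape(space2, 0.05, 1.0, FitnessTopography(2, frozenset({1, 2})))


@pytest.fixture(scope="session")
def smooth4(space4):
    """Four-locus additive landscape without LFGs."""
    return build_landscape(space4, 0.05, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simplex(rng, n, count=1):
    x = rng.dirichlet(np.ones(n), size=count)
    return x[0] if count == 1 else x
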