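import numpy as np
import pytest

from quantmat import TraitMatrix
from quantmat.synthetic import random_spd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spd_factory():
    """Factory for seeded random SPD TraitMatrices."""

    def make(p: int, seed: int, eigenvalues=None) -> TraitMatrix:
        return random_spd(p, seed, eigenvalues=eigenvalues)

    return make


@pytest.fixture
def corr_factory(spd_factory):
    """Factory for seeded random correlation TraitMatrices."""
    from quantmat import to_correlation

    def make(p: int, seed: int) -> TraitMatrix:
        return to_correlation(spd_factory(p, seed))

    return make
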