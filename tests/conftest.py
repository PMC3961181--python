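import numpy as np
import pytest

from scfc.core import Parcellation, StructuralConnectome
from scfc.synthetic import SyntheticConfig, make_sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_sc():
    """The 2-region toy connectome: a single unit-weight edge."""
    parc = Parcellation.canonical(2)
    weights = np.array([[0.0, 1.0], [1.0, 0.0]])
    lengths = np.array([[0.0, 60.0], [60.0, 0.0]])
    return StructuralConnectome(parcellation=parc, weights=weights, lengths=lengths)


@pytest.fixture
def small_sc():
    """A 20-region synthetic connectome with homotopic links."""
    return make_sc(SyntheticConfig(n_regions=20, seed=7))


@pytest.fixture
def medium_sc():
    """A 40-region synthetic connectome."""
    return make_sc(SyntheticConfig(n_regions=40, seed=11))
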