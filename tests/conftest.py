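import numpy as np
import pytest

from motifscaffold.contigs import parse_contigs, sample_placement
from motifscaffold.geometry import make_fixture
from motifscaffold.predictor import PlantedLandscape, ToyPredictor


@pytest.fixture(scope="session")
def helix15():
    return make_fixture("helix", 15, seed=1)


@pytest.fixture(scope="session")
def helix100():
    return make_fixture("helix", 100, seed=5)


@pytest.fixture(scope="session")
def world30():
    """Length-30 single-chain planted landscape (window radius 2)."""
    return PlantedLandscape.from_fixture("helix", 30, seed=7)


@pytest.fixture(scope="session")
def world16():
    """Small single-chain planted world for finite-difference checks."""
    return PlantedLandscape.from_fixture("helix", 16, seed=11)


@pytest.fixture(scope="session")
def world16_two_chain():
    return PlantedLandscape.from_fixture("two_chain_complex", 16, seed=13)


@pytest.fixture(scope="session")
def placement30():
    """Motif at design positions 12-17 of a 30-residue design."""
    return sample_placement(parse_contigs("12,A13-18,12"), seed=0)


@pytest.fixture(scope="session")
def toy30(world30):
    return ToyPredictor(world30)


def random_distribution(L: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(20), size=L)
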