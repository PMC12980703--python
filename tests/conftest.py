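import numpy as np
import pytest

from netperturb.ensembles import BeadEnsemble
from netperturb.networks import GO_LJ, Contact, InteractionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ensemble(rng):
    """12 beads, 50 frames of modest Gaussian jitter around a random fold."""
    base = rng.normal(0.0, 0.4, size=(12, 3))
    coords = base + rng.normal(0.0, 0.05, size=(50, 12, 3))
    return BeadEnsemble(coords=coords)


@pytest.fixture
def dimer_network():
    """Single LJ contact between two beads."""
    return InteractionNetwork(
        [Contact(0, 1, GO_LJ, strength=2.0, geometry=0.4)], n_beads=2, kind=GO_LJ
    )


@pytest.fixture(scope="session")
def toy_model():
    from netperturb.toysampler import make_toy_protein

    return make_toy_protein(20)
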