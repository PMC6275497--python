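import numpy as np
import pytest

from ribofold.fixtures import make_toy_protein, make_toy_system, make_toy_tunnel
from ribofold.model import build_go_system


@pytest.fixture(scope="session")
def hairpin():
    """16-residue beta-hairpin toy chain and its native contact map."""
    return make_toy_protein(16, "hairpin", seed=1)


@pytest.fixture(scope="session")
def hairpin_system(hairpin):
    beads, cmap = hairpin
    return build_go_system(beads, cmap)


@pytest.fixture(scope="session")
def helix_pair_system():
    """Calibrated two-state helix pair (rigid helices, flexible hinge)."""
    return make_toy_system(20, "helix-pair")


@pytest.fixture(scope="session")
def toy_tunnel():
    return make_toy_tunnel(length=6.0, radius=0.55, bead_spacing=0.22,
                           n_shells=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
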