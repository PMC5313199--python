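import numpy as np
import pytest

from replicadock.surface_selection import select_surface_atoms
from replicadock.toy_systems import make_harmonic_pair_system, make_sticky_receptor


@pytest.fixture(scope="session")
def toy():
    """Default sticky-shell docking system (certified)."""
    return make_sticky_receptor()


@pytest.fixture(scope="session")
def toy_groups(toy):
    return select_surface_atoms(toy.system)


@pytest.fixture(scope="session")
def toy_triangle():
    """Three-bead-ligand variant, exercising bonds and multi-atom RMSD."""
    return make_sticky_receptor(n_ligand_beads=3, certify=False)


@pytest.fixture(scope="session")
def harmonic_pair():
    return make_harmonic_pair_system()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
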