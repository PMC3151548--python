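import numpy as np
import pytest

from trajscope import synth
from trajscope.core import Atom, Structure


@pytest.fixture(scope="session")
def helix10():
    """10-residue compact helix with hand-countable side-chain contacts."""
    structure, truth = synth.gen_toy_structure(10, "helix", seed=7)
    return structure, truth


@pytest.fixture(scope="session")
def zigzag6():
    """6-residue 3-D zig-zag chain for elastic-network tests."""
    structure, _ = synth.gen_toy_structure(6, "zigzag", seed=3)
    return structure


@pytest.fixture()
def dimer():
    """Two alpha-carbons 3.8 A apart, sequence-adjacent."""
    atoms = [Atom(1, "CA", "ALA", 1, "A", (0.0, 0.0, 0.0)),
             Atom(2, "CA", "ALA", 2, "A", (3.8, 0.0, 0.0))]
    return Structure(atoms)


@pytest.fixture(scope="session")
def twowell_traj():
    """Two 5-state wells, slow inter-well exchange, 60k steps."""
    mtraj, truth = synth.gen_markov_traj(
        10, [0] * 5 + [1] * 5, intra_p=0.5, inter_p=0.002,
        n_steps=60_000, seed=11)
    return mtraj, truth


def make_structure(coords, resnames=None, segid="A", names=None):
    """Bare structure from an N x 3 array; one single-atom residue per row."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    resnames = resnames or ["ALA"] * n
    names = names or ["CA"] * n
    atoms = [Atom(i + 1, names[i], resnames[i], i + 1, segid, coords[i])
             for i in range(n)]
    return Structure(atoms)
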