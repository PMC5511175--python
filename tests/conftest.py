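import numpy as np
import pytest

from gpcrmsm.io_core import Atom, Topology, Trajectory
from gpcrmsm.msm import TransitionModel, stationary_distribution


def make_topology(n_residues: int, names=("N", "CA", "C", "O")):
    """Simple poly-residue topology: len(names) atoms per residue."""
    atoms = []
    idx = 1
    for r in range(1, n_residues + 1):
        for nm in names:
            elem = nm[0] if nm[0] in "HCNOSP" else "C"
            atoms.append(Atom(idx, nm, r, "ALA", "A", elem))
            idx += 1
    return Topology(atoms)


@pytest.fixture
def topo100():
    """100 residues x 4 backbone atoms."""
    return make_topology(100)


@pytest.fixture
def three_state_model():
    """Symmetric birth-death chain used for hand-derived TPT values."""
    T = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]])
    return TransitionModel(T, lag=1.0, pi=stationary_distribution(T))


@pytest.fixture
def two_state_model():
    T = np.array([[0.9, 0.1], [0.1, 0.9]])
    return TransitionModel(T, lag=1.0, pi=np.array([0.5, 0.5]))


def single_frame(topology, coords):
    return Trajectory(topology, np.asarray(coords, float)[None])
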