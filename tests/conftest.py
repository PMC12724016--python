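import numpy as np
import pytest

from allodyn import synthetic as syn
from allodyn import trajio


@pytest.fixture(scope="session")
def chain_system():
    """10-residue pseudo-Cα helix with side-chain pseudo-atoms."""
    top, ref = syn.make_chain_structure(10, 3.8)
    return top, ref


@pytest.fixture(scope="session")
def gaussian_traj(chain_system):
    """Seeded Gaussian ensemble with two planted correlations."""
    top, ref = chain_system
    spec = syn.CovarianceSpec(10, sigma=1.0, pairs=[(3, 7, 0.9), (2, 9, -0.7)])
    traj = syn.sample_gaussian_trajectory(top, ref, spec, 5000, seed=1)
    return top, traj, spec


@pytest.fixture(scope="session")
def toy_ion_pair():
    """+1/−1 two-particle complex at the distance giving −100 kcal/mol Coulomb."""
    return syn.make_toy_complex(1, 1, [1.0, -1.0], gap=3.320637, seed=0, n_frames=10)


@pytest.fixture()
def ca_selection(chain_system):
    top, _ = chain_system
    return trajio.select(top, "name CA")


def single_atom_topology(radius=1.9, charge=0.0):
    """Minimal one-atom parameterized topology for analytic checks."""
    return trajio.Topology(
        atom_names=np.array(["PT"], dtype=object),
        elements=np.array(["C"], dtype=object),
        resids=np.array([1]),
        resnames=np.array(["ION"], dtype=object),
        chain_ids=np.array(["A"], dtype=object),
        charges=np.array([charge]),
        lj_rmin_half=np.array([2.0]),
        lj_epsilon=np.array([0.1]),
        gb_radius=np.array([radius]),
        masses=np.array([12.011]),
    )


def particle_topology(n, charges=None, radius=1.7, chain="A"):
    """n independent single-atom residues with uniform parameters."""
    return trajio.Topology(
        atom_names=np.array(["PT"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["ION"] * n, dtype=object),
        chain_ids=np.array([chain] * n, dtype=object),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        lj_rmin_half=np.full(n, 2.0),
        lj_epsilon=np.full(n, 0.1),
        gb_radius=np.full(n, radius),
        masses=np.full(n, 12.011),
    )
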