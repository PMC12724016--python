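"""Synthetic trajectories and toy complexes with planted ground truth.

Every analysis stage in this package is validated against data whose
statistical structure is known by construction: Gaussian Cα ensembles with
planted residue-residue correlations, contact pairs with exact frame
occupancies, correlation chains forming a unique optimal network path, and
two-cluster charged/LJ complexes whose interaction energies have closed
forms.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import GeometryError, InputError
from .trajio import Topology, Trajectory, write_parameters, write_structure, write_trajectory

__all__ = [
    "CovarianceSpec",
    "PlantedSystem",
    "make_chain_structure",
    "make_grid_structure",
    "lattice_contacts",
    "sample_gaussian_trajectory",
    "plant_contact_pair",
    "plant_pathway",
    "make_toy_complex",
    "make_planted_lattice_system",
    "write_system",
]

#: Electric conversion constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

# default per-atom parameters for pseudo-residue systems
_DEFAULTS = dict(charge=0.0, lj_rmin_half=2.0, lj_epsilon=0.1, gb_radius=1.7, mass=12.011)


@dataclass
class CovarianceSpec:
    """Planted residue-residue correlation structure.

    ``pairs`` lists (res_i, res_j, rho) with 1-based residue ids and
    ``|rho| < 1``; ``sigma`` is the per-residue displacement amplitude in Å.
    The realized correlation matrix is the planted target when that target is
    already positive semidefinite; with ``ensure_psd`` the target is projected
    onto the PSD cone (eigenvalue clipping + diagonal renormalization, i.e. a
    factor model with loadings E·Λ^1/2) and the projection is the ground truth.
    """

    n_residues: int
    sigma: float | np.ndarray = 1.0
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    ensure_psd: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise InputError("n_residues must be >= 1")
        for i, j, rho in self.pairs:
            if i == j:
                raise InputError(f"planted pair ({i},{j}) is a self-pair")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise InputError(f"planted pair ({i},{j}) outside 1..{self.n_residues}")
            if not abs(rho) < 1:
                raise InputError(f"planted correlation rho={rho} must satisfy |rho| < 1")

    def sigmas(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.n_residues,))
        if np.any(s <= 0):
            raise InputError("sigma must be positive")
        return np.array(s)

    def target_matrix(self) -> np.ndarray:
        C = np.eye(self.n_residues)
        for i, j, rho in self.pairs:
            C[i - 1, j - 1] = C[j - 1, i - 1] = rho
        return C

    def correlation_matrix(self) -> np.ndarray:
        """Realized (guaranteed-PSD) model correlation matrix."""
        C = self.target_matrix()
        w = np.linalg.eigvalsh(C)
        if w[0] >= -1e-10:
            return C
        if not self.ensure_psd:
            raise InputError(
                f"planted correlation structure is not positive semidefinite "
                f"(min eigenvalue {w[0]:.3g}); set ensure_psd=True to project"
            )
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 1e-8, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        return C


@dataclass
class PlantedSystem:
    """A generated system plus the ground truth its analyses should recover."""

    topology: Topology
    trajectory: Trajectory
    ground_truth: dict
    seed: int


def _default_parameters(topology: Topology, charges: np.ndarray | None = None) -> Topology:
    from dataclasses import replace

    n = topology.n_atoms
    return replace(
        topology,
        charges=np.zeros(n) if charges is None else np.asarray(charges, dtype=float),
        lj_rmin_half=np.full(n, _DEFAULTS["lj_rmin_half"]),
        lj_epsilon=np.full(n, _DEFAULTS["lj_epsilon"]),
        gb_radius=np.full(n, _DEFAULTS["gb_radius"]),
        masses=np.full(n, _DEFAULTS["mass"]),
    )


def _pseudo_topology(ca_count: int, side_chains: bool, chain: str = "A") -> Topology:
    names, resids = [], []
    for r in range(1, ca_count + 1):
        names.append("CA")
        resids.append(r)
        if side_chains:
            names.append("CB")
            resids.append(r)
    n = len(names)
    top = Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.array(resids),
        resnames=np.array(["SYN"] * n, dtype=object),
        chain_ids=np.array([chain] * n, dtype=object),
    )
    return _default_parameters(top)


def make_chain_structure(
    n_residues: int, spacing: float = 3.8, *, side_chains: bool = True
) -> tuple[Topology, np.ndarray]:
    """Pseudo-Cα chain on a gentle helix with exact consecutive spacing.

    Each residue carries one optional charged side-chain pseudo-atom ("CB")
    1.5 Å radially outward from its Cα.  Deterministic (seed-free).
    """
    if n_residues < 2:
        raise InputError("n_residues must be >= 2")
    if spacing <= 0:
        raise InputError("spacing must be positive")
    radius, theta = 2.3, 0.6
    chord2 = 2 * radius**2 * (1 - np.cos(theta))
    if chord2 >= spacing**2:
        radius = spacing / 2.0  # keep the chord feasible for tiny spacings
        chord2 = 2 * radius**2 * (1 - np.cos(theta))
    rise = np.sqrt(spacing**2 - chord2)
    k = np.arange(n_residues)
    ca = np.column_stack([radius * np.cos(k * theta), radius * np.sin(k * theta), k * rise])
    coords = []
    for r in range(n_residues):
        coords.append(ca[r])
        if side_chains:
            out = np.array([np.cos(r * theta), np.sin(r * theta), 0.0])
            coords.append(ca[r] + 1.5 * out)
    return _pseudo_topology(n_residues, side_chains), np.array(coords)


def make_grid_structure(
    nx: int, ny: int, spacing: float = 3.8, *, side_chains: bool = False
) -> tuple[Topology, np.ndarray]:
    """Pseudo-Cα residues on a planar square lattice (row-major numbering).

    With the default 3.8 Å lattice constant, 4-neighbors are within a 4.5 Å
    contact cutoff while diagonals (5.37 Å) are not, so the contact graph of
    the static structure is exactly the 2-D lattice.
    """
    if nx < 1 or ny < 1 or nx * ny < 2:
        raise InputError("grid needs at least 2 residues")
    coords = []
    for j in range(ny):
        for i in range(nx):
            ca = np.array([i * spacing, j * spacing, 0.0])
            coords.append(ca)
            if side_chains:
                coords.append(ca + np.array([0.0, 0.0, 1.5]))
    return _pseudo_topology(nx * ny, side_chains), np.array(coords)


def lattice_contacts(nx: int, ny: int) -> list[tuple[int, int]]:
    """4-neighbor contact pairs (1-based, row-major) of an nx x ny lattice."""
    pairs = []
    for j in range(ny):
        for i in range(nx):
            node = j * nx + i + 1
            if i + 1 < nx:
                pairs.append((node, node + 1))
            if j + 1 < ny:
                pairs.append((node, node + nx))
    return pairs


def _shared_directions(spec: CovarianceSpec, rng: np.random.Generator) -> np.ndarray:
    """One fixed unit direction per residue; planted partners share theirs.

    Sharing the direction within each connected component of planted pairs
    makes the expected DCCM entry equal the planted scalar correlation (the
    displacement dot product reduces to the scalar covariance).
    """
    n = spec.n_residues
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in spec.pairs:
        parent[find(i - 1)] = find(j - 1)
    raw = rng.standard_normal((n, 3))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    return raw[[find(i) for i in range(n)]]


def sample_gaussian_trajectory(
    topology: Topology,
    reference: np.ndarray,
    spec: CovarianceSpec,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Stationary Gaussian ensemble around ``reference`` with planted DCCM.

    Residue *i* moves along a fixed unit direction e_i with scalar amplitude
    sigma_i * z_i(t); the z field is zero-mean Gaussian with the spec's
    correlation matrix (sampled through its Cholesky/eigen factor).  All atoms
    of a residue ride along rigidly.
    """
    if n_frames < 2:
        raise InputError("n_frames must be >= 2")
    if topology.n_residues != spec.n_residues:
        raise InputError(
            f"spec has {spec.n_residues} residues, topology has {topology.n_residues}"
        )
    rng = np.random.default_rng(seed)
    C = spec.correlation_matrix()
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        L = V * np.sqrt(np.clip(w, 0, None))
    directions = _shared_directions(spec, rng)
    z = rng.standard_normal((n_frames, spec.n_residues)) @ L.T
    amp = z * spec.sigmas()  # frames x residues
    coords = np.repeat(reference[None, :, :], n_frames, axis=0)
    disp = amp[:, topology.residue_index, None] * directions[topology.residue_index][None, :, :]
    coords += disp
    return Trajectory(coords, topology)


def plant_contact_pair(
    traj: Trajectory,
    res_i: int,
    res_j: int,
    occupancy: float,
    contact_distance: float = 3.0,
    apart_distance: float = 8.0,
    seed: int = 0,
) -> Trajectory:
    """Pin the side-chain pseudo-atoms of two residues at a chosen distance
    in exactly ``round(occupancy * n_frames)`` frames (seeded shuffle).

    Cα positions are untouched; only the two side-chain atoms move.
    """
    if not 0 <= occupancy <= 1:
        raise InputError("occupancy must be in [0, 1]")
    if contact_distance >= apart_distance:
        raise InputError("contact_distance must be smaller than apart_distance")
    top = traj.topology
    resids = top.residue_resids

    def _atoms(resid: int) -> tuple[int, int]:
        ordinals = np.flatnonzero(resids == resid)
        if ordinals.size == 0:
            raise InputError(f"residue {resid} not in topology")
        atoms = top.atoms_of_residue(ordinals[0])
        ca = [a for a in atoms if top.atom_names[a] == "CA"]
        cb = [a for a in atoms if top.atom_names[a] == "CB"]
        if not ca or not cb:
            raise InputError(f"residue {resid} lacks a side-chain pseudo-atom")
        return ca[0], cb[0]

    ca_i, cb_i = _atoms(res_i)
    ca_j, cb_j = _atoms(res_j)
    n = traj.n_frames
    n_contact = int(round(occupancy * n))
    rng = np.random.default_rng(seed)
    contact_frames = np.zeros(n, dtype=bool)
    contact_frames[rng.permutation(n)[:n_contact]] = True

    coords = traj.coords.copy()
    for f in range(n):
        a, b = coords[f, ca_i], coords[f, ca_j]
        axis = b - a
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-12 else np.array([1.0, 0.0, 0.0])
        mid = 0.5 * (a + b)
        d = contact_distance if contact_frames[f] else apart_distance
        coords[f, cb_i] = mid - 0.5 * d * axis
        coords[f, cb_j] = mid + 0.5 * d * axis
    return Trajectory(coords, top, traj.frame_indices.copy())


def plant_pathway(
    spec: CovarianceSpec,
    node_chain: list[int],
    rho_on: float,
    rho_off: float,
    contact_pairs: list[tuple[int, int]],
) -> CovarianceSpec:
    """Plant a uniquely optimal correlation chain on a contact graph.

    Consecutive chain pairs receive ``rho_on``; every other contact pair
    receives ``rho_off``.  Under edge weights W = −log|C| and permanent
    contacts, the minimum-weight path between the chain endpoints is the
    chain itself whenever ``|rho_on| > |rho_off|``.
    """
    if len(node_chain) < 2:
        raise InputError("node_chain must have at least 2 residues")
    if len(set(node_chain)) != len(node_chain):
        raise InputError("node_chain residues must be distinct")
    if abs(rho_on) <= abs(rho_off):
        warnings.warn(
            "planted path is not guaranteed unique: |rho_on| <= |rho_off|",
            UserWarning,
            stacklevel=2,
        )
    chain_edges = {frozenset(p) for p in zip(node_chain, node_chain[1:])}
    contact_set = {frozenset(p) for p in contact_pairs}
    missing = chain_edges - contact_set
    if missing:
        raise InputError(f"chain edges {sorted(map(tuple, missing))} are not contact pairs")
    pairs = []
    for edge in sorted(contact_set, key=lambda e: tuple(sorted(e))):
        i, j = sorted(edge)
        pairs.append((i, j, rho_on if edge in chain_edges else rho_off))
    return CovarianceSpec(spec.n_residues, spec.sigma, pairs, ensure_psd=True)


def _cluster_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Particles on a cubic grid (3.5 Å pitch) with small seeded jitter."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for idx in range(n):
        i, j, k = idx % side, (idx // side) % side, idx // side**2
        pts.append([3.5 * i, 3.5 * j, 3.5 * k])
    pts = np.array(pts, dtype=float)
    if n > 1:
        pts += rng.uniform(-0.25, 0.25, size=pts.shape)
    return pts


def _pairwise_energies(coords, charges, rmin_half, eps, idx_a, idx_b, eps_in=1.0):
    """Reference double-loop Coulomb + LJ cross energies (the analytic oracle)."""
    e_elec = 0.0
    e_vdw = 0.0
    for a in idx_a:
        for b in idx_b:
            r = float(np.linalg.norm(coords[a] - coords[b]))
            e_elec += COULOMB_CONSTANT * charges[a] * charges[b] / (eps_in * r)
            rmin = rmin_half[a] + rmin_half[b]
            e = np.sqrt(eps[a] * eps[b])
            e_vdw += e * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    return e_elec, e_vdw


def make_toy_complex(
    n_A: int,
    n_B: int,
    charge_pattern,
    lj_params: tuple[float, float] | tuple = (2.0, 0.1),
    gap: float = 5.0,
    seed: int = 0,
    *,
    n_frames: int = 1,
    jitter: float = 0.0,
) -> PlantedSystem:
    """Two rigid parameterized clusters separated by ``gap`` (minimum
    cross-cluster distance, Å) with analytic Coulomb/LJ ground truth.

    ``charge_pattern`` lists n_A+n_B charges (e); ``lj_params`` is either a
    scalar pair (rmin/2, epsilon) applied to all particles or two arrays.
    ``jitter > 0`` adds rigid-body displacements of cluster B in frames > 0.
    """
    if n_A < 1 or n_B < 1:
        raise InputError("both clusters need at least one particle")
    charges = np.asarray(charge_pattern, dtype=float)
    if charges.shape != (n_A + n_B,):
        raise InputError(f"charge_pattern must have length {n_A + n_B}")
    rmin_half, eps = lj_params
    rmin_half = np.broadcast_to(np.asarray(rmin_half, dtype=float), (n_A + n_B,)).copy()
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (n_A + n_B,)).copy()

    rng = np.random.default_rng(seed)
    pos_a = _cluster_positions(n_A, rng)
    pos_b = _cluster_positions(n_B, rng)
    # translate B along +x so the minimum cross-cluster distance equals gap
    best_t = None
    base = pos_a[:, 0].max() - pos_b[:, 0].min() + gap
    for a in pos_a:
        for b in pos_b:
            dyz2 = (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2
            if dyz2 <= gap**2:
                t = a[0] - b[0] + np.sqrt(gap**2 - dyz2)
                best_t = t if best_t is None else max(best_t, t)
    pos_b = pos_b + np.array([base if best_t is None else best_t, 0.0, 0.0])
    coords = np.vstack([pos_a, pos_b])

    from scipy.spatial.distance import pdist

    if n_A + n_B > 1 and pdist(coords).min() < 0.5:
        raise GeometryError("generated particles overlap (distance < 0.5 Å)")

    n = n_A + n_B
    top = Topology(
        atom_names=np.array(["PT"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["ION"] * n, dtype=object),
        chain_ids=np.array(["A"] * n_A + ["B"] * n_B, dtype=object),
    )
    from dataclasses import replace

    top = replace(
        top,
        charges=charges,
        lj_rmin_half=rmin_half,
        lj_epsilon=eps,
        gb_radius=np.full(n, _DEFAULTS["gb_radius"]),
        masses=np.full(n, _DEFAULTS["mass"]),
        named_selections={"partA": "chain A", "partB": "chain B"},
    )

    frames = [coords]
    for _ in range(1, n_frames):
        shift = rng.normal(0.0, jitter, size=3) if jitter > 0 else np.zeros(3)
        f = coords.copy()
        f[n_A:] += shift
        frames.append(f)
    traj = Trajectory(np.array(frames), top)

    idx_a, idx_b = np.arange(n_A), np.arange(n_A, n)
    e_elec, e_vdw = _pairwise_energies(coords, charges, rmin_half, eps, idx_a, idx_b)
    truth = {
        "coulomb_cross_energy": e_elec,
        "lj_cross_energy": e_vdw,
        "gap": gap,
        "n_A": n_A,
        "n_B": n_B,
    }
    return PlantedSystem(top, traj, truth, seed)


def make_planted_lattice_system(
    nx: int = 4,
    ny: int = 4,
    chain: list[int] | None = None,
    rho_on: float = 0.9,
    rho_off: float = 0.2,
    n_frames: int = 400,
    seed: int = 0,
    sigma: float = 0.4,
    *,
    planted: bool = True,
) -> PlantedSystem:
    """Lattice-geometry Gaussian system whose dynamic network contains (or,
    with ``planted=False``, lacks) a uniquely optimal correlation chain.

    The default chain runs from one lattice corner to the opposite one; with
    sigma = 0.4 Å lattice contacts persist in essentially every frame.
    """
    top, ref = make_grid_structure(nx, ny)
    contacts = lattice_contacts(nx, ny)
    if chain is None:
        chain = [1 + k * nx for k in range(ny)] + [ny * nx - nx + 2 + k for k in range(nx - 1)]
    spec = CovarianceSpec(nx * ny, sigma=sigma)
    if planted:
        spec = plant_pathway(spec, chain, rho_on, rho_off, contacts)
    traj = sample_gaussian_trajectory(top, ref, spec, n_frames, seed)
    truth = {
        "planted_path": list(chain) if planted else None,
        "planted_correlations": [[i, j, r] for i, j, r in spec.pairs],
        "contact_pairs": [list(p) for p in contacts],
        "rho_on": rho_on if planted else None,
        "rho_off": rho_off if planted else None,
        "source": chain[0],
        "sink": chain[-1],
    }
    return PlantedSystem(top, traj, truth, seed)


def write_system(system: PlantedSystem, outdir, name: str) -> dict[str, str]:
    """Serialize a planted system: PDB + DCD + parameter table + truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": str(outdir / f"{name}.pdb"),
        "dcd": str(outdir / f"{name}.dcd"),
        "parameters": str(outdir / f"{name}.params.csv"),
        "truth": str(outdir / f"{name}.truth.json"),
    }
    first = Trajectory(system.trajectory.coords[:1], system.topology)
    write_structure(first, paths["pdb"])
    write_trajectory(system.trajectory, paths["dcd"])
    write_parameters(system.topology, paths["parameters"])
    truth = dict(system.ground_truth, seed=system.seed)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
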