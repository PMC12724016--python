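"""Interface statistics: salt-bridge populations, distance series, and
solvent-accessible surface area of binding sites.

A salt bridge counts in a frame when the minimum distance between any basic
side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) and any acidic or
phosphate oxygen (Asp OD1/OD2; Glu OE1/OE2; phospho-Ser O1P/O2P/O3P/OG) is
within the cutoff (4.0 Å by default, the common N–O convention).  Synthetic
pseudo-residues participate through their charged side-chain pseudo-atom.

SASA uses the Shrake–Rupley rolling-probe quadrature: each atom's accessible
area is 4π(r+probe)² times the fraction of deterministic sphere points not
occluded by any neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InputError, ParameterError, SelectionError
from .trajio import Selection, Topology, Trajectory

__all__ = [
    "SaltBridgeRecord",
    "SasaSiteResult",
    "salt_bridge_population",
    "scan_interface_salt_bridges",
    "distance_series",
    "sphere_points",
    "compute_sasa",
    "site_sasa",
    "percent_change",
]

BASIC_SIDECHAIN_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "HSD": ("ND1", "NE2"),
    "HSE": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SEP": ("O1P", "O2P", "O3P", "OG"),
    "PSER": ("O1P", "O2P", "O3P", "OG"),
}
#: atom-group override selecting the backbone carbonyl (e.g. E322 main chain)
MAIN_CHAIN_OXYGEN = ("O",)
_PSEUDO_SIDECHAIN = ("CB",)


@dataclass
class SaltBridgeRecord:
    """Population of one basic/acidic residue pair over a trajectory."""

    basic_residue: int
    acidic_residue: int
    basic_atoms: tuple[str, ...]
    acidic_atoms: tuple[str, ...]
    population: float
    bridge_class: str | None = None  # "initial" or "newly_formed"
    per_replica: list[float] | None = None
    label: str = ""


@dataclass
class SasaSiteResult:
    """Summed SASA (Å²) of a named residue site, per frame."""

    site_name: str
    residues: list[int]
    per_frame: np.ndarray
    per_replica_means: list[float] | None = None

    @property
    def mean(self) -> float:
        return float(self.per_frame.mean())

    @property
    def sd(self) -> float:
        return float(self.per_frame.std(ddof=1)) if len(self.per_frame) > 1 else 0.0


def _residue_ordinal(top: Topology, resid: int, chain: str | None = None) -> int:
    hits = [
        k
        for k in range(top.n_residues)
        if top.residue_resids[k] == resid and (chain is None or top.residue_chains[k] == chain)
    ]
    if not hits:
        raise SelectionError(f"residue {resid}{'/' + chain if chain else ''} not in topology")
    return hits[0]


def _group_atoms(top: Topology, ordinal: int, names: tuple[str, ...]) -> np.ndarray:
    atoms = top.atoms_of_residue(ordinal)
    sel = [a for a in atoms if str(top.atom_names[a]) in names]
    return np.array(sel, dtype=np.int64)


def _charged_group(top: Topology, ordinal: int, kind: str, override) -> np.ndarray:
    """Atom group carrying the charged moiety of a residue.

    ``override`` may be a tuple of atom names (e.g. MAIN_CHAIN_OXYGEN).
    """
    resname = str(top.residue_names[ordinal]).upper()
    if override is not None:
        names = tuple(override)
    elif resname in (BASIC_SIDECHAIN_ATOMS if kind == "basic" else ACIDIC_SIDECHAIN_ATOMS):
        table = BASIC_SIDECHAIN_ATOMS if kind == "basic" else ACIDIC_SIDECHAIN_ATOMS
        names = table[resname]
    elif resname in ("SYN", "ION"):
        names = _PSEUDO_SIDECHAIN if resname == "SYN" else ("PT",)
    else:
        raise ParameterError(
            f"residue {top.residue_label(ordinal)} has no recognized {kind} atom group; "
            "pass an atom-name override"
        )
    atoms = _group_atoms(top, ordinal, names)
    if atoms.size == 0:
        raise ParameterError(
            f"residue {top.residue_label(ordinal)} lacks expected atoms {names}"
        )
    return atoms


def _min_distance_series(traj: Trajectory, atoms_a: np.ndarray, atoms_b: np.ndarray) -> np.ndarray:
    a = traj.coords[:, atoms_a, :]
    b = traj.coords[:, atoms_b, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).reshape(traj.n_frames, -1).min(axis=1)


def salt_bridge_population(
    traj: Trajectory,
    basic_residue: int,
    acidic_residue: int,
    cutoff: float = 4.0,
    *,
    basic_atoms: tuple[str, ...] | None = None,
    acidic_atoms: tuple[str, ...] | None = None,
    starting_frame: np.ndarray | int | None = None,
) -> SaltBridgeRecord:
    """Fraction of frames with the basic-N/acidic-O minimum distance <= cutoff.

    ``starting_frame`` (frame coordinates or index) classifies the bridge as
    present in the designated starting structure ("initial") or formed later
    ("newly_formed").
    """
    top = traj.topology
    ka = _residue_ordinal(top, basic_residue)
    kb = _residue_ordinal(top, acidic_residue)
    ga = _charged_group(top, ka, "basic", basic_atoms)
    gb = _charged_group(top, kb, "acidic", acidic_atoms)
    dmin = _min_distance_series(traj, ga, gb)
    population = float(np.mean(dmin <= cutoff))
    bridge_class = None
    if starting_frame is not None:
        ref = (
            traj.coords[int(starting_frame)]
            if isinstance(starting_frame, (int, np.integer))
            else np.asarray(starting_frame, dtype=float)
        )
        d0 = cdist(ref[ga], ref[gb]).min()
        bridge_class = "initial" if d0 <= cutoff else "newly_formed"
    return SaltBridgeRecord(
        basic_residue=basic_residue,
        acidic_residue=acidic_residue,
        basic_atoms=tuple(str(top.atom_names[a]) for a in ga),
        acidic_atoms=tuple(str(top.atom_names[a]) for a in gb),
        population=population,
        bridge_class=bridge_class,
        label=f"{top.residue_label(ka)}-{top.residue_label(kb)}",
    )


def _charged_residues(top: Topology, selection: Selection) -> tuple[list[int], list[int]]:
    """Ordinals of basic and acidic residues inside a selection.

    Standard residues classify by name; pseudo-residues by the sign of their
    side-chain pseudo-atom charge (requires charges to be loaded).
    """
    basic, acidic = [], []
    for ordinal in selection.residue_indices:
        resname = str(top.residue_names[ordinal]).upper()
        if resname in BASIC_SIDECHAIN_ATOMS:
            basic.append(int(ordinal))
        elif resname in ACIDIC_SIDECHAIN_ATOMS:
            acidic.append(int(ordinal))
        elif resname in ("SYN", "ION") and top.charges is not None:
            names = _PSEUDO_SIDECHAIN if resname == "SYN" else ("PT",)
            atoms = _group_atoms(top, int(ordinal), names)
            if atoms.size:
                q = top.charges[atoms].sum()
                if q > 0.25:
                    basic.append(int(ordinal))
                elif q < -0.25:
                    acidic.append(int(ordinal))
    return basic, acidic


def scan_interface_salt_bridges(
    traj: Trajectory,
    selection_A: Selection,
    selection_B: Selection,
    cutoff: float = 4.0,
    min_population: float = 0.0,
    starting_frame: np.ndarray | int | None = 0,
) -> list[SaltBridgeRecord]:
    """Evaluate every basic-acidic cross pair between two disjoint selections."""
    if np.intersect1d(selection_A.atom_indices, selection_B.atom_indices).size:
        raise InputError("interface selections overlap")
    top = traj.topology
    basic_a, acidic_a = _charged_residues(top, selection_A)
    basic_b, acidic_b = _charged_residues(top, selection_B)
    records = []
    for basics, acidics in ((basic_a, acidic_b), (basic_b, acidic_a)):
        for kb in basics:
            for ka in acidics:
                rec = salt_bridge_population(
                    traj,
                    int(top.residue_resids[kb]),
                    int(top.residue_resids[ka]),
                    cutoff,
                    starting_frame=starting_frame,
                )
                if rec.population >= min_population:
                    records.append(rec)
    records.sort(key=lambda r: (-r.population, r.basic_residue, r.acidic_residue))
    return records


def distance_series(
    traj: Trajectory,
    group_A: Selection | np.ndarray,
    group_B: Selection | np.ndarray,
    mode: str = "min",
) -> np.ndarray:
    """Per-frame distance between two atom groups (Å).

    ``mode="min"`` is the minimum inter-atomic distance; ``mode="centroid"``
    uses the geometric centers.
    """
    ga = group_A.atom_indices if isinstance(group_A, Selection) else np.asarray(group_A)
    gb = group_B.atom_indices if isinstance(group_B, Selection) else np.asarray(group_B)
    if ga.size == 0 or gb.size == 0:
        raise SelectionError("distance groups must be non-empty")
    if mode == "min":
        return _min_distance_series(traj, ga, gb)
    if mode == "centroid":
        ca = traj.coords[:, ga, :].mean(axis=1)
        cb = traj.coords[:, gb, :].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=1)
    raise InputError(f"unknown distance mode {mode!r}")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    frame: np.ndarray,
    topology: Topology,
    selection: Selection | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley per-atom SASA (Å²) for one frame.

    Occlusion is tested against the other atoms of the selection (all atoms
    when ``selection`` is None).  Radii come from the topology's ``gb_radius``
    column (Bondi-type radii in the parameter table).
    """
    if n_sphere_points < 100:
        raise InputError("n_sphere_points must be >= 100")
    if topology.gb_radius is None:
        raise ParameterError("SASA needs per-atom radii; load a parameter table")
    idx = (
        selection.atom_indices if selection is not None else np.arange(topology.n_atoms)
    )
    xyz = np.asarray(frame, dtype=float)[idx]
    radii = topology.gb_radius[idx] + probe
    if np.any(radii <= 0):
        raise ParameterError("non-positive atom radius encountered")
    unit = sphere_points(n_sphere_points)
    n = len(idx)
    areas = np.zeros(n)
    d = cdist(xyz, xyz)
    for a in range(n):
        neighbors = np.flatnonzero((d[a] < radii[a] + radii) & (np.arange(n) != a))
        pts = xyz[a] + radii[a] * unit
        if neighbors.size:
            dn = cdist(pts, xyz[neighbors])
            accessible = np.all(dn >= radii[neighbors], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[a] = 4.0 * np.pi * radii[a] ** 2 * frac
    return areas


def site_sasa(
    traj: Trajectory,
    topology: Topology,
    site_residues: list[int],
    probe: float = 1.4,
    n_sphere_points: int = 960,
    stride: int = 1,
    site_name: str = "site",
) -> SasaSiteResult:
    """Per-frame summed SASA of a residue site, occluded by the whole molecule."""
    ordinals = [_residue_ordinal(topology, r) for r in site_residues]
    site_atoms = np.concatenate([topology.atoms_of_residue(k) for k in ordinals])
    mask = np.isin(np.arange(topology.n_atoms), site_atoms)
    frames = range(0, traj.n_frames, max(1, stride))
    values = []
    for f in frames:
        per_atom = compute_sasa(traj.coords[f], topology, None, probe, n_sphere_points)
        values.append(per_atom[mask].sum())
    return SasaSiteResult(site_name, list(site_residues), np.array(values))


def percent_change(result_system: SasaSiteResult | float, result_reference: SasaSiteResult | float) -> float:
    """Signed percent change of a mean vs a reference mean: 100·(x−ref)/ref."""
    x = result_system.mean if isinstance(result_system, SasaSiteResult) else float(result_system)
    ref = (
        result_reference.mean
        if isinstance(result_reference, SasaSiteResult)
        else float(result_reference)
    )
    if ref == 0:
        raise InputError("reference mean is zero; percent change undefined")
    return 100.0 * (x - ref) / ref
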