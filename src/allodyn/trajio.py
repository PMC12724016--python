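"""Structures, parameters, trajectories, selections, and superposition.

File formats (PDB, DCD, PSF) are read and written through MDAnalysis; the
in-memory model is a pair of light containers, :class:`Topology` (per-atom
identities and force-field parameters) and :class:`Trajectory` (a dense
``frames x atoms x 3`` coordinate array in Å).  Residue numbering is 1-based
and taken verbatim from the input file, so labels like K14 or R144 in the
AKT numbering survive every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    AlignmentError,
    DegenerateFitError,
    EmptyInputError,
    FormatError,
    InputError,
    ParameterError,
    SelectionError,
)

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "read_structure",
    "read_parameters",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "superpose",
    "rmsd",
    "rmsd_series",
    "concatenate",
]

PARAMETER_FIELDS = ("charges", "lj_rmin_half", "lj_epsilon", "gb_radius", "masses")


@dataclass
class Topology:
    """Per-atom identities plus optional energy parameters.

    Parameter arrays (charge in e, LJ rmin/2 and GB radius in Å, epsilon in
    kcal/mol, mass in amu) may be ``None`` when no energy stage is requested.
    ``named_selections`` maps a group name (e.g. ``"PH"``, ``"VL1"``) to a
    selection expression usable via ``group NAME``.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    charges: np.ndarray | None = None
    lj_rmin_half: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    gb_radius: np.ndarray | None = None
    masses: np.ndarray | None = None
    named_selections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        n = self.n_atoms
        for name in PARAMETER_FIELDS:
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != (n,):
                    raise AlignmentError(
                        f"parameter array {name!r} has length {arr.shape}, expected {n}"
                    )
                setattr(self, name, arr)
        # Residue table: order of first appearance of (chain, resid).
        keys = list(zip(self.chain_ids, self.resids))
        seen: dict[tuple, int] = {}
        per_atom = np.empty(n, dtype=np.int64)
        for i, key in enumerate(keys):
            if key not in seen:
                seen[key] = len(seen)
            per_atom[i] = seen[key]
        self._residue_index = per_atom
        self._residue_keys = list(seen)
        # strictly increasing resids within each chain
        for chain in dict.fromkeys(self.chain_ids):
            r = [rid for cid, rid in seen if cid == chain]
            if any(b <= a for a, b in zip(r, r[1:])):
                raise FormatError(f"residue indices not strictly increasing in chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self._residue_keys)

    @property
    def residue_index(self) -> np.ndarray:
        """0-based residue ordinal for each atom."""
        return self._residue_index

    @property
    def residue_resids(self) -> np.ndarray:
        """1-based author resid for each residue ordinal."""
        return np.array([rid for _, rid in self._residue_keys], dtype=np.int64)

    @property
    def residue_chains(self) -> np.ndarray:
        return np.array([cid for cid, _ in self._residue_keys], dtype=object)

    @property
    def residue_names(self) -> np.ndarray:
        first = np.zeros(self.n_residues, dtype=np.int64)
        for i in range(self.n_atoms - 1, -1, -1):
            first[self._residue_index[i]] = i
        return self.resnames[first]

    def atoms_of_residue(self, ordinal: int) -> np.ndarray:
        return np.flatnonzero(self._residue_index == ordinal)

    def residue_label(self, ordinal: int) -> str:
        name = self.residue_names[ordinal]
        one = _THREE_TO_ONE.get(str(name).upper(), "")
        return f"{one or name}{self.residue_resids[ordinal]}"

    def has_parameters(self, *names: str) -> bool:
        names = names or PARAMETER_FIELDS
        return all(getattr(self, f) is not None for f in names)

    def require_parameters(self, *names: str) -> None:
        missing = [f for f in (names or PARAMETER_FIELDS) if getattr(self, f) is None]
        if missing:
            raise ParameterError(
                f"energy stage requires per-atom parameters {missing}; "
                "load them with read_parameters()"
            )

    def heavy_atom_mask(self) -> np.ndarray:
        elems = np.array([str(e).upper() for e in self.elements])
        return elems != "H"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H", "HSE": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "SER": "S",
    "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V", "SEP": "S", "PSER": "S",
}


@dataclass
class Trajectory:
    """Cartesian coordinates (Å), ``frames x atoms x 3``, bound to a Topology."""

    coords: np.ndarray
    topology: Topology
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coordinate array has shape {self.coords.shape}, expected (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("trajectory has no frames")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise AlignmentError(
                f"trajectory has {self.coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("trajectory contains non-finite coordinates")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.coords.shape[0])
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset_frames(self, idx) -> "Trajectory":
        idx = np.asarray(idx)
        return Trajectory(self.coords[idx], self.topology, self.frame_indices[idx])

    def last_half(self) -> "Trajectory":
        """Frames with index >= floor(n/2) — the analysis window used throughout."""
        return self.subset_frames(np.arange(self.n_frames // 2, self.n_frames))


@dataclass(frozen=True)
class Selection:
    """Sorted, duplicate-free atom indices plus the induced residue ordinals."""

    atom_indices: np.ndarray
    residue_indices: np.ndarray
    expression: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)


# ---------------------------------------------------------------------------
# selection expressions
# ---------------------------------------------------------------------------

_KEYWORDS = {"name", "resid", "resname", "chain", "element", "group", "all", "and", "or", "not"}


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    """Recursive-descent parser for the small selection language.

    Supported: ``all``, ``name CA CB``, ``resid 5-60 70``, ``resname LYS``,
    ``chain A``, ``element C``, ``group NAME``, combined with ``and``, ``or``,
    ``not`` and parentheses.
    """

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() == "and":
            self.take()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.parse_not()
        if self.peek() == "(":
            self.take()
            mask = self.parse_or()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.parse_primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in {"and", "or", "not", ")"}:
            vals.append(self.take())
        if not vals:
            raise SelectionError("selection keyword given without values")
        return vals

    def parse_primitive(self) -> np.ndarray:
        tok = self.take()
        top = self.top
        if tok == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if tok == "name":
            vals = set(self._values())
            return np.array([str(a) in vals for a in top.atom_names])
        if tok == "resname":
            vals = set(v.upper() for v in self._values())
            return np.array([str(r).upper() in vals for r in top.resnames])
        if tok == "chain":
            vals = set(self._values())
            return np.array([str(c) in vals for c in top.chain_ids])
        if tok == "element":
            vals = set(v.upper() for v in self._values())
            return np.array([str(e).upper() in vals for e in top.elements])
        if tok == "resid":
            wanted = np.zeros(top.n_atoms, dtype=bool)
            known = set(int(r) for r in top.resids)
            for val in self._values():
                if "-" in val[1:]:  # allow negative single values
                    lo_s, hi_s = val[1:].split("-", 1)
                    lo, hi = int(val[0] + lo_s), int(hi_s)
                    if not any(lo <= r <= hi for r in known):
                        raise SelectionError(f"resid range {val!r} matches no residue")
                    wanted |= (top.resids >= lo) & (top.resids <= hi)
                else:
                    rid = int(val)
                    if rid not in known:
                        raise SelectionError(f"resid {rid} not present in topology")
                    wanted |= top.resids == rid
            return wanted
        if tok == "group":
            name = self.take()
            if name not in top.named_selections:
                raise SelectionError(f"unknown named group {name!r}")
            return _SelParser(_tokenize(top.named_selections[name]), top).parse()
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to a deterministic, sorted atom set.

    Raises :class:`SelectionError` for unknown keywords/residues/names and for
    empty results.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    res = np.unique(topology.residue_index[idx])
    return Selection(idx, res, expression)


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis
    return MDAnalysis


def _guess_element(name: str) -> str:
    name = name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path) -> tuple[Topology, Trajectory]:
    """Read a PDB file; every MODEL becomes one trajectory frame.

    Alternate locations are resolved to the highest-occupancy, first-listed
    conformer per atom.
    """
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (EmptyInputError, MemoryError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        if "no atoms" in str(exc).lower() or isinstance(exc, IndexError):
            raise EmptyInputError(f"{path}: no atoms found") from exc
        raise FormatError(f"{path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyInputError(f"{path}: no atoms found")

    atoms = u.atoms
    keep = np.arange(len(atoms))
    if hasattr(atoms, "altLocs"):
        alt = np.array([a or "" for a in atoms.altLocs], dtype=object)
        if np.any(alt != ""):
            occ = (
                np.asarray(atoms.occupancies, dtype=float)
                if hasattr(atoms, "occupancies")
                else np.ones(len(atoms))
            )
            best: dict[tuple, int] = {}
            for i in range(len(atoms)):
                key = (atoms.segids[i] if hasattr(atoms, "segids") else "",
                       atoms.resids[i], atoms.names[i])
                j = best.get(key)
                if j is None or occ[i] > occ[j]:
                    best[key] = i
            keep = np.array(sorted(best.values()))
    ag = atoms[keep]

    n = len(ag)
    try:
        elements = np.array([str(e).upper() or _guess_element(nm)
                             for e, nm in zip(ag.elements, ag.names)], dtype=object)
    except Exception:  # noqa: BLE001 - PDBs without element column
        elements = np.array([_guess_element(nm) for nm in ag.names], dtype=object)
    chain_ids = (
        np.array([c or "A" for c in ag.chainIDs], dtype=object)
        if hasattr(ag, "chainIDs")
        else np.array([s or "A" for s in ag.segids], dtype=object)
    )
    top = Topology(
        atom_names=np.array(ag.names, dtype=object),
        elements=elements,
        resids=np.array(ag.resids, dtype=np.int64),
        resnames=np.array(ag.resnames, dtype=object),
        chain_ids=chain_ids,
    )
    frames = np.empty((len(u.trajectory), n, 3))
    for f, _ in enumerate(u.trajectory):
        frames[f] = ag.positions
    return top, Trajectory(frames, top)


def read_parameters(path, topology: Topology, *, required: bool = False) -> Topology:
    """Attach per-atom parameters from a PSF (charges/masses) or a table.

    The table format is whitespace- or comma-separated with the columns
    ``atom_index charge lj_rmin_half lj_epsilon gb_radius mass`` (1-based
    atom_index, matching file order).  Returns a new Topology.
    """
    import pandas as pd

    path = str(path)
    if path.endswith(".psf"):
        mda = _mda()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"{path}: {exc}") from exc
        if len(u.atoms) != topology.n_atoms:
            raise AlignmentError(
                f"PSF has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
            )
        out = replace(topology, charges=np.asarray(u.atoms.charges, dtype=float),
                      masses=np.asarray(u.atoms.masses, dtype=float))
        if required:
            out.require_parameters()
        return out

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: {exc}") from exc
    if "atom_index" not in df.columns:
        raise FormatError(f"{path}: parameter table must carry an 'atom_index' column")
    if len(df) != topology.n_atoms:
        raise AlignmentError(
            f"parameter table has {len(df)} rows, topology has {topology.n_atoms} atoms"
        )
    df = df.sort_values("atom_index")
    if not np.array_equal(df["atom_index"].to_numpy(), np.arange(1, topology.n_atoms + 1)):
        raise AlignmentError("atom_index column must be 1..n_atoms")
    cols = {"charge": "charges", "lj_rmin_half": "lj_rmin_half",
            "lj_epsilon": "lj_epsilon", "gb_radius": "gb_radius", "mass": "masses"}
    values = {}
    for col, fieldname in cols.items():
        if col in df.columns:
            values[fieldname] = df[col].to_numpy(dtype=float)
    out = replace(topology, **values)
    if required:
        out.require_parameters()
    return out


def write_parameters(topology: Topology, path) -> None:
    import pandas as pd

    topology.require_parameters()
    pd.DataFrame(
        {
            "atom_index": np.arange(1, topology.n_atoms + 1),
            "charge": topology.charges,
            "lj_rmin_half": topology.lj_rmin_half,
            "lj_epsilon": topology.lj_epsilon,
            "gb_radius": topology.gb_radius,
            "mass": topology.masses,
        }
    ).to_csv(path, index=False)


def _empty_universe(topology: Topology):
    mda = _mda()
    n_res = topology.n_residues
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        n_segments=len(dict.fromkeys(topology.chain_ids)),
        atom_resindex=topology.residue_index,
        residue_segindex=[
            list(dict.fromkeys(topology.chain_ids)).index(c) for c in topology.residue_chains
        ],
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(map(str, topology.atom_names)))
    u.add_TopologyAttr("elements", list(map(str, topology.elements)))
    u.add_TopologyAttr("resids", topology.residue_resids)
    u.add_TopologyAttr("resnames", list(map(str, topology.residue_names)))
    u.add_TopologyAttr("segids", list(dict.fromkeys(map(str, topology.chain_ids))))
    u.add_TopologyAttr("chainIDs", list(map(str, topology.chain_ids)))
    return u


def write_structure(traj: Trajectory, path) -> None:
    """Write a (possibly multi-model) PDB."""
    mda = _mda()
    u = _empty_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=traj.n_frames > 1) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a CHARMM/NAMD-style 32-bit DCD."""
    mda = _mda()
    u = _empty_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read a DCD (or multi-model PDB fallback) against an existing topology."""
    path = str(path)
    if path.endswith(".pdb"):
        top2, traj = read_structure(path)
        if top2.n_atoms != topology.n_atoms:
            raise AlignmentError(
                f"{path}: trajectory has {top2.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        return Trajectory(traj.coords, topology)
    from MDAnalysis.coordinates.DCD import DCDReader

    try:
        reader = DCDReader(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: {exc}") from exc
    if reader.n_atoms != topology.n_atoms:
        reader.close()
        raise AlignmentError(
            f"{path}: trajectory has {reader.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    frames = []
    try:
        for ts in reader:
            frames.append(ts.positions.astype(np.float64).copy())
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: truncated after {len(frames)} frames: {exc}") from exc
    finally:
        reader.close()
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    return Trajectory(np.array(frames), topology)


def concatenate(trajs: list[Trajectory]) -> Trajectory:
    """Join replica trajectories frame-wise (topologies must match in size)."""
    if not trajs:
        raise InputError("no trajectories to concatenate")
    n = trajs[0].n_atoms
    if any(t.n_atoms != n for t in trajs):
        raise AlignmentError("trajectories have differing atom counts")
    return Trajectory(np.concatenate([t.coords for t in trajs], axis=0), trajs[0].topology)


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation/translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t)`` with ``x @ R.T + t`` the fitted coordinates.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def _resolve_reference(traj: Trajectory, reference_frame) -> np.ndarray:
    if isinstance(reference_frame, (int, np.integer)):
        return traj.coords[int(reference_frame)]
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise AlignmentError("reference frame shape does not match trajectory")
    return ref


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def superpose(traj: Trajectory, reference_frame, fit_selection: Selection) -> Trajectory:
    """Rigid-body fit of every frame onto the reference over ``fit_selection``.

    Internal geometry of each frame is untouched (pure rotation+translation).
    """
    ref = _resolve_reference(traj, reference_frame)
    idx = fit_selection.atom_indices
    _check_fit_atoms(ref[idx])
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f][idx], ref[idx])
        out[f] = traj.coords[f] @ R.T + t
    return Trajectory(out, traj.topology, traj.frame_indices.copy())


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    reference_frame,
    selection: Selection,
    *,
    superpose_first: bool = False,
) -> np.ndarray:
    """Per-frame RMSD (Å) of ``selection`` against the reference."""
    if selection.n_atoms == 0:
        raise SelectionError("empty selection for RMSD")
    if superpose_first:
        traj = superpose(traj, reference_frame, selection)
    ref = _resolve_reference(traj, reference_frame)[selection.atom_indices]
    diff = traj.coords[:, selection.atom_indices, :] - ref
    return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
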