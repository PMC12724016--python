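"""MM/GBSA binding free energy with per-residue decomposition.

The binding free energy between two parts of one molecule is estimated with
the single-trajectory end-state protocol:

    ΔG_b = ΔE_MM + ΔG_sol − TΔS
    ΔE_MM = ΔE_inter + ΔE_elec + ΔE_vdW          (ΔE_inter = 0 exactly here)
    ΔG_sol = ΔG_sol^elec + ΔG_sol^nonpolar
    ΔG_sol^nonpolar = γ·SASA + β                  (γ = 0.00542, β = 0.92)

Polar solvation uses the generalized Born model with OBC-II effective radii
(pairwise descreening, tanh rescaling with α=1.0, β=0.8, γ=4.85); the
entropy term comes from normal-mode analysis of an explicit energy model and
is available for toy systems whose full potential is known.

Energies are kcal/mol, lengths Å, charges elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    CapabilityError,
    ClashError,
    InputError,
    NumericalError,
    ParameterError,
)
from .interface import compute_sasa
from .trajio import Selection, Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyOptions",
    "EnergyDecomposition",
    "ToyEnergyModel",
    "mm_cross_energy",
    "born_radii",
    "gb_polar_energy",
    "nonpolar_solvation",
    "harmonic_entropy",
    "binding_free_energy",
    "per_residue_decomposition",
]

#: kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637
_HALF_COULOMB = COULOMB_CONSTANT / 2.0  # 166.03185
#: hc/k_B in cm·K, converts wavenumbers to vibrational temperatures
_C2 = 1.4387768775039337
#: gas constant, kcal/(mol·K)
_R = 1.987204259e-3
#: (kcal/mol/Å²/amu) -> s⁻² for mass-weighted Hessian eigenvalues
_OMEGA2 = 4.184e26
_C_CM = 2.99792458e10  # speed of light, cm/s


@dataclass
class EnergyOptions:
    """Dielectrics, surface-tension constants, GB variant, and snapshot counts."""

    eps_in: float = 1.0
    eps_out: float = 78.5
    gamma: float = 0.00542  # kcal/(mol·Å²)
    beta: float = 0.92  # kcal/mol
    temperature: float = 310.0  # K
    n_energy_snapshots: int = 2500
    n_entropy_snapshots: int = 50
    entropy: bool = False
    salt_kappa: float = 0.0  # optional Debye–Hückel screening, 1/Å
    sasa_probe: float = 1.4
    sasa_points: int = 960
    gb_variant: str = "OBC-II"
    gb_alpha: float = 1.0
    gb_beta: float = 0.8
    gb_gamma: float = 4.85
    gb_offset: float = 0.09
    gb_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise InputError("dielectric constants must be positive")
        if self.n_energy_snapshots < 1 or (self.entropy and self.n_entropy_snapshots < 1):
            raise InputError("snapshot counts must be >= 1 for enabled terms")


@dataclass
class EnergyDecomposition:
    """Term-wise and per-residue breakdown of ΔG_b.

    ``terms`` holds one per-snapshot array per energy term; ``minus_t_delta_s``
    is the averaged −TΔS (0 when entropy is disabled).
    """

    snapshot_indices: np.ndarray
    terms: dict[str, np.ndarray]
    minus_t_delta_s: float = 0.0
    per_residue: dict[int, float] | None = None
    significant: list[int] | None = None
    options: EnergyOptions | None = None
    replica_values: list[float] = field(default_factory=list)

    @property
    def term_means(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.terms.items()}

    @property
    def delta_e_mm(self) -> float:
        m = self.term_means
        return m["dE_inter"] + m["dE_elec"] + m["dE_vdW"]

    @property
    def delta_g_sol(self) -> float:
        m = self.term_means
        return m["dG_sol_elec"] + m["dG_sol_nonpolar"]

    @property
    def delta_g_per_snapshot(self) -> np.ndarray:
        return sum(self.terms[k] for k in
                   ("dE_inter", "dE_elec", "dE_vdW", "dG_sol_elec", "dG_sol_nonpolar")) \
            + self.minus_t_delta_s

    @property
    def delta_g(self) -> float:
        return self.delta_e_mm + self.delta_g_sol + self.minus_t_delta_s


def _indices(part) -> np.ndarray:
    return part.atom_indices if isinstance(part, Selection) else np.asarray(part, dtype=np.int64)


def _mm_pair_matrices(frame, topology, idx_a, idx_b, eps_in):
    topology.require_parameters("charges", "lj_rmin_half", "lj_epsilon")
    xa, xb = frame[idx_a], frame[idx_b]
    r = cdist(xa, xb)
    if r.min() < 0.1:
        a, b = np.unravel_index(np.argmin(r), r.shape)
        raise ClashError(
            f"atoms {int(idx_a[a])} and {int(idx_b[b])} are {r[a, b]:.3f} Å apart"
        )
    q = topology.charges
    elec = COULOMB_CONSTANT * np.outer(q[idx_a], q[idx_b]) / (eps_in * r)
    rmin = topology.lj_rmin_half[idx_a][:, None] + topology.lj_rmin_half[idx_b][None, :]
    eps = np.sqrt(np.outer(topology.lj_epsilon[idx_a], topology.lj_epsilon[idx_b]))
    sr6 = (rmin / r) ** 6
    vdw = eps * (sr6**2 - 2 * sr6)
    return elec, vdw


def mm_cross_energy(
    frame: np.ndarray,
    topology: Topology,
    part_A,
    part_B,
    eps_in: float = 1.0,
) -> tuple[float, float]:
    """Gas-phase cross-part Coulomb and Lennard-Jones energies (no cutoff).

    CHARMM-style combining: r_min,ij = r_min,i/2 + r_min,j/2 and
    ε_ij = sqrt(ε_i ε_j); E_vdW = ε_ij[(r_min/r)¹² − 2(r_min/r)⁶].
    """
    idx_a, idx_b = _indices(part_A), _indices(part_B)
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("parts A and B share atoms")
    elec, vdw = _mm_pair_matrices(np.asarray(frame, float), topology, idx_a, idx_b, eps_in)
    return float(elec.sum()), float(vdw.sum())


def born_radii(
    coords: np.ndarray,
    radii: np.ndarray,
    *,
    scale: float = 0.8,
    offset: float = 0.09,
    alpha: float = 1.0,
    beta: float = 0.8,
    gamma: float = 4.85,
) -> np.ndarray:
    """Effective Born radii by OBC pairwise descreening with tanh rescaling.

    An isolated atom's Born radius reduces to its intrinsic radius minus the
    dielectric offset.
    """
    coords = np.asarray(coords, float)
    rho = np.asarray(radii, float) - offset
    if np.any(rho <= 0):
        raise ParameterError("intrinsic GB radius must exceed the dielectric offset")
    n = len(rho)
    r = cdist(coords, coords)
    s = scale * rho
    integral = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            rij = r[i, j]
            sj = s[j]
            if rho[i] >= rij + sj:  # neighbor fully engulfed, no descreening
                continue
            L = max(abs(rij - sj), rho[i])
            U = rij + sj
            acc += 0.5 * (
                1.0 / L
                - 1.0 / U
                + 0.25 * (rij - sj**2 / rij) * (1.0 / U**2 - 1.0 / L**2)
                + 0.5 * np.log(L / U) / rij
            )
        integral[i] = acc
    psi = integral * rho
    inv_b = 1.0 / rho - np.tanh(alpha * psi - beta * psi**2 + gamma * psi**3) / np.asarray(
        radii, float
    )
    if np.any(inv_b <= 0):
        bad = int(np.flatnonzero(inv_b <= 0)[0])
        raise NumericalError(f"non-positive effective Born radius for atom {bad}")
    return 1.0 / inv_b


def gb_polar_energy(
    frame: np.ndarray,
    topology: Topology,
    selection=None,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
    *,
    options: EnergyOptions | None = None,
    return_per_atom: bool = False,
):
    """Polar solvation free energy of a species by the generalized Born model.

    G_pol = −(332.0637/2)·(1/ε_in − 1/ε_out)·Σ_ij q_i q_j / f_GB with
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); self terms included.
    Born radii are computed for the species alone (recomputed per species in
    binding calculations).
    """
    opts = options or EnergyOptions(eps_in=eps_in, eps_out=eps_out)
    topology.require_parameters("charges", "gb_radius")
    idx = _indices(selection) if selection is not None else np.arange(topology.n_atoms)
    xyz = np.asarray(frame, float)[idx]
    q = topology.charges[idx]
    B = born_radii(
        xyz,
        topology.gb_radius[idx],
        scale=opts.gb_scale,
        offset=opts.gb_offset,
        alpha=opts.gb_alpha,
        beta=opts.gb_beta,
        gamma=opts.gb_gamma,
    )
    r2 = cdist(xyz, xyz) ** 2
    bb = np.outer(B, B)
    f = np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))
    if opts.salt_kappa > 0:
        tau = 1.0 / opts.eps_in - np.exp(-opts.salt_kappa * f) / opts.eps_out
    else:
        tau = 1.0 / opts.eps_in - 1.0 / opts.eps_out
    pair = -_HALF_COULOMB * tau * np.outer(q, q) / f
    per_atom = pair.sum(axis=1)
    total = float(per_atom.sum())
    if return_per_atom:
        return total, per_atom
    return total


def nonpolar_solvation(sasa_total: float, gamma: float = 0.00542, beta: float = 0.92) -> float:
    """Nonpolar solvation free energy: γ·SASA + β (kcal/mol)."""
    if sasa_total < 0:
        raise InputError("SASA must be non-negative")
    return gamma * sasa_total + beta


# ---------------------------------------------------------------------------
# toy energy model + normal-mode entropy
# ---------------------------------------------------------------------------


class ToyEnergyModel:
    """Coulomb + Lennard-Jones + harmonic-bond potential for toy systems.

    Bonds are (i, j, k, r0) with V = ½k(r−r0)²; k in kcal/mol/Å².  Provides
    the analytic gradient needed for minimization and normal-mode analysis.
    """

    def __init__(self, topology: Topology, bonds=None, eps_in: float = 1.0,
                 atom_indices=None):
        topology.require_parameters("charges", "lj_rmin_half", "lj_epsilon", "masses")
        self.top = topology
        idx = np.arange(topology.n_atoms) if atom_indices is None else np.asarray(atom_indices)
        self.idx = idx
        self.charges = topology.charges[idx]
        self.rmin_half = topology.lj_rmin_half[idx]
        self.eps = topology.lj_epsilon[idx]
        self.masses = topology.masses[idx]
        self.eps_in = eps_in
        pos = {int(a): k for k, a in enumerate(idx)}
        self.bonds = []
        for i, j, k, r0 in bonds or []:
            if int(i) in pos and int(j) in pos:
                self.bonds.append((pos[int(i)], pos[int(j)], float(k), float(r0)))

    @property
    def n_atoms(self) -> int:
        return len(self.idx)

    def subset(self, atom_indices) -> "ToyEnergyModel":
        bonds = [(int(self.idx[i]), int(self.idx[j]), k, r0) for i, j, k, r0 in self.bonds]
        return ToyEnergyModel(self.top, bonds, self.eps_in, atom_indices)

    def _nonbonded(self, x: np.ndarray):
        n = self.n_atoms
        e = 0.0
        g = np.zeros_like(x)
        bonded = {(i, j) for i, j, _, _ in self.bonds} | {(j, i) for i, j, _, _ in self.bonds}
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                dv = x[i] - x[j]
                r = np.linalg.norm(dv)
                qq = COULOMB_CONSTANT * self.charges[i] * self.charges[j] / self.eps_in
                e += qq / r
                dedr = -qq / r**2
                rmin = self.rmin_half[i] + self.rmin_half[j]
                epsij = np.sqrt(self.eps[i] * self.eps[j])
                sr6 = (rmin / r) ** 6
                e += epsij * (sr6**2 - 2 * sr6)
                dedr += epsij * 12.0 * (sr6 - sr6**2) / r
                g[i] += dedr * dv / r
                g[j] -= dedr * dv / r
        return e, g

    def _bonded(self, x: np.ndarray):
        e = 0.0
        g = np.zeros_like(x)
        for i, j, k, r0 in self.bonds:
            dv = x[i] - x[j]
            r = np.linalg.norm(dv)
            e += 0.5 * k * (r - r0) ** 2
            dedr = k * (r - r0)
            g[i] += dedr * dv / r
            g[j] -= dedr * dv / r
        return e, g

    def energy(self, coords: np.ndarray) -> float:
        x = np.asarray(coords, float).reshape(self.n_atoms, 3)
        return self._nonbonded(x)[0] + self._bonded(x)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, float).reshape(self.n_atoms, 3)
        return (self._nonbonded(x)[1] + self._bonded(x)[1]).ravel()


def vibrational_entropy(frequencies_cm1: np.ndarray, temperature: float) -> float:
    """Harmonic-oscillator vibrational entropy (kcal/mol/K) summed over modes."""
    nu = np.asarray(frequencies_cm1, float)
    x = _C2 * nu / temperature
    return float(_R * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def _rigid_body_basis(x: np.ndarray, masses: np.ndarray) -> np.ndarray:
    n = len(masses)
    sqm = np.sqrt(masses)
    vecs = []
    for d in range(3):
        v = np.zeros((n, 3))
        v[:, d] = sqm
        vecs.append(v.ravel())
    com = (masses[:, None] * x).sum(axis=0) / masses.sum()
    rel = x - com
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        v = np.cross(np.broadcast_to(axis, (n, 3)), rel) * sqm[:, None]
        vecs.append(v.ravel())
    basis = []
    for v in vecs:
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.array(basis).T  # 3n x n_rigid


def harmonic_entropy(
    structure: np.ndarray,
    energy_model: ToyEnergyModel,
    temperature: float = 310.0,
    *,
    minimize: bool = True,
    hessian_step: float = 1e-4,
    imaginary_tolerance_cm1: float = 5.0,
) -> dict:
    """Normal-mode vibrational entropy of one species.

    The structure is locally minimized to gradient norm < 1e-6, the
    mass-weighted Hessian is built by central differences of the analytic
    gradient, rigid-body modes are projected out, and each vibrational mode
    contributes standard harmonic-oscillator entropy.  Imaginary frequencies
    above ~5 cm⁻¹ after minimization raise an error.
    """
    x = np.asarray(structure, float).reshape(energy_model.n_atoms, 3).copy()
    if minimize and np.linalg.norm(energy_model.gradient(x)) > 1e-6:
        from scipy.optimize import minimize as _min

        res = _min(
            lambda v: energy_model.energy(v),
            x.ravel(),
            jac=lambda v: energy_model.gradient(v),
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": 10000},
        )
        x = res.x.reshape(-1, 3)
        if np.linalg.norm(energy_model.gradient(x)) > 1e-6:
            raise NumericalError("minimization did not reach gradient norm < 1e-6")

    n3 = 3 * energy_model.n_atoms
    H = np.empty((n3, n3))
    flat = x.ravel()
    for k in range(n3):
        plus = flat.copy()
        minus = flat.copy()
        plus[k] += hessian_step
        minus[k] -= hessian_step
        H[:, k] = (energy_model.gradient(plus) - energy_model.gradient(minus)) / (
            2 * hessian_step
        )
    H = 0.5 * (H + H.T)
    sqm = np.sqrt(np.repeat(energy_model.masses, 3))
    Hmw = H / np.outer(sqm, sqm)
    V = _rigid_body_basis(x, energy_model.masses)
    P = np.eye(n3) - V @ V.T
    Hp = P @ Hmw @ P
    lam = np.linalg.eigvalsh(Hp)
    nu = np.sign(lam) * np.sqrt(np.abs(lam) * _OMEGA2) / (2 * np.pi * _C_CM)
    if np.any(nu < -imaginary_tolerance_cm1):
        raise NumericalError(
            f"imaginary frequency {nu.min():.2f} cm⁻¹ after minimization; not a minimum"
        )
    vib = nu[nu > imaginary_tolerance_cm1]
    S = vibrational_entropy(vib, temperature)
    return {
        "frequencies_cm1": vib,
        "entropy": S,
        "minus_TS": -temperature * S,
        "minimized_coords": x,
    }


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------


def _snapshot_indices(n_frames: int, count: int) -> np.ndarray:
    """Evenly spaced snapshots from the latter half of the trajectory."""
    start = n_frames // 2
    return np.unique(np.linspace(start, n_frames - 1, min(count, n_frames - start)).astype(int))


def _species_sasa(frame, topology, idx, probe, n_points):
    sub_sel = Selection(np.sort(idx), np.unique(topology.residue_index[idx]))
    return compute_sasa(frame, topology, sub_sel, probe, n_points)


def binding_free_energy(
    traj: Trajectory,
    topology: Topology,
    part_A,
    part_B,
    options: EnergyOptions | None = None,
    energy_model: ToyEnergyModel | None = None,
) -> EnergyDecomposition:
    """Single-trajectory MM/GBSA binding free energy between two parts.

    Part geometries are cut from complex snapshots, so the internal bonded
    term ΔE_inter is exactly zero.  Gas-phase and solvation terms average over
    evenly spaced snapshots from the latter half of the trajectory; −TΔS (when
    enabled) over its own smaller snapshot subset.
    """
    opts = options or EnergyOptions()
    idx_a, idx_b = np.sort(_indices(part_A)), np.sort(_indices(part_B))
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("parts A and B overlap")
    if opts.entropy and energy_model is None:
        raise CapabilityError(
            "entropy requested but no energy model supplies the full potential; "
            "disable entropy or provide a ToyEnergyModel"
        )
    idx_c = np.sort(np.concatenate([idx_a, idx_b]))
    snaps = _snapshot_indices(traj.n_frames, opts.n_energy_snapshots)
    terms = {k: np.zeros(len(snaps)) for k in
             ("dE_inter", "dE_elec", "dE_vdW", "dG_sol_elec", "dG_sol_nonpolar")}
    for s, f in enumerate(snaps):
        frame = traj.coords[f]
        e_elec, e_vdw = mm_cross_energy(frame, topology, idx_a, idx_b, opts.eps_in)
        gp_c = gb_polar_energy(frame, topology, idx_c, options=opts)
        gp_a = gb_polar_energy(frame, topology, idx_a, options=opts)
        gp_b = gb_polar_energy(frame, topology, idx_b, options=opts)
        sasa_c = _species_sasa(frame, topology, idx_c, opts.sasa_probe, opts.sasa_points).sum()
        sasa_a = _species_sasa(frame, topology, idx_a, opts.sasa_probe, opts.sasa_points).sum()
        sasa_b = _species_sasa(frame, topology, idx_b, opts.sasa_probe, opts.sasa_points).sum()
        terms["dE_elec"][s] = e_elec
        terms["dE_vdW"][s] = e_vdw
        terms["dG_sol_elec"][s] = gp_c - gp_a - gp_b
        terms["dG_sol_nonpolar"][s] = (
            nonpolar_solvation(sasa_c, opts.gamma, opts.beta)
            - nonpolar_solvation(sasa_a, opts.gamma, opts.beta)
            - nonpolar_solvation(sasa_b, opts.gamma, opts.beta)
        )
    minus_t_delta_s = 0.0
    if opts.entropy:
        esnaps = _snapshot_indices(traj.n_frames, opts.n_entropy_snapshots)
        model_c = energy_model.subset(idx_c) if energy_model.n_atoms != len(idx_c) else energy_model
        model_a = energy_model.subset(idx_a)
        model_b = energy_model.subset(idx_b)
        pos_c = {int(a): k for k, a in enumerate(idx_c)}
        vals = []
        for f in esnaps:
            frame = traj.coords[f]
            sc = harmonic_entropy(frame[idx_c], model_c, opts.temperature)["entropy"]
            sa = harmonic_entropy(frame[idx_a], model_a, opts.temperature)["entropy"]
            sb = harmonic_entropy(frame[idx_b], model_b, opts.temperature)["entropy"]
            vals.append(-opts.temperature * (sc - sa - sb))
        minus_t_delta_s = float(np.mean(vals))
        del pos_c
    return EnergyDecomposition(snaps, terms, minus_t_delta_s, options=opts)


def per_residue_decomposition(
    traj: Trajectory,
    topology: Topology,
    part_A,
    part_B,
    options: EnergyOptions | None = None,
    threshold: float = -1.0,
) -> EnergyDecomposition:
    """Per-residue share of the enthalpic binding terms.

    Cross-pair gas-phase terms split half to each side's atom; polar solvation
    uses each atom's GB contribution change; nonpolar uses γ·ΔSASA per atom.
    The global β intercept and the entropy term are not decomposed.  Residues
    below ``threshold`` kcal/mol form the significant set.
    """
    opts = options or EnergyOptions()
    idx_a, idx_b = np.sort(_indices(part_A)), np.sort(_indices(part_B))
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("parts A and B overlap")
    idx_c = np.sort(np.concatenate([idx_a, idx_b]))
    pos_c = {int(a): k for k, a in enumerate(idx_c)}
    snaps = _snapshot_indices(traj.n_frames, opts.n_energy_snapshots)
    per_atom_total = np.zeros(len(idx_c))
    terms = {k: np.zeros(len(snaps)) for k in
             ("dE_inter", "dE_elec", "dE_vdW", "dG_sol_elec", "dG_sol_nonpolar")}
    for s, f in enumerate(snaps):
        frame = traj.coords[f]
        elec, vdw = _mm_pair_matrices(frame, topology, idx_a, idx_b, opts.eps_in)
        contrib = np.zeros(len(idx_c))
        half = 0.5 * (elec + vdw)
        for k, a in enumerate(idx_a):
            contrib[pos_c[int(a)]] += half[k, :].sum()
        for k, b in enumerate(idx_b):
            contrib[pos_c[int(b)]] += half[:, k].sum()
        gp_c, pa_c = gb_polar_energy(frame, topology, idx_c, options=opts, return_per_atom=True)
        gp_a, pa_a = gb_polar_energy(frame, topology, idx_a, options=opts, return_per_atom=True)
        gp_b, pa_b = gb_polar_energy(frame, topology, idx_b, options=opts, return_per_atom=True)
        dpol = pa_c.copy()
        for k, a in enumerate(idx_a):
            dpol[pos_c[int(a)]] -= pa_a[k]
        for k, b in enumerate(idx_b):
            dpol[pos_c[int(b)]] -= pa_b[k]
        contrib += dpol
        s_c = _species_sasa(frame, topology, idx_c, opts.sasa_probe, opts.sasa_points)
        s_a = _species_sasa(frame, topology, idx_a, opts.sasa_probe, opts.sasa_points)
        s_b = _species_sasa(frame, topology, idx_b, opts.sasa_probe, opts.sasa_points)
        dsasa = s_c.copy()
        for k, a in enumerate(idx_a):
            dsasa[pos_c[int(a)]] -= s_a[k]
        for k, b in enumerate(idx_b):
            dsasa[pos_c[int(b)]] -= s_b[k]
        contrib += opts.gamma * dsasa
        per_atom_total += contrib
        terms["dE_elec"][s] = elec.sum()
        terms["dE_vdW"][s] = vdw.sum()
        terms["dG_sol_elec"][s] = gp_c - gp_a - gp_b
        terms["dG_sol_nonpolar"][s] = opts.gamma * (s_c.sum() - s_a.sum() - s_b.sum()) - opts.beta
    per_atom_total /= len(snaps)
    per_residue: dict[int, float] = {}
    for k, a in enumerate(idx_c):
        resid = int(topology.resids[a])
        per_residue[resid] = per_residue.get(resid, 0.0) + float(per_atom_total[k])
    significant = sorted(r for r, v in per_residue.items() if v < threshold)
    return EnergyDecomposition(
        snaps, terms, 0.0, per_residue=per_residue, significant=significant, options=opts
    )
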