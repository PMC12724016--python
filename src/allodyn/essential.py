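"""Essential dynamics: PCA of Cα fluctuations and cross-correlation matrices.

The covariance is built from atomic fluctuations around the *mean* structure
of the (already superposed) trajectory; the reference frame is used only for
the superposition itself.  Eigenvalues carry the variance of each principal
component in Å²; DCCM entries are the normalized dot-product correlations

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),   C_ij in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, ConfigError, InputError, NumericalError
from .trajio import Selection, Trajectory, superpose

__all__ = [
    "PCAResult",
    "CorrelationMatrix",
    "compute_pca",
    "pc_loadings",
    "project",
    "compute_dccm",
    "bin_correlations",
    "average_dccm",
]


@dataclass
class PCAResult:
    """Eigendecomposition of the 3N Cartesian covariance of a selection."""

    mean: np.ndarray  # selection atoms x 3, Å
    eigenvalues: np.ndarray  # Å², descending, clipped at 0
    eigenvectors: np.ndarray  # 3N x n_components, orthonormal columns
    projections: np.ndarray  # frames x n_components, centered
    atom_indices: np.ndarray
    residue_indices: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else np.zeros_like(self.eigenvalues)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class CorrelationMatrix:
    """Residue-residue dynamic cross-correlation matrix (unit diagonal)."""

    residue_indices: np.ndarray  # 0-based residue ordinals
    residue_resids: np.ndarray  # 1-based author resids, for labeling
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise AlignmentError("correlation matrix must be square")
        if np.max(np.abs(m - m.T)) > 1e-10:
            raise NumericalError("correlation matrix must be symmetric")
        if np.max(np.abs(m)) > 1 + 1e-12:
            raise NumericalError("correlation entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


def _fluctuations(traj: Trajectory, selection: Selection) -> tuple[np.ndarray, np.ndarray]:
    x = traj.coords[:, selection.atom_indices, :]
    mean = x.mean(axis=0)
    return x - mean, mean


def compute_pca(
    traj: Trajectory,
    selection: Selection,
    reference_frame=None,
    *,
    superpose_first: bool = False,
) -> PCAResult:
    """PCA of the Cartesian fluctuations of ``selection``.

    With ``superpose_first`` the trajectory is first rigid-body aligned to
    ``reference_frame`` on the same selection; otherwise frames are assumed
    already superposed.  Components are sorted by descending eigenvalue and
    per-frame projections are centered.
    """
    if traj.n_frames < 2:
        raise InputError("PCA needs at least 2 frames")
    if superpose_first:
        traj = superpose(traj, 0 if reference_frame is None else reference_frame, selection)
    dx, mean = _fluctuations(traj, selection)
    n3 = 3 * selection.n_atoms
    if traj.n_frames <= n3:
        warnings.warn(
            f"PCA with {traj.n_frames} frames for {n3} degrees of freedom; "
            "eigenvalues will be noisy",
            UserWarning,
            stacklevel=2,
        )
    flat = dx.reshape(traj.n_frames, n3)
    cov = flat.T @ flat / traj.n_frames
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    proj = flat @ v
    proj -= proj.mean(axis=0)
    return PCAResult(
        mean=mean,
        eigenvalues=w,
        eigenvectors=v,
        projections=proj,
        atom_indices=selection.atom_indices.copy(),
        residue_indices=selection.residue_indices.copy(),
    )


def pc_loadings(pca: PCAResult, component_k: int = 1) -> np.ndarray:
    """Per-atom contribution profile of component k (1-based).

    Each value is the Euclidean norm of that atom's 3-vector inside the
    (unit-norm) eigenvector, so the squared profile sums to 1.  For Cα-only
    selections this is the per-residue contribution.
    """
    if not 1 <= component_k <= pca.n_components:
        raise IndexError(f"component {component_k} out of range 1..{pca.n_components}")
    vec = pca.eigenvectors[:, component_k - 1].reshape(-1, 3)
    return np.linalg.norm(vec, axis=1)


def project(traj: Trajectory, pca: PCAResult, components: tuple[int, ...] = (1, 2)) -> np.ndarray:
    """Project frames onto selected components (1-based), preserving order."""
    if traj.n_atoms <= pca.atom_indices.max():
        raise AlignmentError("trajectory does not contain the PCA selection atoms")
    cols = np.asarray(components, dtype=int) - 1
    if cols.min() < 0 or cols.max() >= pca.n_components:
        raise IndexError(f"components {components} out of range 1..{pca.n_components}")
    dx = traj.coords[:, pca.atom_indices, :] - pca.mean
    flat = dx.reshape(traj.n_frames, -1)
    return flat @ pca.eigenvectors[:, cols]


def compute_dccm(traj: Trajectory, selection: Selection) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the residues of ``selection``.

    One position vector per residue (the selection must hold one anchor atom,
    normally the Cα, per residue).  A residue whose fluctuation vanishes is an
    error — it indicates broken superposition or a frozen coordinate.
    """
    if traj.n_frames < 2:
        raise InputError("DCCM needs at least 2 frames")
    top = traj.topology
    if selection.n_atoms != selection.n_residues:
        raise InputError(
            "DCCM selection must contain exactly one anchor atom per residue "
            f"(got {selection.n_atoms} atoms over {selection.n_residues} residues)"
        )
    dx, _ = _fluctuations(traj, selection)  # frames x residues x 3
    inner = np.einsum("fid,fjd->ij", dx, dx) / traj.n_frames
    var = np.diag(inner)
    tiny = var <= 1e-12 * max(float(var.max(initial=0.0)), 1.0)
    if np.any(tiny):
        bad = int(np.flatnonzero(tiny)[0])
        ordinal = selection.residue_indices[bad]
        raise NumericalError(
            f"residue {top.residue_label(ordinal)} has zero fluctuation; cannot normalize DCCM"
        )
    denom = np.sqrt(np.outer(var, var))
    C = inner / denom
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    res = selection.residue_indices
    return CorrelationMatrix(res.copy(), top.residue_resids[res], C)


def bin_correlations(
    matrix: CorrelationMatrix, bins: list[tuple[float, float]]
) -> list[set[tuple[int, int]]]:
    """Assign off-diagonal residue pairs (by author resid, i<j) to half-open
    bins [lo, hi).  Bins must be disjoint."""
    ivs = sorted(bins)
    for (lo1, hi1), (lo2, _) in zip(ivs, ivs[1:]):
        if lo1 >= hi1:
            raise ConfigError(f"bin [{lo1}, {hi1}) is empty or inverted")
        if lo2 < hi1:
            raise ConfigError("correlation bins overlap")
    if ivs and ivs[-1][0] >= ivs[-1][1]:
        raise ConfigError(f"bin [{ivs[-1][0]}, {ivs[-1][1]}) is empty or inverted")
    out: list[set[tuple[int, int]]] = [set() for _ in bins]
    resids = matrix.residue_resids
    n = matrix.n_residues
    for a in range(n):
        for b in range(a + 1, n):
            val = matrix.matrix[a, b]
            for k, (lo, hi) in enumerate(bins):
                if lo <= val < hi:
                    out[k].add((int(resids[a]), int(resids[b])))
                    break
    return out


def average_dccm(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean across replicas; the diagonal is re-set to 1."""
    if not matrices:
        raise InputError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.matrix.shape != first.matrix.shape or not np.array_equal(
            m.residue_resids, first.residue_resids
        ):
            raise AlignmentError("replica DCCMs cover different residues")
    mean = np.mean([m.matrix for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(first.residue_indices.copy(), first.residue_resids.copy(), mean)


def dccm_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the DCCM as a diverging heatmap (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    r = matrix.residue_resids
    im = ax.imshow(
        matrix.matrix,
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
        origin="lower",
        extent=(r[0], r[-1], r[0], r[-1]),
    )
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.colorbar(im, ax=ax, label=r"$C_{ij}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
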