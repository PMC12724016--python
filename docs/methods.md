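# Methods

This note documents the models implemented in `allodyn`, the parameters that
matter, the synthetic data used to validate them, and the numerical and
design choices made where conventions diverge.

## Scope and data model

The package analyzes molecular-dynamics ensembles of a single molecule whose
internal interfaces are of interest (the motivating case is a kinase whose
regulatory PH domain packs against its catalytic domain). The in-memory
model is deliberately small: a `Topology` (per-atom names, elements, 1-based
author residue numbering, chain ids, and optional charge / Lennard-Jones /
GB-radius / mass columns) and a `Trajectory` (a dense frames × atoms × 3
array in Å). File I/O (PDB, DCD, PSF) goes through MDAnalysis; the DCD
dialect is the CHARMM/NAMD 32-bit one. Alternate locations resolve to the
highest-occupancy, first-listed conformer. Residue numbering is taken
verbatim from the input so that residue labels used in the literature (K14,
R144, pS473, …) survive every stage.

Replicas are separate `Trajectory` objects. The analysis window is the last
half of each replica — frames with index ≥ ⌊n/2⌋, the only unambiguous
reading of "the last half of each trajectory" — applied per replica before
any stride or snapshot selection.

## Superposition and essential dynamics

Frames are rigid-body fitted (Kabsch SVD, with the determinant correction
for reflections) to a reference frame over a fit selection, typically the Cα
atoms of the well-ordered core, excluding disordered termini and linkers.
Degenerate fits (<3 atoms, or a collinear set, detected by rank of the
centered coordinates at tolerance 1e−8) are errors.

PCA diagonalizes the 3N×3N covariance of the selection's Cartesian
fluctuations. Two conventions matter and are fixed here:

- Fluctuations are taken around the trajectory **mean** structure; the
  reference frame serves only for superposition.
- The covariance is symmetrized before `eigh` and round-off negative
  eigenvalues are clipped at zero.

Eigenvalues are Å² variances sorted descending; projections are centered.
When frames ≤ 3N the spectrum is noisy and a warning (not an error) is
emitted. Per-residue loadings are the Euclidean norms of each atom's
3-vector inside a unit eigenvector, so squared loadings sum to 1.

The DCCM is C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over one anchor atom
(the Cα) per residue. A residue with vanishing fluctuation (relative
variance below 1e−12 of the largest) is an error — in practice it means the
superposition failed or a coordinate was frozen — rather than being silently
skipped. Replica DCCMs are averaged element-wise with the diagonal reset to
1; PCA, by contrast, runs on the concatenated analysis windows, matching how
single-ensemble PCA panels and replica-averaged DCCMs are usually reported.
Per-replica PCA remains available by calling `compute_pca` per replica.

## Dynamic network and optimal paths

Nodes are residues (Cα anchors). An edge joins residues i, j when the
minimum heavy-atom/heavy-atom distance is below `contact_cutoff` (default
4.5 Å) in at least `occupancy_threshold` (default 0.75) of the analysis
frames. "Neighboring nodes are not considered in contact": the exclusion
radius is not standardized, so the package uses the smallest version —
|i−j| ≤ `neighbor_exclusion` (default 1) on the same chain — and exposes it.
Edges carry W_ij = −log|C_ij| ≥ 0 (|C| clipped at 1); edges with |C_ij| <
1e−6 are dropped with a logged count, which is equivalent to giving them
unbounded weight while avoiding non-finite arithmetic.

Optimal paths use Dijkstra distances from the sink followed by a greedy
reconstruction over shortest-path-DAG edges that always takes the smallest
next residue index; this yields the minimum-weight path with a
deterministic, lexicographically-smallest tie-break. Disconnected
source/sink pairs return an explicit no-path value, not an exception. The
pooled network (occupancy over the union of replica frames, replica-averaged
DCCM) is the default; per-replica networks can be built by passing a single
replica. Tests verify exact agreement with exhaustive simple-path
enumeration on hundreds of random ≤8-node graphs.

## Interface statistics

**Salt bridges.** The criterion — minimum distance ≤ 4.0 Å between basic
side-chain nitrogens (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) and acidic or
phosphate oxygens (Asp OD1/OD2; Glu OE1/OE2; phospho-Ser O1P/O2P/O3P/OG,
residue names SEP/PSER) — is the common N–O convention; source analyses of
this kind rarely state their cutoff, so it is exposed (`--sb-cutoff`) and
results at 3.5/4.5 Å are one rerun away. Main-chain carbonyl variants (e.g.
a "main-chain E322" partner) are selectable via an atom-group override.
Bridges are classed `initial` or `newly_formed` by applying the same
criterion to the designated starting structure. Populations are means of
per-frame indicators, exactly reproducing planted occupancies.

**Distances.** `min` (minimum inter-atomic) or `centroid` (geometric
centers) modes. Note that the centroid distance can be *smaller* than every
pairwise distance when one group lies between the atoms of the other; only
min ≤ mean-pairwise and centroid ≤ mean-pairwise hold in general, and the
tests assert exactly those.

**SASA.** Shrake–Rupley with a deterministic golden-spiral quadrature
(default 960 points, probe 1.4 Å) and Bondi-type radii taken from the
parameter table's GB-radius column. A quadrature point on atom i's expanded
sphere (r_i + probe) is accessible when outside every neighbor's expanded
sphere. An isolated sphere reproduces 4π(r+probe)² exactly up to the
counting resolution; site SASA sums the site's atoms with occlusion against
the whole molecule. Site accessibility changes between systems are reported
as signed percent change of the replica-mean.

## MM/GBSA

Single-trajectory end-state protocol: receptor and ligand geometries are cut
from complex snapshots, so the internal bonded term ΔE_inter is identically
zero and the identity ΔG_b = ΔE_MM + ΔG_sol − TΔS holds per snapshot to
machine precision (asserted at 1e−9).

- **Gas phase.** E_elec = Σ 332.0637·q_iq_j/(ε_in·r_ij) kcal/mol (default
  ε_in = 1) and CHARMM-form LJ, ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶] with
  r_min,ij = r_min,i/2 + r_min,j/2, ε_ij = √(ε_iε_j), no cutoff. Pairs
  closer than 0.1 Å raise a clash error naming the pair.
- **Polar solvation.** Generalized Born with OBC-II effective radii:
  pairwise HCT descreening integrals over reduced radii ρ̃ = ρ − 0.09 Å
  (uniform descreening scale 0.8), Ψ = Iρ̃, and
  1/R = 1/ρ̃ − tanh(1.0·Ψ − 0.8·Ψ² + 4.85·Ψ³)/ρ. Then
  G_pol = −(332.0637/2)(1/ε_in − 1/ε_out)Σ_ij q_iq_j/f_GB with
  f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j}), self terms included, ε_out = 78.5.
  Born radii are recomputed for each species (complex, part A, part B). An
  isolated ion reduces to the Born formula with R = ρ − 0.09. Salt screening
  is off by default; an optional Debye–Hückel κ multiplies the solvent term
  with e^{−κf}.
- **Nonpolar solvation.** γ·SASA + β per species with γ = 0.00542
  kcal/(mol·Å²), β = 0.92 kcal/mol. Because β enters once per species, the
  binding nonpolar term is γ·(SASA_C − SASA_A − SASA_B) − β; the sign
  convention is stated in the output headers and the β intercept is reported
  separately from per-residue maps.
- **Entropy.** Normal-mode analysis at T = 310 K: local minimization to
  gradient norm < 1e−6, mass-weighted Hessian by central differences of the
  analytic gradient (step 1e−4 Å), rigid-body modes projected out
  (orthonormalized translation/rotation vectors; the projector drops
  degenerate ones, e.g. the axial rotation of a diatomic), and
  harmonic-oscillator entropy per mode. Residual frequencies below 5 cm⁻¹
  are treated as rigid-body remnants; imaginary frequencies beyond that
  tolerance raise a non-minimum error. Entropy requires an explicit energy
  model for the species' full potential; the package supplies a
  Coulomb+LJ+harmonic-bond `ToyEnergyModel` for generated complexes, and the
  flag defaults off for protein inputs, where no force field is available —
  relative ΔG_b comparisons between systems are then entropy-free, which is
  the regime in which end-state estimates are meaningful anyway.
- **Snapshots.** Gas/solvation terms average over up to 2500 evenly spaced
  snapshots from the latter half of each replica; entropy over its own
  (default 50) subset; the final ΔG_b is the mean over replicas with
  per-replica values retained.
- **Decomposition.** Each cross pair's gas-phase energy splits half to each
  side's atom; polar solvation uses each atom's GB row-sum change between
  complex and isolated species; nonpolar uses γ·ΔSASA per atom. Residue sums
  conserve the enthalpic total (checked at 1e−6 kcal/mol). The significance
  threshold is −1.0 kcal/mol, applied to the enthalpic per-residue value —
  entropy is never decomposed per residue.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed); identical calls are
bit-identical.

- `make_chain_structure` / `make_grid_structure`: pseudo-Cα geometries (a
  gentle helix with exact 3.8 Å consecutive spacing, or a planar lattice
  with 3.8 Å pitch whose static contact graph is exactly the 2-D lattice
  under the 4.5 Å cutoff). One optional side-chain pseudo-atom per residue
  sits 1.5 Å off the Cα and stands in for the charged moiety.
- `sample_gaussian_trajectory`: residue i moves along one fixed unit
  direction e_i with amplitude σ_i·z_i(t), z drawn from a stationary
  zero-mean Gaussian whose correlation matrix carries the planted ρ values.
  Members of a planted pair share their direction, so the expected DCCM
  entry equals the planted scalar ρ exactly — parameter recovery is a sharp
  test. Non-PSD planted targets either raise an error or (for
  pathway-planting, where many overlapping pairs are set) are projected onto
  the PSD cone by eigenvalue clipping with diagonal renormalization — a
  factor model with loadings E·Λ^1/2 — and the projected matrix is the
  stored ground truth.
- `plant_contact_pair`: pins the two side-chain pseudo-atoms at the contact
  distance in exactly round(occupancy·n_frames) frames chosen by a seeded
  permutation (not Bernoulli draws), so populations are exact at any n; Cα
  positions and all other atoms are untouched.
- `plant_pathway`: assigns ρ_on to consecutive chain pairs and ρ_off to all
  other contact pairs of a supplied contact graph; with |ρ_on| > |ρ_off| the
  minimum-weight route between the chain endpoints is the chain itself
  (warned as degenerate otherwise). The trajectory-level realization uses
  the lattice geometry with `neighbor_exclusion = 0` in the study config, so
  the full lattice is the background graph; defaults ρ_on = 0.9,
  ρ_off = 0.2, σ = 0.4 Å over 400 frames keep lattice contacts essentially
  permanent (thermal distance changes beyond the 0.7 Å slack to the cutoff
  are rare) while leaving the chain's weight advantage large relative to
  sampling noise in −log|Ĉ|.
- `make_toy_complex`: two rigid jittered-grid clusters of parameterized
  particles at an exact minimum cross-cluster separation, with closed-form
  Coulomb and LJ cross energies (evaluated by an explicit double loop,
  independent of the vectorized implementation) stored as ground truth.

What the synthetic data does **not** emulate: real protein fold geometry,
anharmonic and multi-basin dynamics, solvent and ions, hydrogens, rotameric
side-chain states, or force-field detail. Passing tests therefore
demonstrate that each estimator recovers the statistical or energetic
quantity it claims to compute — not that any biological conclusion follows
from a particular real trajectory. Real-data runs consume standard
PDB/PSF/DCD inputs through the same code paths.

## Orchestration and determinism

`run_study` validates the config eagerly (all violations reported at once;
unknown keys rejected), fills defaults (4.5 Å / 0.75 / 4.0 Å / 1.4 Å / γ, β
/ 2500 / 50), and runs enabled stages per system, isolating failures per
system and exiting nonzero at the end if any occurred. Everything stochastic
lives in the synthetic generators under the single config seed; snapshot
selection is deterministic even spacing; CSV outputs are byte-identical on
rerun. The manifest records every tunable that affects the numbers, plus
package version and collected warnings. Stage timings go to the log, not to
outputs.

Test and acceptance problem sizes (hundreds of frames, ≤20 residues, 5000
frames for correlation recovery, 200 random graphs for the path oracle) were
chosen as the smallest sizes at which sampling error is comfortably inside
the asserted bounds.

## Known limitations

- The GB descreening scale is uniform (0.8) rather than per-element, and
  radii come from the parameter table; against Amber `mm_pbsa` outputs,
  small systematic offsets in G_pol are expected (the exact igb/radii pairing
  of any given study is rarely recoverable from its text).
- Normal-mode entropy is unavailable for proteins without a force field;
  ΔG_b for real systems is reported entropy-free, so only relative values
  across systems are meaningful — which end-state methods recommend anyway.
- The salt-bridge criterion (distance, 4.0 Å) is a convention, not a ground
  truth; populations shift at 3.5/4.5 Å and the CLI makes the sweep trivial.
- No periodic-box handling: frames must contain whole molecules.
- `optimal_path` reports the single optimal route; suboptimal-path
  ensembles, community structure, and betweenness are out of scope.
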