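# allodyn

Trajectory analysis of protein autoinhibition dynamics: essential dynamics
(PCA), dynamic cross-correlation matrices, allosteric pathway networks,
interface salt-bridge populations, binding-site solvent accessibility, and
MM/GBSA binding free energies with per-residue decomposition — plus a
synthetic-trajectory generator that plants known statistical structure so
every stage can be validated against ground truth at desk scale.

The package grew out of the analysis stack used to characterize AKT kinase
autoinhibition, where the pleckstrin-homology (PH) domain packs against the
kinase domain and phosphorylation of S473 triggers release through an
allosteric path along the kinase N-lobe. It is aimed at computational
structural biologists who have topology/trajectory files (PDB/PSF/DCD, NAMD
or CHARMM conventions) and want a reproducible, scriptable version of this
analysis pipeline — or who want to test such pipelines without microsecond
simulations.

## Methods at a glance

- **Essential dynamics.** Eigendecomposition of the Cartesian covariance of
  selected Cα atoms after rigid-body superposition. Eigenvalues λ_k (Å²) are
  per-component variances; per-residue loadings locate flexible regions.
- **Dynamic cross-correlation.** C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)
  over residue displacement vectors Δr_i(t) = r_i(t) − ⟨r_i⟩, C_ij ∈ [−1, 1];
  replica matrices are averaged element-wise.
- **Dynamic network analysis.** Residues are nodes; an edge joins two
  residues in contact (minimum heavy-atom distance < 4.5 Å) in at least 75%
  of frames, excluding sequence neighbors, weighted by W_ij = −log|C_ij|.
  The minimum-weight (Dijkstra) path between a source and sink residue is
  the optimal allosteric pathway.
- **Salt-bridge populations.** Fraction of frames with basic-N / acidic-O
  minimum distance ≤ 4.0 Å (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2 vs Asp/Glu
  carboxylates and phospho-Ser phosphate oxygens), classified as present in
  the starting structure or newly formed.
- **SASA.** Shrake–Rupley quadrature (960 deterministic sphere points,
  1.4 Å probe); site SASA sums the atoms of listed residues with occlusion
  against the whole molecule.
- **MM/GBSA.** ΔG_b = ΔE_MM + ΔG_sol − TΔS with ΔE_MM = ΔE_inter + ΔE_elec +
  ΔE_vdW (single-trajectory protocol, so ΔE_inter = 0 exactly),
  ΔG_sol^elec from the generalized Born model with OBC-II effective radii,
  ΔG_sol^nonpolar = γ·SASA + β with γ = 0.00542 kcal/(mol·Å²) and β = 0.92
  kcal/mol, and −TΔS from normal-mode analysis (toy energy models).
  Per-residue decomposition splits cross terms half to each side.

## Worked example

Generate a synthetic 16-residue lattice system with a planted correlation
chain, then recover the allosteric path from its dynamic network:

```bash
$ allodyn simulate --out data --name demo --kind lattice --n-res 16 \
    --n-frames 200 --seed 5
$ allodyn network --topology data/demo.pdb --trajectory data/demo.dcd \
    --neighbor-exclusion 0 --source 1 --sink 16 --out net
24 edges
1 -> 5 -> 9 -> 13 -> 14 -> 15 -> 16  (weight 2.3857)
```

The recovered route is exactly the planted chain (stored in
`data/demo.truth.json`): the generator gave consecutive chain residues
correlation 0.9 (edge weight −log 0.9 ≈ 0.105) against a 0.2 background, so
the minimum-weight path hugs the chain. The total weight is the sum of
−log|C_ij| over its six edges as measured from the sampled trajectory.

The same executable reproduces the in-text per-residue arithmetic used to
rank binding contributions against a reference residue:

```bash
$ allodyn compare --values "K14=-5.6,R23=-5.0,R25=-2.9" --reference K14
{
 "K14": 100,
 "R23": 89,
 "R25": 52
}
```

i.e. with per-residue binding contributions of −5.6, −5.0 and −2.9 kcal/mol,
R23 and R25 carry 89% and 52% of the reference residue's contribution.

Full multi-system studies run from a YAML config (systems, replicas, named
selections, per-stage parameters) with `allodyn run --config study.yaml`,
writing one CSV per stage per system plus a manifest of every parameter that
affects the numbers. See `docs/methods.md` for the model details and the
design decisions behind each stage.

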