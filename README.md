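# pocketscan

Ensemble-based mapping of small-molecule binding pockets on protein
conformers, built for GTPase-style molecular switches (Rho, Ras and
relatives) that cycle between GTP-bound, GDP-bound and nucleotide-free
(APO) states.

Crystallographic databases and simulation trajectories offer many
conformers of the same protein. Instead of looking for pockets in a
single structure, `pocketscan` asks: *which residues form probe-binding
hot spots consistently across an ensemble, and which pockets appear only
in particular nucleotide states?* State-selective pockets — especially
ones distal to the conserved nucleotide site — are candidate allosteric
sites for selective inhibitors.

## What it computes

**Probe occupancy** (the central statistic). For each structure *s* and
residue *i*, a binary contact indicator c<sub>is</sub> = 1 if any heavy
atom of any fragment probe lies strictly within 5.0 Å of any heavy atom
of residue *i*. Occupancy over a structure set of size *n* is

  O<sub>i</sub> = (1/n) Σ<sub>s</sub> c<sub>is</sub> ∈ [0, 1],

1 meaning a proximal probe site exists in every structure. Probe poses
come from any external fragment-mapping tool (multi-model PDB) or from
the built-in geometric grid scan.

**Differential occupancy.** Between two state-labelled sub-ensembles,
each residue's 2×2 contact table is tested (two-sided Fisher exact by
default, or a structure-label permutation test); residues with p < 0.05
are flagged. Profiles are compared across datasets with the Pearson
correlation of O<sub>i</sub>.

**Conformational analysis.** PCA of the covariance matrix
C<sub>ij</sub> = ⟨(r<sub>i</sub> − ⟨r<sub>i</sub>⟩)(r<sub>j</sub> −
⟨r<sub>j</sub>⟩)⟩ of superposed Cα coordinates; average-linkage
hierarchical clustering on pairwise RMSD with closest-to-mean
representative selection; per-residue RMSF and mean B-factor; the
dynamical cross-correlation map ⟨Δr<sub>i</sub>·Δr<sub>j</sub>⟩ /
√(⟨|Δr<sub>i</sub>|²⟩⟨|Δr<sub>j</sub>|²⟩).

**Sequence conservation.** Per-column Shannon entropy S = −Σ p log₂ p
under a 21-letter alphabet (20 amino acids + gap) and a 7-letter
physicochemical alphabet, normalised to C = 1 − S/log₂N so conserved
columns score 1; a column is called conserved when C₂₁ > 0.6 or
C₇ > 0.6, and columns with >30% gaps are masked.

**Solvent exposure.** Sphere-sampling (Shrake–Rupley-style) SASA with a
1.4 Å probe; a residue is exposed when its area exceeds 40% of the same
residue type's area in an internally built extended Ala-X-Ala
tripeptide.

**Library filtering.** The six-descriptor compound filter (MW < 553 Da,
rotatable bonds ≤ 14, donors ≤ 6, acceptors ≥ 3, PSA ≥ 30 Å²,
logP ≥ −0.5) and the docking-score cutoff (score ≤ −8, ranked).

A synthetic-data module generates two-state ensembles with a planted
collective mode, state-preferential probe poses, Bernoulli contact
matrices and alignments with controlled conservation, so the whole
pipeline is testable without downloads.

## Worked example

```python
import pocketscan as pk

# A synthetic two-state study: 200 residues, 30 structures per state,
# a pocket block contacted with probability 0.9 (GDP) vs 0.1 (GTP).
prof_gdp, prof_gtp, planted = pk.simulate_contact_matrices(seed=7)
results = pk.DifferentialOccupancy(prof_gdp, prof_gtp).fit()
print(results.summary())
```

```text
Differential probe occupancy
  states: GDP (n=30) vs GTP (n=30)
  test: fisher   alpha: 0.05
  residues: 200   significant: 23
  residue   occ_a   occ_b   delta    p-value
       62    0.93    0.03    0.90   2.29e-13
       70    0.97    0.07    0.90   2.29e-13
       65    0.93    0.07    0.87   3.22e-12
       ...
```

The planted pocket spans residues 60–79; all twenty are recovered (the
23 flags include 20 planted plus 3 borderline null residues), with
occupancy near the generative 0.9/0.1 probabilities and p-values far
below the 0.05 threshold.

```python
# PCA of a planted-mode ensemble: the leading component recovers the
# inter-state displacement direction.
spec = pk.SyntheticSpec.for_mode_recovery(seed=7)
cs, truth = pk.make_two_state_ensemble(spec)
pca_res = pk.pca(pk.superpose_ensemble(cs))
print(pca_res.summary())
print("cosine(PC1, planted mode):",
      round(abs(pca_res.modes[:, 0] @ truth["mode"]), 4))
```

```text
Ensemble PCA
  atoms (Cα): 50    components: 150
  total variance: 7.984 Å²
  PC   eigenvalue(Å²)   var%    cum%
  1          2.2939    28.7    28.7
  2          0.0879     1.1    29.8
  ...
cosine(PC1, planted mode): 0.9978
```

PC1 carries the planted 3 Å inter-state mode (eigenvalue ≈ (3/2)² +
σ² = 2.29 Å²) while the remaining components are isotropic noise at
σ² = 0.04 Å², and its direction matches the ground truth to cosine
0.998.

## Command line

Every stage is also a `pocketscan` subcommand operating on plain-text
files (`synth`, `ingest`, `pca`, `cluster`, `dccm`, `conserve`, `sasa`,
`contacts`, `occupancy`, `diff`, `screenfilter`); see `pocketscan
--help`. Ensembles are described by a TSV manifest with columns `id`,
`file`, `chain` and optional `state` / `probe_file`.

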