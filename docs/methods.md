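# Methods

This note records the models, conventions, numerical choices and known
limitations of `pocketscan`, in the spirit of a model-description
document: what is computed, under which assumptions, and what the tests
on synthetic data do and do not demonstrate.

## Probe occupancy and differential statistics

The primitive datum is binary and per structure: residue *i* in
structure *s* either coordinates a fragment probe (any heavy-atom pair
strictly within the contact cutoff, default 5.0 Å) or it does not.
Occupancy is the mean of this indicator over a structure set, so it is
an estimate of the probability that a conformer of that set presents a
probe-binding site at residue *i*. The per-structure contact matrix is
retained on every `OccupancyProfile` precisely so that inference can
return to the underlying binary data rather than the summary fractions.

Boundary conventions are strict everywhere they matter: a pair at
exactly 5.0 Å is *not* a contact, a residue at exactly 40% relative
exposure is *not* exposed, a column with exactly 30% gaps is *not*
masked, p = 0.05 is *not* significant, and a compound of exactly
553 Da fails the weight filter while a docking score of exactly −8 is
retained. These follow the printed comparison operators of the criteria
they implement.

**Differential test.** The default is the two-sided Fisher exact test
on the 2×2 table (contacted / not contacted × state A / state B),
chosen because the underlying datum is a per-structure Bernoulli
variable, making the hypergeometric conditional model exact and fully
deterministic. A label-permutation alternative uses |ΔO| as statistic
with p = (1 + #{null ≥ observed}) / (1 + n_perm), deterministic given a
seed. No multiple-testing correction is applied to the significance
flags (the flags reproduce a raw p < 0.05 rule); a Benjamini–Hochberg
column is emitted alongside for users who want it.

Calibration on synthetic nulls shows both tests are valid but
conservative at small per-state counts: with 30 binary observations per
state the discrete null support is so coarse that the achieved level is
≈ 0.03 at nominal 0.05. The type-I calibration study therefore uses 100
structures per state, where the permutation null is fine enough for the
achieved level (≈ 0.04) to be meaningfully compared with the nominal
one. This is a property of exact tests on small binary samples, not of
the implementation.

## Synthetic study conditions

The generator's defaults are the package's reference conditions and are
used unchanged by the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_residues` | 200 | chain length |
| `n_per_state` | 30 | structures per nucleotide state |
| `amplitude` | 3.0 Å | norm of the planted inter-state displacement |
| `sigma` | 0.2 Å | isotropic per-axis positional noise |
| `mode_block` | 24–40 | switch-like block carrying the mode |
| `probe_prob` | 0.9 / 0.1 | per-structure pocket-probe probability by state |
| pocket block (contact sims) | 60–79 | planted pocket residues |
| null contact probability | 0.5 | state-independent background contacts |

The backbone is a smooth helix-like curve with canonical 3.8 Å Cα
spacing (2.3 Å radius, 100° twist, 1.5 Å rise). The planted mode is a
radial push of the block, **orthogonalised against the six rigid-body
modes** of the mean geometry and normalised. This matters: least-squares
superposition removes rigid motion, so a mode with a net
translation/rotation component would be partially absorbed by the fit
and the recovered PC1 could not match the nominal ground truth. After
orthogonalisation the planted signal passes through superposition
undistorted, and the noiseless between-state RMSD has the closed form
amplitude/√N.

Null residues in the contact simulations are contacted with probability
0.5 in *both* states rather than never, so the false-positive rate of
the differential test is measured against a live null instead of a
degenerate one.

**Mode-recovery design.** The angular error of a leading sample
eigenvector scales as √(3Nσ²/(nλ₁)). At the reference noise level the
default 60-structure ensemble in 600 coordinate dimensions gives an
expected PC1 error near 0.4 rad-equivalents (cosine ≈ 0.93) — an
estimation limit, not an implementation defect. The mode-recovery study
(`SyntheticSpec.for_mode_recovery`) therefore uses 50 residues × 600
structures, where the expected cosine exceeds 0.997. The generative PC1
variance fraction is (a²/4 + σ²)/(a²/4 + 3Nσ²).

**What the fixtures do not emulate.** No side chains, no packing, no
sequence-structure coupling, no correlated (collective) noise, no
missing residues or alternate conformations beyond what the PDB reader
handles. Passing tests demonstrate the statistics and geometry are
computed correctly under the stated generative model; they do not
demonstrate robustness to crystallographic artefacts (lattice contacts,
refinement restraints) present in real ensembles.

## Conformational analysis conventions

* Covariance uses the population divisor *n*, reading the covariance as
  an ensemble average; multiply eigenvalues by n/(n−1) for the sample
  form.
* Eigenvector signs follow a fixed convention (largest-magnitude
  component positive) so projections are reproducible across runs.
* Ensemble superposition fits all members to the first, then iterates
  fits onto the running mean to convergence; the default core is all
  shared Cα positions. An optional iterated-core refinement (drop the
  top-variance quartile, re-fit, repeat) is available but off by
  default.
* Hierarchical clustering is average linkage on the pairwise-RMSD
  matrix (fresh optimal superposition per pair), cut into exactly *k*
  groups (default 24); clusters are renumbered by population, ties by
  the lowest member index. The cluster representative minimises RMSD to
  the cluster mean, computed after superposing members onto the first
  member and once re-fitting onto the mean; ties go to the lowest
  structure index.
* DCCM entries for residues with zero fluctuation are undefined and
  reported as NaN rather than 0 or 1.

## Sequence conservation

Entropy is computed in bits over the observed class frequencies; 'X'
entries are treated as missing and dropped from the column before
counting, while gaps count as a class of their own in both alphabets.
The 7-letter grouping is aliphatic {A,V,L,I,M,C}, aromatic {F,W,Y,H},
polar {S,T,N,Q}, positive {K,R}, negative {D,E}, special {G,P}, plus
the gap. Normalisation is C = 1 − S/log₂N, pinned by the boundary
behaviour that a fully conserved column scores 1 and a maximally
diverse column scores 0; the number of sequences enters only the
frequencies and is kept as profile metadata. Because any logarithm base
cancels in S/log₂N, the scores are base-independent. No sequence
weighting or redundancy filtering is applied.

## Solvent accessibility

SASA uses sphere sampling with a deterministic Fibonacci (golden
spiral) point set — no RNG, so results are bit-reproducible — with 960
points per atom by default. Van der Waals radii are the Bondi (1964)
element values, user-replaceable per call; hydrogens are never present
(heavy atoms only throughout the package). Convergence on a
multi-atom-per-residue backbone fixture is <1% per residue when the
point count is doubled; single-atom residues (bare Cα traces) converge
more slowly since no within-residue averaging occurs.

The Ala-X-Ala reference areas are not shipped as data: they are
computed once per session by building each extended tripeptide
internally (seeded ETKDG embedding, backbone dihedrals set to
φ = −120°, ψ = 120°; proline's ring φ left as embedded) and running the
same calculator on it. A user-supplied reference table is accepted
wherever the built-in one is used. Different radius sets or reference
geometries shift absolute areas by a few percent; the exposed/buried
classification at the 40% threshold is the stable quantity.

## Geometric probe scan

The built-in pseudo-probe generator marks grid points (default 1.0 Å
spacing) that are near the surface (2.5 Å to `shell_distance`, default
4.5 Å, from the nearest heavy atom) yet sheltered from solvent (at
least `burial_threshold` = 45 heavy atoms within 8 Å — calibrated to
protein heavy-atom density ≈ 0.057 Å⁻³, where a flat surface point sees
roughly 30 atoms and a concave pocket point substantially more).
Retained points are clustered by 6-neighbour grid adjacency; components
under 3 points are dropped. The scan is deterministic and
order-invariant; it marks sheltered concavities, not energetically
favourable hot spots, and carries no chemistry.

## Nucleotide-state annotation

HET codes map to states via a default table: GTP, GNP (GppNHp), GSP
(GTPγS), GCP (GppCp) → GTP; GDP → GDP; none of these → APO; both
classes present → UNKNOWN. The analog list is an explicit, overridable
choice — crystallographers commonly use non-hydrolysable analogs to
trap the active state, but any mapping can be supplied.

## Problem sizes

The test suite and acceptance script run desk-scale studies: 10-seed
replicates of the 200-residue / 30-per-state differential study,
100-per-state calibration nulls with 2000 permutations, the
50-residue / 600-structure mode-recovery ensemble, and 200-residue
surface-area fixtures. These sizes were chosen so each study estimates
its quantity with useful precision while the full suite completes in
about a minute of compute.

## Known limitations

* PDB input only (mmCIF beyond coordinates, assemblies and symmetry
  expansion are out of scope); author residue numbering is kept
  verbatim, with alignment-based mapping available for cross-structure
  comparison.
* The differential flags reproduce a raw p < 0.05 rule; near-threshold
  membership in the flagged set depends on the chosen test.
* Compound descriptors are consumed, not computed; polar surface area
  is interpreted in Å².
* The package does not run molecular dynamics, external fragment
  mapping, or docking; it analyses their outputs.
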