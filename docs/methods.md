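# Methods

## Problem setting

Given (i) a set of protein structures, each mapped to a row of one master
multiple sequence alignment, (ii) a list of binding-site alignment
columns, and (iii) a table of true/false/unknown labels per (sequence,
compound) pair, the package predicts the missing labels and reports the
local structural features that carry the signal. Labels are per sequence;
structures are the unit of clustering, so a sequence with many crystal
forms (active/inactive conformations, different ligands) contributes all
of them.

## Data model and input handling

Structures are reduced to one *site* per selected column: the residue
type and the centroid of the side-chain heavy atoms (N, CA, C, O, OXT
excluded; glycine falls back to CA; hydrogens are ignored; for residues
with alternate conformations the highest-occupancy conformer is kept,
ties broken by altloc order). A structure gapped at any selected column,
or with an unresolved residue there, is excluded — the conservative
reading of a gap filter — and counted in the set's provenance record.

Binding-site columns can be given explicitly or derived from a reference
structure with a bound ligand: a column qualifies when any heavy atom of
its residue lies within the cutoff (default 5 Å) of any ligand atom, and
columns whose alignment gap fraction exceeds `max_gap_fraction` (default
0.5 — "highly gapped" is otherwise unquantified) are removed. Selection
is monotone in the cutoff.

Affinities in nM are binned at 10 µM: `Kd ≤ 10,000 nM` is a binder. The
boundary maps to *true* because the threshold is meant as the largest
affinity still indicating meaningful binding. Columns are 0-based
internally and 1-based in human-readable output.

## Distance between substructures

For a column triple, two structures are compared by
`D = w_s·lRMSD + w_p·Σ pharm(tₐ,t_b)` with `w_s = w_p = 1` by default.
Correspondence is fixed by alignment column — there is no residue
matching step — and the three-point superposition uses the closed-form
SVD solution with the determinant correction, so only proper rotations
are allowed; three points are the smallest set with a unique 3-D
superposition. Degenerate (coincident) point sets still yield a defined
RMSD. The batched all-pairs implementation is tested entrywise against
the scalar routine and against an independent rotation-sampling oracle to
1e-3 Å.

The pharmacophore matrix ships as a replaceable CSV. The default is
derived from six binary features per residue type (H-bond donor, H-bond
acceptor, aromatic, positively ionizable, negatively ionizable,
hydrophobic); the dissimilarity of two types is the number of differing
features, scaled by 1.0 so that one feature difference weighs like 1 Å of
lRMSD. Any 20×20 symmetric non-negative matrix with zero diagonal can be
substituted to change the chemical term.

## Embedding and clustering

Each row of a subset's N×N distance matrix is treated as a feature vector.
Rows are projected onto principal axes fitted with per-row weights
`1/(structures of that sequence)` — the overrepresentation correction —
keeping the smallest dimensionality that explains 90% of variance, capped
at 10. Component signs follow a fixed convention (largest-magnitude
loading positive) so repeated runs are byte-identical. The all-identical
degenerate case returns a single zero dimension.

Gaussian mixtures are fitted over K = 1..25 and three covariance families
(spherical, diagonal, full) and selected by BIC; assignments are
maximum-posterior. Ties resolve to smaller K, then the simpler family.
Model search uses k-means++ initialisation with 2 restarts per candidate
and stops a family's K scan after 2 consecutive BIC non-improvements;
with thousands of subset clusterings per dataset this keeps a full run in
minutes while the BIC optimum, which sits in a single broad basin on
these embeddings, is still found. Passing `bic_patience=None` and a
larger `n_init` restores an exhaustive scan. Per-subset seeds are derived
deterministically from the master seed and the subset index, so results
are identical for any worker count.

Silhouettes use Euclidean distance in the embedding. A lone cluster and
singleton clusters score 0 by convention; values are checked against a
direct O(N²) implementation of the definition.

## HPC selection and purity

Purity of a cluster is `multiplicity of the most frequent known label /
number of known labels`; unknowns are disregarded. Counting is
sequence-weighted by default (each sequence one vote however many of its
structures are present); structure-level counting is available for
ablation. A cluster is an HPC when purity ≥ 1.0 (the strictest possible
threshold, the default), mean silhouette ≥ 0 (negative-silhouette
clusters are malformed), and at least one known label is present.
Majority ties — possible only below the default threshold — resolve to
*false*. Clusters with only unknown labels are skipped but can still
receive votes as test members.

The cross-family analysis counts, per compound, true-labelled HPCs and
the subset whose member sequences span two or more phylogenetic families;
the purity-distribution export emits (affinity purity, family purity)
pairs for clusters with a strict true majority.

## Voting, decision boundary, prediction

A structure receives one vote per subset whose cluster is an HPC, for
that HPC's majority label; votes per label are bounded by `C(P,3)`. A
linear-kernel SVM (C = 1.0, unweighted classes) on the 2-D vote vectors
of labeled structures defines the boundary; the sign convention makes
positive decision values the *true* side, and exact zero resolves to
*false* — conservative for a binding claim. Confidences come from a
sigmoid (Platt) fit of the training decision values; only their ranking
is used downstream (enrichment), not their absolute scale. Zero-vote
structures are excluded from classification and reported as
`no-evidence`. Sequence-level predictions average the member structures'
decision values and confidences, labelling by sign with zero → false.
A single-class training set raises a degenerate-model error; the pipeline
falls back to the majority label with a logged warning.

## Evaluation

Folds are single-linkage components of the ≥70%-identity graph over the
aligned domain (identity = matches / columns where neither sequence is
gapped). Single linkage is chosen because its defining property is
exactly the guarantee needed: no test sequence shares threshold identity
with any training sequence. Per fold, test labels are masked to unknown
*before* purity is computed, HPCs and the SVM are derived from the
remainder, and the fold's sequences are scored; a leakage test verifies
the masked view is bit-identical whichever values the hidden labels had.
Metrics are pooled (micro-averaged) across folds because fold sizes are
non-uniform; per-fold averaging is the obvious alternative and was
rejected as unstable for tiny folds. ROC and PR AUCs use trapezoidal
integration with tie-aware ranking; ROC AUC is verified against the
all-pairs concordance statistic. The enrichment factor of the top
fraction f (default 0.05) uses `N_top = ceil(f·N)` so the bucket is never
empty, and reports `EF_max = N/n_actives`, the enrichment of a perfect
ranking.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
protein physics. Defaults: 60 sequences, structure counts geometric with
mean 2 (so some sequences have several structures, many just one), a
27-position site, 7 families, two signal triples — (2, 9, 17) and
(5, 12, 23) — two archetypes per label class, 0.1 Å per-structure
coordinate jitter, 20% of sequences unlabeled, no label noise. Background
positions share one base geometry; their residue types vary *within* one
pharmacophore-equivalence group per position (mostly the hydrophobic set
A/C/I/L/M/P/V), so background subsets stay uninformative in both distance
terms while sequence identity between unrelated sequences stays far below
the 70% fold threshold. At signal triples, each archetype gets its own
3-point constellation (rejection-sampled to keep inter-archetype lRMSD at
least 5× the jitter, capped at 3 Å so that raising the jitter genuinely
erodes the margin rather than forcing wider spacing) and its own residue
triple drawn from chemically close letters (A/F/W/T/G), giving a modest
chemical contrast on top of the geometric one. Families are assigned
round-robin so every archetype spans several families, exercising the
cross-family analysis. Each structure receives an arbitrary rigid motion,
so superposition is genuinely exercised.

What passing tests therefore show: the pipeline recovers planted,
well-separated label-pure substructure clusters and propagates labels
with high held-out AUC under these conditions. What they do not show:
performance on real binding sites, where backbone flexibility, alignment
errors, correlated positions and label noise are not modelled here.

The hand-written worked example (11 retained structures, 5 columns)
exercises every edge path: a structure dropped for an alignment gap, a
glycine site, unknown labels, and a remote outlier that ends with zero
votes.

## Numerical and reproducibility choices

Distance matrices are symmetrised exactly by construction and clipped at
zero; embeddings, mixtures and SVMs are seeded; outputs are written with
fixed `%.6g` formatting so identical config + seed gives byte-identical
CSVs, for any number of workers. Clusterings are cached per dataset
(keyed by a hash of the site table and the clustering parameters) and
shared across compounds, which are processed fully independently.

## Known limitations

- The exact algebraic weighting between the structural and chemical terms
  is configuration, not dogma; the default equal weighting is sensible on
  Å-scale data but should be revisited for other units.
- Purity is computed on flat binary labels; hierarchical (e.g. EC-style)
  labels are out of scope.
- Calibration is a sigmoid on training decision values; absolute
  confidences are not guaranteed calibrated on test data, only the
  ranking is used.
- The recovery experiment's problem size (60 sequences, ~120 structures,
  2925 clusterings) was chosen as the smallest scale at which the
  combinatorial machinery is fully exercised; much larger datasets will
  want the parallel path (`n_jobs`) and the on-disk cache.
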