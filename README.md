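# ccorps

Semi-supervised prediction of binary protein annotations — typically
*does this kinase bind this inhibitor?* — from local binding-site
structure, by **c**ombinatorial **c**lustering **o**f **r**esidue
**p**osition **s**ubsets.

## Who this is for

Structural bioinformaticians with (a) many structures of related proteins
mapped to one master sequence alignment, (b) a set of binding-site
alignment columns, and (c) binding labels (true / false / unknown) for
*some* of the sequences. The package finds the local structural features
that separate binders from non-binders and transfers labels to the
unannotated proteins. The canonical application is the human kinome: the
ATP site is so conserved that whole-site comparison blurs selectivity,
while individual residue triples can be sharply discriminative (the
gatekeeper pocket being the textbook example).

## Method

For a binding site of `P` alignment columns, all `C(P,3)` column triples
are enumerated (`P = 27` gives 2925). For each triple, every structure
contributes a 3-residue *substructure* — side-chain centroids plus residue
types — and all pairs are compared with

```
D(a,b) = w_s · lRMSD(a,b) + w_p · Σᵢ pharm(tₐᵢ, t_bᵢ)
```

where `lRMSD` is the least RMSD of the three corresponding centroids under
optimal proper rigid superposition, and `pharm` is a 20×20 amino-acid
dissimilarity (default: count of differing binary pharmacophore features —
donor, acceptor, aromatic, ±ionizable, hydrophobic). Rows of the distance
matrix are PCA-embedded (sequences are inverse-weighted by their structure
count so heavily crystallised proteins do not dominate) and clustered with
a Gaussian mixture; the component count and covariance family are chosen
by BIC.

A cluster is a **highly predictive cluster (HPC)** when its known labels
are 100% pure (unknowns disregarded; each sequence counted once) and its
mean silhouette is non-negative. Every structure inherits one vote per
subset whose cluster is an HPC; the (false, true) vote vectors of labeled
structures train a linear-kernel SVM whose hyperplane classifies the rest,
with Platt-calibrated confidences for ranking. Evaluation uses
cross-validation over 70%-identity single-linkage sequence groups
("nr-clusters") with test labels masked *before* HPC selection, reporting
ROC AUC, PR AUC, and the top-5% enrichment factor
`EF = (n_top/N_top)/(n_act/N)`.

## Worked example

```python
import ccorps

sset, labels = ccorps.worked_example_fixture()   # 11 structures, 5 columns
matrix = ccorps.default_pharm_matrix()
subsets = ccorps.column_subsets(sset.position_columns, 3)   # 10 triples
coll = ccorps.compute_all_clusterings(sset, subsets, matrix, seed=1)
hpcs = ccorps.select_hpcs(coll, sset, labels, "example-inhibitor")
votes = {v.structure_id: v.votes for v in ccorps.tally_votes(hpcs, coll)}
print(len(hpcs), votes["U1_a"], votes["X1_a"])
```

prints

```
18 {False: 0, True: 9} {False: 0, True: 0}
```

Eighteen HPCs are found (nine per label). The unlabeled structure `U1_a`
sits inside a true-labelled HPC in 9 of the 10 subset clusterings, so it
will be predicted a binder; the remote outlier `X1_a` falls in
single-member clusters with no known labels anywhere and is reported as
`no-evidence` rather than classified.

The same run from the shell:

```bash
ccorps synth --out data/ --seed 7            # synthetic dataset with planted signal
ccorps evaluate --sites data/site_table.csv --labels data/labels.csv --out run/
ccorps cross-family --reference              # published kinome HPC table summary
```

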