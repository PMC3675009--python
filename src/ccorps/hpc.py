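"""Label purity and Highly Predictive Cluster (HPC) selection.

A cluster's purity is the fraction of its known labels equal to the most
frequent known label; unknown labels are disregarded.  Counting is
sequence-weighted by default: each sequence counts once no matter how many
of its structures fall in the cluster, which keeps heavily crystallised
kinases from inflating purity.  A cluster is an HPC when its purity reaches
the threshold (default 1.0, the strictest possible), its mean silhouette is
non-negative (malformed, overlapping clusters are rejected) and it contains
at least one known label.  An HPC's majority label is the vote it casts for
its unlabeled members.

The cross-family analysis counts, per compound, how many true-labelled HPCs
contain sequences from two or more phylogenetic families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from .clustering import ClusteringCollection
from .io_model import AlignedStructureSet, LabelTable

__all__ = [
    "HPCRecord",
    "ClusterPurityPoint",
    "label_purity",
    "select_hpcs",
    "hpc_label_array",
    "precompute_member_pairs",
    "purity_distribution",
    "count_cross_family_hpcs",
]


@dataclass
class HPCRecord:
    subset: tuple[int, ...]
    cluster_id: int
    majority_label: bool
    affinity_purity: float
    mean_silhouette: float
    member_sequence_ids: frozenset[str]
    member_structure_ids: frozenset[str]
    family_set: frozenset[str]
    n_known: int


@dataclass
class ClusterPurityPoint:
    subset: tuple[int, ...]
    cluster_id: int
    affinity_purity: float
    phylo_purity: float


def label_purity(labels: Iterable[Hashable]) -> tuple[float, Hashable]:
    """Purity and majority label of a multiset of known labels.

    purity = multiplicity of the most frequent label / multiset size.
    Ties resolve deterministically to the smallest label under sort order
    (for booleans: false before true).
    """
    counts = Counter(labels)
    if not counts:
        raise ValueError("label multiset is empty after removing unknowns")
    top = max(counts.values())
    majority = sorted(lab for lab, c in counts.items() if c == top)[0]
    return top / sum(counts.values()), majority


# ---------------------------------------------------------------------------
# vectorised per-cluster label statistics


def _member_pairs(coll: ClusteringCollection, member_idx: np.ndarray, s: int):
    """Unique (cluster, member) pairs for subset ``s``.

    ``member_idx`` maps each structure to its counting unit: the sequence
    index for sequence-weighted counting, or the structure index itself for
    structure-level counting.
    """
    key = coll.assignments[:, s].astype(np.int64) * (member_idx.max() + 1) + member_idx
    uniq = np.unique(key)
    return uniq // (member_idx.max() + 1), uniq % (member_idx.max() + 1)


def precompute_member_pairs(
    coll: ClusteringCollection, member_idx: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Unique (cluster, member) pairs per subset; label-independent.

    Computing these once lets cross-validation re-derive purity for every
    fold's masked label table without touching the clusterings again.
    """
    return [_member_pairs(coll, member_idx, s) for s in range(coll.n_subsets)]


def _cluster_counts(
    coll: ClusteringCollection,
    member_idx: np.ndarray,
    label_of_member: np.ndarray,
    s: int,
    pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Per-cluster true/false known-label counts for subset ``s``.

    ``label_of_member`` holds 1 (true), 0 (false) or -1 (unknown) per
    counting unit.  Returns (clusters, members, n_true, n_false) where the
    first two are the unique pair arrays for the subset.
    """
    K = int(coll.n_clusters[s])
    clusters, members = pairs[s] if pairs is not None else _member_pairs(
        coll, member_idx, s
    )
    lab = label_of_member[members]
    n_true = np.bincount(clusters[lab == 1], minlength=K)
    n_false = np.bincount(clusters[lab == 0], minlength=K)
    return clusters, members, n_true, n_false


def _label_vector(
    unit_ids: Sequence[str], labels: LabelTable, compound_id: str
) -> np.ndarray:
    known = labels.labels_for(compound_id)
    return np.array(
        [1 if known.get(u) is True else 0 if known.get(u) is False else -1
         for u in unit_ids],
        dtype=np.int8,
    )


def _counting_units(sset: AlignedStructureSet, sequence_weighted: bool):
    if sequence_weighted:
        return sset.sequence_index(), sset.unique_sequence_ids
    n = len(sset)
    return np.arange(n), sset.structure_ids


def hpc_label_array(
    coll: ClusteringCollection,
    sset: AlignedStructureSet,
    labels: LabelTable,
    compound_id: str,
    purity_threshold: float = 1.0,
    min_mean_silhouette: float = 0.0,
    sequence_weighted: bool = True,
    pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """(S, K_cap) int8 array: 1 true-HPC, 0 false-HPC, -1 not an HPC.

    This is the compact form used by vote tallying and cross-validation; it
    encodes exactly the same selection rule as :func:`select_hpcs`.
    ``pairs`` may carry the output of :func:`precompute_member_pairs` to
    avoid recomputing cluster membership across repeated calls.
    """
    member_idx, unit_ids = _counting_units(sset, sequence_weighted)
    if sequence_weighted:
        lab = _label_vector(unit_ids, labels, compound_id)
    else:
        lab = _label_vector(sset.sequence_ids, labels, compound_id)
    if not (lab >= 0).any():
        raise ValueError(f"no known labels for compound {compound_id!r}")
    S = coll.n_subsets
    out = np.full((S, coll.cluster_mean_sil.shape[1]), -1, dtype=np.int8)
    for s in range(S):
        K = int(coll.n_clusters[s])
        _, _, n_true, n_false = _cluster_counts(coll, member_idx, lab, s, pairs)
        known = n_true + n_false
        with np.errstate(invalid="ignore", divide="ignore"):
            purity = np.maximum(n_true, n_false) / known
        ok = (
            (known >= 1)
            & (purity >= purity_threshold - 1e-12)
            & (coll.cluster_mean_sil[s, :K] >= min_mean_silhouette)
        )
        # majority: ties (possible only below the default threshold) -> false
        out[s, :K][ok] = (n_true > n_false)[ok].astype(np.int8)
    return out


def select_hpcs(
    coll: ClusteringCollection,
    sset: AlignedStructureSet,
    labels: LabelTable,
    compound_id: str,
    purity_threshold: float = 1.0,
    min_mean_silhouette: float = 0.0,
    sequence_weighted: bool = True,
) -> list[HPCRecord]:
    """All HPCs across every subset clustering, as full records.

    Clusters whose known labels are all unknown are skipped; they can still
    receive votes as test members.
    """
    member_idx, unit_ids = _counting_units(sset, sequence_weighted)
    lab = (
        _label_vector(unit_ids, labels, compound_id)
        if sequence_weighted
        else _label_vector(sset.sequence_ids, labels, compound_id)
    )
    if not (lab >= 0).any():
        raise ValueError(f"no known labels for compound {compound_id!r}")
    seq_idx = sset.sequence_index()
    seq_ids = sset.unique_sequence_ids
    fam = dict(sset.family_map())
    fam.update(labels.family)
    struct_ids = np.array(sset.structure_ids)
    records: list[HPCRecord] = []
    for s in range(coll.n_subsets):
        K = int(coll.n_clusters[s])
        clusters, members, n_true, n_false = _cluster_counts(coll, member_idx, lab, s)
        known = n_true + n_false
        assign = coll.assignments[:, s]
        for c in range(K):
            if known[c] < 1:
                continue
            purity = max(n_true[c], n_false[c]) / known[c]
            mean_sil = float(coll.cluster_mean_sil[s, c])
            if purity < purity_threshold - 1e-12 or mean_sil < min_mean_silhouette:
                continue
            in_cluster = assign == c
            member_seq = frozenset(seq_ids[i] for i in np.unique(seq_idx[in_cluster]))
            families = frozenset(
                f for f in (fam.get(q) for q in member_seq) if f is not None
            )
            records.append(
                HPCRecord(
                    subset=coll.subsets[s],
                    cluster_id=c,
                    majority_label=bool(n_true[c] > n_false[c]),
                    affinity_purity=float(purity),
                    mean_silhouette=mean_sil,
                    member_sequence_ids=member_seq,
                    member_structure_ids=frozenset(struct_ids[in_cluster]),
                    family_set=families,
                    n_known=int(known[c]),
                )
            )
    return records


def purity_distribution(
    coll: ClusteringCollection,
    sset: AlignedStructureSet,
    labels: LabelTable,
    compound_id: str,
    sequence_weighted: bool = True,
) -> list[ClusterPurityPoint]:
    """(affinity purity, phylogenetic purity) for true-majority clusters.

    Only clusters with strictly more than half their known labels true are
    emitted.  Phylogenetic purity is the most frequent family's fraction
    over the cluster's sequences with a known family.
    """
    member_idx, unit_ids = _counting_units(sset, sequence_weighted)
    lab = (
        _label_vector(unit_ids, labels, compound_id)
        if sequence_weighted
        else _label_vector(sset.sequence_ids, labels, compound_id)
    )
    seq_idx = sset.sequence_index()
    seq_ids = sset.unique_sequence_ids
    fam = dict(sset.family_map())
    fam.update(labels.family)
    points: list[ClusterPurityPoint] = []
    for s in range(coll.n_subsets):
        K = int(coll.n_clusters[s])
        _, _, n_true, n_false = _cluster_counts(coll, member_idx, lab, s)
        known = n_true + n_false
        assign = coll.assignments[:, s]
        for c in range(K):
            if known[c] < 1 or n_true[c] * 2 <= known[c]:
                continue
            members = [seq_ids[i] for i in np.unique(seq_idx[assign == c])]
            fams = [fam[q] for q in members if fam.get(q) is not None]
            phylo = label_purity(fams)[0] if fams else 0.0
            points.append(
                ClusterPurityPoint(
                    subset=coll.subsets[s],
                    cluster_id=c,
                    affinity_purity=float(n_true[c] / known[c]),
                    phylo_purity=float(phylo),
                )
            )
    return points


def count_cross_family_hpcs(
    hpcs: Iterable[HPCRecord], families: dict[str, str] | None = None
) -> tuple[int, int]:
    """(number of true-HPCs, number spanning >= 2 families).

    ``families`` optionally overrides the family sets stored on the
    records.  Sequences with unknown family never contribute to spanning.
    """
    n_true = 0
    n_span = 0
    for h in hpcs:
        if not h.majority_label:
            continue
        n_true += 1
        fams = h.family_set
        if families is not None:
            fams = frozenset(
                f
                for f in (families.get(q) for q in h.member_sequence_ids)
                if f is not None
            )
        if len(fams) >= 2:
            n_span += 1
    return n_true, n_span
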