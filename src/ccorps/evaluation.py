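"""Cross-validation over sequence-identity folds and ranking metrics.

Folds are non-redundant sequence groups ("nr-clusters"): single-linkage
components of the graph joining sequence pairs whose identity over the
aligned domain reaches the threshold (default 70%).  Single linkage is
exactly the guarantee required — no test sequence shares >= threshold
identity with any training sequence.  Each nr-cluster is one fold; within a
fold the test sequences' labels are masked to unknown *before* HPC
selection, so no test label can leak into any purity computation.

Metrics are pooled (micro-averaged) across folds: ROC AUC, PR AUC
(trapezoidal), and the enrichment factor of the top-ranked fraction
(default 5%),

    EF = (actives_in_top / N_top) / (n_actives / N_total),

with N_top = ceil(fraction * N_total) and EF_max = N_total / n_actives (the
value a perfect ranking of all actives into the top bucket would reach).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import ClusteringCollection
from .hpc import hpc_label_array, precompute_member_pairs
from .io_model import AlignedStructureSet, LabelTable
from .prediction import (
    DegenerateModelError,
    Prediction,
    VoteVector,
    aggregate_to_sequence,
    predict,
    train_decision_boundary,
    votes_from_label_array,
)

__all__ = [
    "FoldPlan",
    "EvalReport",
    "pairwise_identity",
    "build_identity_folds",
    "cross_validate",
    "roc_pr",
    "roc_pr_points",
    "enrichment_factor",
]


@dataclass
class FoldPlan:
    identity_threshold: float
    nr_clusters: list[frozenset[str]]

    @property
    def folds(self) -> list[frozenset[str]]:
        return self.nr_clusters

    def __len__(self) -> int:
        return len(self.nr_clusters)


@dataclass
class EvalReport:
    compound_id: str
    roc_auc: float
    pr_auc: float
    ef: float
    ef_max: float
    ef_fraction: float
    n_pos: int
    n_neg: int
    predictions: list[tuple[str, bool, Prediction]] = field(default_factory=list)
    n_no_evidence: int = 0
    n_skipped_folds: int = 0


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where neither row is gapped."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    matches = valid = 0
    for ca, cb in zip(a, b):
        if ca in "-." or cb in "-.":
            continue
        valid += 1
        matches += ca == cb
    return matches / valid if valid else 0.0


def build_identity_folds(
    sequences: Mapping[str, str], threshold: float = 0.70
) -> FoldPlan:
    """Single-linkage identity groups; one fold per group.

    Output ordering is canonical (groups sorted by their smallest member),
    so the plan is invariant to input order.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences to build folds")
    parent = {i: i for i in ids}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i_pos, qi in enumerate(ids):
        for qj in ids[i_pos + 1 :]:
            if pairwise_identity(sequences[qi], sequences[qj]) >= threshold:
                ri, rj = find(qi), find(qj)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[str, set[str]] = {}
    for q in ids:
        groups.setdefault(find(q), set()).add(q)
    clusters = sorted((frozenset(g) for g in groups.values()), key=lambda g: min(g))
    return FoldPlan(identity_threshold=threshold, nr_clusters=clusters)


# ---------------------------------------------------------------------------
# metrics


def roc_pr(scores: Sequence[float], truth: Sequence[bool]) -> tuple[float, float]:
    """ROC AUC and PR AUC of a ranking; both classes must be present."""
    from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

    y = np.asarray(truth, bool)
    s = np.asarray(scores, float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute AUCs")
    roc = float(roc_auc_score(y, s))
    prec, rec, _ = precision_recall_curve(y, s)
    pr = float(auc(rec, prec))
    return roc, pr


def roc_pr_points(
    scores: Sequence[float], truth: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Curve point tables for plotting: (fpr, tpr) and (recall, precision)."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = np.asarray(truth, bool)
    s = np.asarray(scores, float)
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return np.column_stack([fpr, tpr]), np.column_stack([rec, prec])


def enrichment_factor(
    scores: Sequence[float],
    truth: Sequence[bool],
    fraction: float = 0.05,
) -> tuple[float, float]:
    """Enrichment factor of the top-ranked fraction and the maximum attainable.

    Targets are ranked by score descending (stable: ties keep input order).
    EF_max = N_total / n_actives, the enrichment of a ranking that puts
    every active at the top.
    """
    y = np.asarray(truth, bool)
    s = np.asarray(scores, float)
    n_total = len(y)
    n_act = int(y.sum())
    if n_act == 0:
        raise ValueError("enrichment is undefined with zero actives")
    n_top = max(1, math.ceil(fraction * n_total))
    order = np.argsort(-s, kind="stable")
    top_actives = int(y[order[:n_top]].sum())
    ef = (top_actives / n_top) / (n_act / n_total)
    ef_max = n_total / n_act
    return float(ef), float(ef_max)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    sset: AlignedStructureSet,
    labels: LabelTable,
    compound_id: str,
    plan: FoldPlan,
    coll: ClusteringCollection,
    purity_threshold: float = 1.0,
    min_mean_silhouette: float = 0.0,
    sequence_weighted: bool = True,
    svm_C: float = 1.0,
    ef_fraction: float = 0.05,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-nr-cluster-out evaluation, pooled across folds.

    Per fold: the fold's sequences are masked to unknown, HPCs are
    re-selected from the masked table, a decision boundary is trained on
    the remaining labeled structures' votes, and the fold's sequences are
    scored.  The clusterings themselves are label-independent and therefore
    shared across folds.
    """
    known = labels.labels_for(compound_id)
    if len(set(known.values())) < 2:
        raise ValueError("compound must have known labels of both classes")
    seq_ids = np.array(sset.sequence_ids)
    member_idx = (
        sset.sequence_index() if sequence_weighted else np.arange(len(sset))
    )
    pairs = precompute_member_pairs(coll, member_idx)
    pooled: list[tuple[str, bool, Prediction]] = []
    n_no_evidence = 0
    n_skipped = 0
    for fold in plan.nr_clusters:
        test_seqs = {q for q in fold if q in known}
        if not test_seqs:
            continue
        masked = labels.masked(test_seqs, compound_id)
        train_known = masked.labels_for(compound_id)
        if len(set(train_known.values())) < 2:
            n_skipped += 1
            continue
        hpc_labels = hpc_label_array(
            coll,
            sset,
            masked,
            compound_id,
            purity_threshold=purity_threshold,
            min_mean_silhouette=min_mean_silhouette,
            sequence_weighted=sequence_weighted,
            pairs=pairs,
        )
        counts = votes_from_label_array(coll, hpc_labels)
        votes = [
            VoteVector(sid, {False: int(c[0]), True: int(c[1])}, coll.n_subsets)
            for sid, c in zip(coll.structure_ids, counts)
        ]
        train_rows = [
            i
            for i, q in enumerate(seq_ids)
            if q in train_known and votes[i].total > 0
        ]
        y_train = [train_known[seq_ids[i]] for i in train_rows]
        if len(set(y_train)) < 2:
            n_skipped += 1
            continue
        model = train_decision_boundary(
            [votes[i] for i in train_rows], y_train, C=svm_C, seed=seed
        )
        test_rows = [i for i, q in enumerate(seq_ids) if q in test_seqs]
        struct_preds = predict(model, [votes[i] for i in test_rows])
        seq_of = {votes[i].structure_id: seq_ids[i] for i in test_rows}
        for p in aggregate_to_sequence(struct_preds, seq_of):
            if p.predicted_label is None:
                n_no_evidence += 1
                continue
            pooled.append((p.id, known[p.id], p))
    if not pooled:
        raise ValueError("cross-validation produced no scored predictions")
    truths = [t for _, t, _ in pooled]
    dvs = [p.decision_value for _, _, p in pooled]
    confs = [p.confidence for _, _, p in pooled]
    roc, pr = roc_pr(dvs, truths)
    ef, ef_max = enrichment_factor(confs, truths, ef_fraction)
    return EvalReport(
        compound_id=compound_id,
        roc_auc=roc,
        pr_auc=pr,
        ef=ef,
        ef_max=ef_max,
        ef_fraction=ef_fraction,
        n_pos=int(sum(truths)),
        n_neg=int(len(truths) - sum(truths)),
        predictions=pooled,
        n_no_evidence=n_no_evidence,
        n_skipped_folds=n_skipped,
    )
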