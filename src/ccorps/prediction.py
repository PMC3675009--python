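"""Vote tallying and the linear-SVM decision boundary.

Every time a structure's cluster in some subset clustering is an HPC, the
structure receives one vote for that HPC's majority label — at most one
vote per subset, so each label's count is bounded by C(P, 3).  The
resulting 2-D (false, true) vote vectors of the labeled structures train a
linear-kernel SVM; unlabeled structures are classified by the side of the
hyperplane their vote vector falls on.  Confidences are calibrated
probabilities from a sigmoid (Platt) fit on the training decision values;
their ranking, not their absolute value, drives enrichment analysis.

Structures that never fall inside any HPC carry no evidence either way;
they are excluded from classification and reported with the label
``no-evidence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .clustering import ClusteringCollection
from .hpc import HPCRecord

__all__ = [
    "VoteVector",
    "DecisionModel",
    "Prediction",
    "DegenerateModelError",
    "tally_votes",
    "votes_from_label_array",
    "train_decision_boundary",
    "predict",
    "aggregate_to_sequence",
]


class DegenerateModelError(ValueError):
    """Training set contains a single class; no boundary can be fitted."""


@dataclass
class VoteVector:
    structure_id: str
    votes: dict[bool, int]
    n_clusterings: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.votes.values()):
            raise ValueError("vote counts must be non-negative")
        if any(v > self.n_clusterings for v in self.votes.values()):
            raise ValueError("a label's votes cannot exceed the subset count")

    @property
    def total(self) -> int:
        return sum(self.votes.values())

    @property
    def as_array(self) -> np.ndarray:
        # feature order: (false votes, true votes)
        return np.array([self.votes.get(False, 0), self.votes.get(True, 0)], float)


@dataclass
class DecisionModel:
    svm: SVC
    calibration: LogisticRegression
    C: float
    seed: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(X)

    def confidences(self, decision_values: np.ndarray) -> np.ndarray:
        return self.calibration.predict_proba(
            np.asarray(decision_values, float).reshape(-1, 1)
        )[:, 1]


@dataclass
class Prediction:
    id: str
    predicted_label: bool | None  # None marks a no-evidence target
    decision_value: float
    confidence: float
    votes_false: int = 0
    votes_true: int = 0

    @property
    def label_text(self) -> str:
        if self.predicted_label is None:
            return "no-evidence"
        return "true" if self.predicted_label else "false"


def votes_from_label_array(
    coll: ClusteringCollection,
    hpc_labels: np.ndarray,
    target_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """(n_targets, 2) array of (false, true) vote counts.

    ``hpc_labels`` is the (S, K_cap) array from
    :func:`ccorps.hpc.hpc_label_array`.  A target gains one vote per subset
    whose cluster (the one the target sits in) is an HPC.
    """
    idx = (
        np.arange(len(coll.structure_ids))
        if target_indices is None
        else np.asarray(target_indices)
    )
    assign = coll.assignments[idx]  # (n, S)
    lab = hpc_labels[np.arange(coll.n_subsets)[None, :], assign]  # (n, S)
    return np.stack([(lab == 0).sum(axis=1), (lab == 1).sum(axis=1)], axis=1)


def tally_votes(
    hpcs: Iterable[HPCRecord],
    coll: ClusteringCollection,
    target_ids: Sequence[str] | None = None,
) -> list[VoteVector]:
    """Per-target HPC vote counts, at most one vote per subset per target."""
    subset_index = {s: i for i, s in enumerate(coll.subsets)}
    hpc_labels = np.full(
        (coll.n_subsets, coll.cluster_mean_sil.shape[1]), -1, dtype=np.int8
    )
    for h in hpcs:
        hpc_labels[subset_index[h.subset], h.cluster_id] = int(h.majority_label)
    id_index = {sid: i for i, sid in enumerate(coll.structure_ids)}
    ids = list(target_ids) if target_ids is not None else coll.structure_ids
    counts = votes_from_label_array(coll, hpc_labels, [id_index[t] for t in ids])
    return [
        VoteVector(
            structure_id=t,
            votes={False: int(c[0]), True: int(c[1])},
            n_clusterings=coll.n_subsets,
        )
        for t, c in zip(ids, counts)
    ]


def train_decision_boundary(
    train_votes: Sequence[VoteVector] | np.ndarray,
    labels: Sequence[bool],
    C: float = 1.0,
    seed: int = 0,
) -> DecisionModel:
    """Maximum-margin linear classifier on the 2-D vote space.

    Decision values are signed so positive means true.  A sigmoid mapping
    from decision value to probability is fitted on the training decision
    values for confidence ranking.
    """
    X = (
        np.array([v.as_array for v in train_votes])
        if train_votes and isinstance(train_votes[0], VoteVector)
        else np.asarray(train_votes, float)
    )
    y = np.asarray(labels, bool)
    if len(set(y.tolist())) < 2:
        raise DegenerateModelError("training set needs an example of each label")
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(X, y)
    dv = svm.decision_function(X)
    calib = LogisticRegression(random_state=seed)
    calib.fit(dv.reshape(-1, 1), y)
    return DecisionModel(svm=svm, calibration=calib, C=C, seed=seed)


def predict(
    model: DecisionModel, votes: Sequence[VoteVector]
) -> list[Prediction]:
    """Classify vote vectors by hyperplane side.

    A decision value of exactly zero resolves to false (conservative for a
    binding claim).  Zero-vote targets are returned flagged as no-evidence
    with NaN decision value; callers exclude them from metrics.
    """
    preds: list[Prediction] = []
    scored = [(i, v) for i, v in enumerate(votes) if v.total > 0]
    dv_map: dict[int, float] = {}
    conf_map: dict[int, float] = {}
    if scored:
        X = np.array([v.as_array for _, v in scored])
        dv = model.decision_values(X)
        conf = model.confidences(dv)
        for (i, _), d, c in zip(scored, dv, conf):
            dv_map[i], conf_map[i] = float(d), float(c)
    for i, v in enumerate(votes):
        if v.total == 0:
            preds.append(
                Prediction(
                    id=v.structure_id,
                    predicted_label=None,
                    decision_value=float("nan"),
                    confidence=float("nan"),
                    votes_false=v.votes.get(False, 0),
                    votes_true=v.votes.get(True, 0),
                )
            )
        else:
            preds.append(
                Prediction(
                    id=v.structure_id,
                    predicted_label=dv_map[i] > 0.0,
                    decision_value=dv_map[i],
                    confidence=conf_map[i],
                    votes_false=v.votes.get(False, 0),
                    votes_true=v.votes.get(True, 0),
                )
            )
    return preds


def aggregate_to_sequence(
    per_structure: Sequence[Prediction],
    sequence_of: Mapping[str, str],
) -> list[Prediction]:
    """Average structure-level decisions into per-sequence predictions.

    The sequence's decision value (and confidence) is the mean over its
    structures with evidence; the label follows the sign, with zero
    resolving to false.  Sequences whose structures are all no-evidence stay
    no-evidence.
    """
    groups: dict[str, list[Prediction]] = {}
    for p in per_structure:
        groups.setdefault(sequence_of[p.id], []).append(p)
    out: list[Prediction] = []
    for seq, preds in groups.items():
        scored = [p for p in preds if p.predicted_label is not None]
        if not scored:
            out.append(
                Prediction(seq, None, float("nan"), float("nan"))
            )
            continue
        dv = float(np.mean([p.decision_value for p in scored]))
        conf = float(np.mean([p.confidence for p in scored]))
        out.append(
            Prediction(
                id=seq,
                predicted_label=dv > 0.0,
                decision_value=dv,
                confidence=conf,
                votes_false=int(np.mean([p.votes_false for p in scored])),
                votes_true=int(np.mean([p.votes_true for p in scored])),
            )
        )
    return out
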