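"""Purity, HPC selection rules, and the cross-family analysis."""

from __future__ import annotations

import numpy as np
import pytest

from ccorps.clustering import ClusteringCollection
from ccorps.hpc import (
    HPCRecord,
    count_cross_family_hpcs,
    hpc_label_array,
    label_purity,
    purity_distribution,
    select_hpcs,
)
from ccorps.io_model import (
    AlignedStructure,
    AlignedStructureSet,
    LabelTable,
    ResidueSite,
)

COMPOUND = "c"


class TestLabelPurity:
    @pytest.mark.parametrize(
        "labels,purity,majority",
        [
            ([True, True, False], 2 / 3, True),
            (["AGC", "CAMK", "TK"], 1 / 3, "AGC"),
            ([True, True], 1.0, True),
            ([False], 1.0, False),
        ],
    )
    def test_examples(self, labels, purity, majority):
        p, m = label_purity(labels)
        assert p == pytest.approx(purity)
        assert m == majority

    def test_tie_resolves_to_smallest(self):
        p, m = label_purity([True, False])
        assert p == 0.5
        assert m is False

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            label_purity([])


def _mini(assignments_by_subset, mean_sils, families=None, n_structs=6):
    """Hand-built set + collection: sequence A has two structures."""
    seq_of = ["A", "A", "B", "C", "D", "E"][:n_structs]
    structures = []
    for i, seq in enumerate(seq_of):
        sites = [ResidueSite(c, "A", np.array([float(i), float(c), 0.0])) for c in range(4)]
        structures.append(AlignedStructure(f"st{i}", seq, (families or {}).get(seq), sites))
    sset = AlignedStructureSet(structures, [0, 1, 2, 3])
    S = len(assignments_by_subset)
    assignments = np.array(assignments_by_subset, dtype=np.int16).T
    n_clusters = np.array([a.max() + 1 for a in np.array(assignments_by_subset)], dtype=np.int32)
    k_cap = int(n_clusters.max())
    mean_sil = np.full((S, k_cap), np.nan, dtype=np.float32)
    for s, sils in enumerate(mean_sils):
        mean_sil[s, : len(sils)] = sils
    coll = ClusteringCollection(
        subsets=[(0, 1, s + 2) for s in range(S)],
        structure_ids=[st.structure_id for st in structures],
        assignments=assignments,
        n_clusters=n_clusters,
        point_silhouette=np.zeros((n_structs, S), dtype=np.float32),
        cluster_mean_sil=mean_sil,
        descriptors=[{} for _ in range(S)],
    )
    return sset, coll


class TestSelectHpcs:
    def test_pure_cluster_selected(self):
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]])
        labels = LabelTable(entries={("C", COMPOUND): True, ("D", COMPOUND): True})
        hpcs = select_hpcs(coll, sset, labels, COMPOUND)
        assert len(hpcs) == 1
        h = hpcs[0]
        assert h.majority_label is True
        assert h.cluster_id == 1
        assert h.member_sequence_ids == frozenset({"C", "D", "E"})
        assert h.n_known == 2

    def test_negative_silhouette_rejected(self):
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, -0.1]])
        labels = LabelTable(entries={("C", COMPOUND): True, ("D", COMPOUND): True})
        assert select_hpcs(coll, sset, labels, COMPOUND) == []

    def test_mixed_cluster_rejected_at_full_purity(self):
        sset, coll = _mini([[0, 0, 0, 0, 0, 1]], [[0.3, 0.3]])
        labels = LabelTable(
            entries={
                ("A", COMPOUND): True,
                ("B", COMPOUND): True,
                ("C", COMPOUND): True,
                ("D", COMPOUND): False,
            }
        )
        assert select_hpcs(coll, sset, labels, COMPOUND) == []
        # relaxing the threshold admits the 3/4-true cluster
        relaxed = select_hpcs(coll, sset, labels, COMPOUND, purity_threshold=0.75)
        assert len(relaxed) == 1 and relaxed[0].majority_label is True

    def test_sequence_weighting_counts_each_sequence_once(self):
        # cluster 0 holds both structures of A (true) and one of B (false):
        # sequence-weighted purity is a 1:1 tie -> not an HPC; counting
        # structures instead gives 2/3 true
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]])
        labels = LabelTable(
            entries={
                ("A", COMPOUND): True,
                ("B", COMPOUND): False,
                ("C", COMPOUND): True,
                ("D", COMPOUND): True,
            }
        )
        seq_w = select_hpcs(coll, sset, labels, COMPOUND, purity_threshold=0.6)
        assert [h.cluster_id for h in seq_w] == [1]
        struct_w = select_hpcs(
            coll, sset, labels, COMPOUND, purity_threshold=0.6, sequence_weighted=False
        )
        assert sorted(h.cluster_id for h in struct_w) == [0, 1]

    def test_unknown_only_cluster_skipped(self):
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]])
        labels = LabelTable(entries={("A", COMPOUND): True, ("B", COMPOUND): True})
        hpcs = select_hpcs(coll, sset, labels, COMPOUND)
        # cluster 1 has only unknown labels; cluster 0 is pure true
        assert [h.cluster_id for h in hpcs] == [0]

    def test_monotone_in_purity_threshold(self, worked_coll, worked_example):
        sset, labels = worked_example
        counts = []
        for thr in (0.5, 0.75, 0.9, 1.0):
            counts.append(
                len(select_hpcs(worked_coll, sset, labels, "example-inhibitor",
                                purity_threshold=thr))
            )
        assert counts == sorted(counts, reverse=True)

    def test_absent_compound_rejected(self):
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]])
        with pytest.raises(ValueError):
            select_hpcs(coll, sset, LabelTable(), "nope")

    def test_label_array_agrees_with_records(self, worked_coll, worked_example):
        sset, labels = worked_example
        hpcs = select_hpcs(worked_coll, sset, labels, "example-inhibitor")
        arr = hpc_label_array(worked_coll, sset, labels, "example-inhibitor")
        expected = {(h.subset, h.cluster_id): int(h.majority_label) for h in hpcs}
        for s, subset in enumerate(worked_coll.subsets):
            for c in range(int(worked_coll.n_clusters[s])):
                assert arr[s, c] == expected.get((subset, c), -1)


class TestPurityDistribution:
    def test_true_majority_points(self):
        families = {"A": "TK", "B": "TK", "C": "AGC", "D": "CAMK", "E": "TK"}
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]], families=families)
        labels = LabelTable(
            entries={
                ("C", COMPOUND): True,
                ("D", COMPOUND): True,
                ("E", COMPOUND): True,
                ("A", COMPOUND): True,
                ("B", COMPOUND): False,
            },
            family=families,
        )
        points = purity_distribution(coll, sset, labels, COMPOUND)
        # cluster 0 is a 50/50 tie: excluded by the strict-majority rule
        assert [p.cluster_id for p in points] == [1]
        p = points[0]
        assert p.affinity_purity == pytest.approx(1.0)
        # cluster 1 families: AGC, CAMK, TK -> most frequent fraction 1/3
        assert p.phylo_purity == pytest.approx(1 / 3)

    def test_single_family_cluster(self):
        families = {"C": "TK", "D": "TK", "E": "TK"}
        sset, coll = _mini([[0, 0, 0, 1, 1, 1]], [[0.4, 0.5]], families=families)
        labels = LabelTable(
            entries={("C", COMPOUND): True, ("D", COMPOUND): True}, family=families
        )
        points = purity_distribution(coll, sset, labels, COMPOUND)
        assert points[0].affinity_purity == 1.0
        assert points[0].phylo_purity == 1.0


def _hpc(majority, families, subset=(0, 1, 2), cluster_id=0):
    members = frozenset(f"q{i}" for i in range(len(families)))
    return HPCRecord(
        subset=subset,
        cluster_id=cluster_id,
        majority_label=majority,
        affinity_purity=1.0,
        mean_silhouette=0.5,
        member_sequence_ids=members,
        member_structure_ids=members,
        family_set=frozenset(families),
        n_known=len(families),
    )


class TestCrossFamilyCounts:
    def test_examples(self):
        hpcs = [
            _hpc(True, ["TK"]),
            _hpc(True, ["TK", "AGC"], cluster_id=1),
            _hpc(True, ["CMGC"], cluster_id=2),
        ]
        assert count_cross_family_hpcs(hpcs) == (3, 1)

    def test_empty(self):
        assert count_cross_family_hpcs([]) == (0, 0)

    def test_false_hpcs_ignored(self):
        hpcs = [_hpc(False, ["TK", "AGC"]), _hpc(True, ["TK"], cluster_id=1)]
        assert count_cross_family_hpcs(hpcs) == (1, 0)

    def test_order_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        fams = ["TK", "AGC", "CMGC", "CK1"]
        hpcs = [
            _hpc(bool(rng.integers(2)),
                 list(rng.choice(fams, size=rng.integers(1, 4), replace=False)),
                 cluster_id=i)
            for i in range(20)
        ]
        n_true, n_span = count_cross_family_hpcs(hpcs)
        assert n_span <= n_true
        shuffled = list(hpcs)
        rng.shuffle(shuffled)
        assert count_cross_family_hpcs(shuffled) == (n_true, n_span)
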