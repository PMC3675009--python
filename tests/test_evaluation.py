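"""Identity folds, ranking metrics, and the leakage-free CV contract."""

from __future__ import annotations

import numpy as np
import pytest

from ccorps.evaluation import (
    build_identity_folds,
    cross_validate,
    enrichment_factor,
    pairwise_identity,
    roc_pr,
)


class TestPairwiseIdentity:
    def test_gap_columns_excluded(self):
        assert pairwise_identity("AV-K", "AVG-") == pytest.approx(1.0)
        assert pairwise_identity("AVKL", "AVGG") == pytest.approx(0.5)

    def test_no_overlap(self):
        assert pairwise_identity("A---", "-AAA") == 0.0


class TestIdentityFolds:
    def test_identical_sequences_share_fold(self):
        plan = build_identity_folds({"a": "AVKL", "b": "AVKL", "c": "GGGG"}, 0.7)
        fold_of = {q: i for i, f in enumerate(plan.folds) for q in f}
        assert fold_of["a"] == fold_of["b"] != fold_of["c"]

    def test_single_linkage_transitive(self):
        # A~B and B~C exceed the threshold, A~C does not; single linkage
        # still puts all three in one group (transitive closure)
        seqs = {
            "A": "AAAAAAAAAA",
            "B": "CAAAAAAAAA",  # A-B identity 0.9
            "C": "CDDDAAAAAA",  # B-C identity 0.7, A-C identity 0.6
        }
        assert pairwise_identity(seqs["A"], seqs["B"]) == pytest.approx(0.9)
        assert pairwise_identity(seqs["B"], seqs["C"]) == pytest.approx(0.7)
        assert pairwise_identity(seqs["A"], seqs["C"]) == pytest.approx(0.6)
        plan = build_identity_folds(seqs, 0.7)
        assert len(plan.folds) == 1

    def test_lower_threshold_groups_are_unions(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("AVKL"))
        seqs = {
            f"s{i}": "".join(rng.choice(alphabet, size=12)) for i in range(15)
        }
        loose = build_identity_folds(seqs, 0.5)
        strict = build_identity_folds(seqs, 0.7)
        for g in strict.folds:
            assert any(g <= big for big in loose.folds)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        alphabet = np.array(list("AVKL"))
        seqs = {f"s{i}": "".join(rng.choice(alphabet, size=10)) for i in range(12)}
        a = build_identity_folds(seqs, 0.6)
        shuffled = {k: seqs[k] for k in reversed(list(seqs))}
        b = build_identity_folds(shuffled, 0.6)
        assert a.nr_clusters == b.nr_clusters

    def test_partition(self):
        seqs = {f"s{i}": "AVKL" if i % 2 else "GGGG" for i in range(8)}
        plan = build_identity_folds(seqs, 0.7)
        all_ids = sorted(q for f in plan.folds for q in f)
        assert all_ids == sorted(seqs)


class TestRocPr:
    def test_perfect_and_reversed(self):
        truth = [True] * 5 + [False] * 5
        scores = [1.0 - 0.01 * i for i in range(10)]
        roc, pr = roc_pr(scores, truth)
        assert roc == 1.0
        assert pr == pytest.approx(1.0, abs=1e-9)
        roc_rev, _ = roc_pr([-s for s in scores], truth)
        assert roc_rev == 0.0

    def test_matches_concordance_oracle(self):
        # ROC AUC equals the Mann-Whitney all-pairs concordance statistic
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = rng.normal(size=n) + truth
            pos = scores[truth]
            neg = scores[~truth]
            conc = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            roc, _ = roc_pr(scores, truth)
            assert roc == pytest.approx(conc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([0.1, 0.2], [True, True])


class TestEnrichmentFactor:
    def test_perfect_enrichment(self):
        truth = [True] * 5 + [False] * 95
        scores = list(range(100, 0, -1))
        ef, ef_max = enrichment_factor(scores, truth, 0.05)
        assert ef == pytest.approx(20.0)
        assert ef_max == pytest.approx(20.0)

    def test_zero_actives_in_top(self):
        truth = [False] * 95 + [True] * 5
        scores = list(range(100, 0, -1))
        ef, ef_max = enrichment_factor(scores, truth, 0.05)
        assert ef == 0.0
        assert ef_max == pytest.approx(20.0)

    def test_random_ranking_near_one(self):
        rng = np.random.default_rng(3)
        truth = np.array([True] * 20 + [False] * 80)
        efs = []
        for _ in range(1000):
            scores = rng.random(100)
            ef, _ = enrichment_factor(scores, truth, 0.05)
            efs.append(ef)
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            truth = rng.random(n) < 0.3
            if not truth.any():
                continue
            ef, ef_max = enrichment_factor(rng.random(n), truth, 0.1)
            assert 0.0 <= ef <= ef_max + 1e-9

    def test_zero_actives_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor([0.1, 0.2], [False, False], 0.5)


class TestCrossValidate:
    def test_small_planted_recovery(self, small_synth, small_synth_coll):
        config, sset, labels, truth = small_synth
        plan = build_identity_folds(sset.aligned_sequences(), 0.70)
        report = cross_validate(
            sset, labels, config.compound_id, plan, small_synth_coll, seed=config.seed
        )
        assert report.roc_auc >= 0.9
        assert report.n_pos > 0 and report.n_neg > 0

    def test_masking_is_leakproof(self, small_synth, small_synth_coll):
        # the masked view seen by HPC selection is independent of the test
        # sequences' labels: flipping every hidden label before masking
        # leaves the selected HPCs bit-identical
        from ccorps.hpc import hpc_label_array
        from ccorps.io_model import LabelTable

        config, sset, labels, _ = small_synth
        known = labels.labels_for(config.compound_id)
        test_seqs = sorted(known)[:5]
        flipped = LabelTable(
            entries={
                (q, comp): (not lab if q in test_seqs else lab)
                for (q, comp), lab in labels.entries.items()
            },
            family=dict(labels.family),
        )
        arr_masked = hpc_label_array(
            small_synth_coll, sset,
            labels.masked(test_seqs, config.compound_id), config.compound_id,
        )
        arr_flipped = hpc_label_array(
            small_synth_coll, sset,
            flipped.masked(test_seqs, config.compound_id), config.compound_id,
        )
        assert np.array_equal(arr_masked, arr_flipped)

    def test_fold_with_single_class_skipped(self, small_synth, small_synth_coll):
        from ccorps.io_model import LabelTable

        config, sset, labels, _ = small_synth
        known = labels.labels_for(config.compound_id)
        # keep one false label only: every fold missing it trains single-class
        trues = [q for q, v in known.items() if v]
        falses = [q for q, v in known.items() if not v]
        entries = {(q, config.compound_id): True for q in trues}
        entries[(falses[0], config.compound_id)] = False
        lt = LabelTable(entries=entries, family=dict(labels.family))
        plan = build_identity_folds(sset.aligned_sequences(), 0.70)
        with pytest.raises(ValueError):
            # a single false sequence: the fold containing it cannot train,
            # every other fold predicts but pooled truth is single-class
            cross_validate(sset, lt, config.compound_id, plan, small_synth_coll)
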