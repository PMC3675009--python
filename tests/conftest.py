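"""Shared fixtures: the hand-written worked example, its clusterings, and
the session-scoped planted-signal recovery experiment."""

from __future__ import annotations

import numpy as np
import pytest

import ccorps
from ccorps.distance import column_subsets, default_pharm_matrix
from ccorps.synthetic import SynthConfig, generate, worked_example_fixture

COMPOUND = "example-inhibitor"


@pytest.fixture(scope="session")
def pharm():
    return default_pharm_matrix()


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_coll(worked_example, pharm):
    sset, _ = worked_example
    subsets = column_subsets(sset.position_columns, 3)
    return ccorps.compute_all_clusterings(sset, subsets, pharm, seed=1)


@pytest.fixture(scope="session")
def small_synth():
    """Compact planted dataset: one signal triple over an 8-position site."""
    config = SynthConfig(
        n_sequences=30,
        P=8,
        signal_subsets=((1, 4, 6),),
        fraction_unlabeled=0.2,
        seed=11,
    )
    return config, *generate(config)


@pytest.fixture(scope="session")
def small_synth_coll(small_synth, pharm):
    config, sset, labels, truth = small_synth
    subsets = column_subsets(sset.position_columns, 3)
    return ccorps.compute_all_clusterings(sset, subsets, pharm, seed=config.seed)


@pytest.fixture(scope="session")
def recovery_experiment(pharm):
    """Full-scale planted-signal recovery: defaults (60 sequences, P=27,
    two signal triples, 0.1 A jitter), all 2925 subset clusterings, then
    identity-fold cross-validation.  Shared across the acceptance tests.
    """
    from ccorps.evaluation import build_identity_folds, cross_validate

    config = SynthConfig(seed=7)
    sset, labels, truth = generate(config)
    subsets = column_subsets(sset.position_columns, 3)
    coll = ccorps.compute_all_clusterings(sset, subsets, pharm, seed=config.seed)
    plan = build_identity_folds(sset.aligned_sequences(), 0.70)
    report = cross_validate(
        sset, labels, config.compound_id, plan, coll, seed=config.seed
    )
    return {
        "config": config,
        "sset": sset,
        "labels": labels,
        "truth": truth,
        "coll": coll,
        "plan": plan,
        "report": report,
    }
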