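"""End-to-end orchestration: cluster -> select HPCs -> vote -> predict ->
evaluate -> cross-family report.

Subset clusterings depend only on structures, never on labels, so they are
computed once per dataset, cached on disk, and shared by every compound.
Compounds are processed fully independently: adding or removing one never
changes another's outputs.  All stage outputs are CSV/JSON with fixed
number formatting, so identical config + seed reproduce byte-identical
files regardless of worker count.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import clustering as _clustering
from .clustering import ClusteringCollection, compute_all_clusterings
from .distance import PharmMatrix, column_subsets, default_pharm_matrix, load_pharm_matrix
from .evaluation import EvalReport, build_identity_folds, cross_validate
from .hpc import HPCRecord, count_cross_family_hpcs, select_hpcs
from .io_model import (
    AlignedStructureSet,
    LabelTable,
    read_family_csv,
    read_label_csv,
    read_msa,
    read_site_table,
)
from .prediction import DegenerateModelError, Prediction, predict, tally_votes, train_decision_boundary

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_full",
    "report_cross_family",
    "load_reference_hpc_table",
    "summarize_reference_hpc_table",
    "load_dataset_summary",
    "write_hpc_csv",
    "write_predictions_csv",
]

_FMT = "%.6g"  # canonical float formatting for byte-stable outputs


def _f(x: float) -> str:
    return _FMT % float(x)


@dataclass
class RunConfig:
    """Flat configuration for a full run (YAML-serialisable)."""

    sites: str
    labels: str
    output_dir: str
    alignment: str | None = None
    families: str | None = None
    pharm_matrix: str | None = None
    w_struct: float = 1.0
    w_pharm: float = 1.0
    variance_target: float = 0.90
    d_max: int = 10
    k_max: int = _clustering.DEFAULT_K_MAX
    n_init: int = _clustering.DEFAULT_N_INIT
    bic_patience: int | None = _clustering.DEFAULT_BIC_PATIENCE
    purity_threshold: float = 1.0
    min_mean_silhouette: float = 0.0
    sequence_weighted: bool = True
    svm_C: float = 1.0
    cv_identity_threshold: float = 0.70
    run_cv: bool = False
    ef_fraction: float = 0.05
    compounds: list[str] | None = None
    subset_size: int = 3
    seed: int = 0
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        os.replace(tmp, path)


# ---------------------------------------------------------------------------
# caching


def _dataset_hash(config: RunConfig) -> str:
    h = hashlib.sha256()
    h.update(Path(config.sites).read_bytes())
    key = {
        "pharm_matrix": config.pharm_matrix,
        "w_struct": config.w_struct,
        "w_pharm": config.w_pharm,
        "variance_target": config.variance_target,
        "d_max": config.d_max,
        "k_max": config.k_max,
        "n_init": config.n_init,
        "bic_patience": config.bic_patience,
        "sequence_weighted": config.sequence_weighted,
        "subset_size": config.subset_size,
        "seed": config.seed,
    }
    h.update(json.dumps(key, sort_keys=True).encode())
    return h.hexdigest()[:16]


def compute_clusterings(
    sset: AlignedStructureSet,
    config: RunConfig,
    matrix: PharmMatrix,
    cache_dir: Path | None = None,
) -> ClusteringCollection:
    """Compute (or load from cache) every subset clustering of the dataset."""
    subsets = column_subsets(sset.position_columns, config.subset_size)
    cache_path = None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_path = cache_dir / f"clusterings_{_dataset_hash(config)}.npz"
        if cache_path.exists():
            return ClusteringCollection.load(cache_path)
    coll = compute_all_clusterings(
        sset,
        subsets,
        matrix,
        seed=config.seed,
        n_jobs=config.n_jobs,
        w_struct=config.w_struct,
        w_pharm=config.w_pharm,
        variance_target=config.variance_target,
        d_max=config.d_max,
        weighted_embedding=config.sequence_weighted,
        k_max=config.k_max,
        n_init=config.n_init,
        bic_patience=config.bic_patience,
    )
    if cache_path is not None:
        coll.save(cache_path)
    return coll


# ---------------------------------------------------------------------------
# stage output writers


def write_clustering_csv(coll: ClusteringCollection, path: str | Path) -> None:
    """structure_id, subset (1-based columns), cluster_id, silhouette."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure_id", "subset", "cluster_id", "silhouette"])
        for s, subset in enumerate(coll.subsets):
            label = "+".join(str(c + 1) for c in subset)
            for i, sid in enumerate(coll.structure_ids):
                w.writerow(
                    [sid, label, int(coll.assignments[i, s]),
                     _f(coll.point_silhouette[i, s])]
                )


def write_hpc_csv(
    hpcs: Iterable[HPCRecord], compound_id: str, path: str | Path
) -> None:
    """HPC table; alignment columns are reported 1-based."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["compound_id", "subset", "cluster_id", "majority_label", "purity",
             "mean_silhouette", "n_known", "member_sequence_ids", "family_set"]
        )
        rows = sorted(
            hpcs, key=lambda h: (h.subset, h.cluster_id)
        )
        for h in rows:
            w.writerow(
                [
                    compound_id,
                    "+".join(str(c + 1) for c in h.subset),
                    h.cluster_id,
                    "true" if h.majority_label else "false",
                    _f(h.affinity_purity),
                    _f(h.mean_silhouette),
                    h.n_known,
                    ";".join(sorted(h.member_sequence_ids)),
                    ";".join(sorted(h.family_set)),
                ]
            )


def write_predictions_csv(
    preds: Sequence[tuple[str, str, Prediction, bool | None]], path: str | Path
) -> None:
    """Rows of (id, level, prediction, truth-if-known)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "level", "votes_true", "votes_false", "decision_value",
             "confidence", "predicted_label", "truth"]
        )
        for pid, level, p, truth in preds:
            w.writerow(
                [
                    pid,
                    level,
                    p.votes_true,
                    p.votes_false,
                    "" if np.isnan(p.decision_value) else _f(p.decision_value),
                    "" if np.isnan(p.confidence) else _f(p.confidence),
                    p.label_text,
                    "" if truth is None else ("true" if truth else "false"),
                ]
            )


# ---------------------------------------------------------------------------
# cross-family report


def report_cross_family(
    hpc_tables: Mapping[str, Sequence[HPCRecord]],
    families: Mapping[str, str] | None = None,
) -> dict:
    """Per-compound (n true-HPCs, n spanning >= 2 families) plus totals."""
    rows = []
    for compound in sorted(hpc_tables):
        n_true, n_span = count_cross_family_hpcs(hpc_tables[compound], families)
        rows.append(
            {
                "compound_id": compound,
                "n_true_hpcs": n_true,
                "n_cross_family": n_span,
                "spanning_pct": 100.0 * n_span / n_true if n_true else 0.0,
            }
        )
    total_true = sum(r["n_true_hpcs"] for r in rows)
    total_span = sum(r["n_cross_family"] for r in rows)
    return {
        "rows": rows,
        "total_true_hpcs": total_true,
        "total_cross_family": total_span,
        "spanning_pct": 100.0 * total_span / total_true if total_true else 0.0,
    }


def write_cross_family_csv(report: dict, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "n_true_hpcs", "n_cross_family", "spanning_pct"])
        for r in report["rows"]:
            w.writerow(
                [r["compound_id"], r["n_true_hpcs"], r["n_cross_family"],
                 _f(r["spanning_pct"])]
            )
        w.writerow(
            ["TOTAL", report["total_true_hpcs"], report["total_cross_family"],
             _f(report["spanning_pct"])]
        )


# ---------------------------------------------------------------------------
# packaged reference tables (published kinome study statistics)


def _data_path(name: str):
    return resources.files("ccorps.data").joinpath(name)


def load_reference_hpc_table() -> list[dict]:
    """Published per-inhibitor true-HPC counts for the human kinome study."""
    with _data_path("kinome_hpc_table.csv").open() as fh:
        return [
            {
                "compound_id": row["compound_id"],
                "n_true_hpcs": int(row["n_true_hpcs"]),
                "n_cross_family": int(row["n_cross_family"]),
            }
            for row in csv.DictReader(fh)
        ]


def summarize_reference_hpc_table(rows: list[dict] | None = None) -> dict:
    """Column sums and spanning percentages of the reference HPC table."""
    if rows is None:
        rows = load_reference_hpc_table()
    total_true = sum(r["n_true_hpcs"] for r in rows)
    total_span = sum(r["n_cross_family"] for r in rows)
    per_compound = {
        r["compound_id"]: (
            100.0 * r["n_cross_family"] / r["n_true_hpcs"]
            if r["n_true_hpcs"]
            else 0.0
        )
        for r in rows
    }
    return {
        "total_true_hpcs": total_true,
        "total_cross_family": total_span,
        "spanning_pct": 100.0 * total_span / total_true,
        "per_compound_pct": per_compound,
    }


def load_dataset_summary() -> dict:
    """Published kinome dataset bookkeeping: per-family rows plus totals."""
    with _data_path("kinome_dataset_summary.csv").open() as fh:
        rows = [
            {
                "family": r["family"],
                "n_structures": int(r["n_structures"]),
                "n_sequences": int(r["n_sequences"]),
                "n_annotated": int(r["n_annotated"]),
            }
            for r in csv.DictReader(fh)
        ]
    with _data_path("kinome_dataset_counts.json").open() as fh:
        counts = json.load(fh)
    return {"per_family": rows, **counts}


# ---------------------------------------------------------------------------
# full run


def run_full(config: RunConfig) -> RunManifest:
    """Execute every stage and write all outputs under ``config.output_dir``."""
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=_version())

    sset = read_site_table(config.sites)
    labels = read_label_csv(config.labels)
    if config.families:
        labels.family.update(read_family_csv(config.families))
    aligned = (
        read_msa(config.alignment) if config.alignment else sset.aligned_sequences()
    )
    manifest.stage_counts["n_structures"] = len(sset)
    manifest.stage_counts["n_sequences"] = len(sset.unique_sequence_ids)
    manifest.stage_counts["n_positions"] = len(sset.position_columns)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            {
                "input_filtering": sset.provenance,
                "n_structures": len(sset),
                "n_sequences": len(sset.unique_sequence_ids),
                "columns_1based": [c + 1 for c in sset.position_columns],
            },
            fh, indent=2, sort_keys=True,
        )

    matrix = (
        load_pharm_matrix(config.pharm_matrix)
        if config.pharm_matrix
        else default_pharm_matrix()
    )

    t0 = time.time()
    coll = compute_clusterings(sset, config, matrix, cache_dir=outdir / "cache")
    manifest.timings_s["clustering"] = round(time.time() - t0, 3)
    manifest.stage_counts["n_subset_clusterings"] = coll.n_subsets
    write_clustering_csv(coll, outdir / "clusterings.csv")
    with open(outdir / "model_descriptors.json", "w") as fh:
        json.dump(
            {
                "+".join(str(c + 1) for c in subset): desc
                for subset, desc in zip(coll.subsets, coll.descriptors)
            },
            fh, indent=2, sort_keys=True,
        )

    compounds = config.compounds or sorted(labels.compounds)
    hpc_tables: dict[str, list[HPCRecord]] = {}
    for compound in compounds:
        t0 = time.time()
        cdir = outdir / compound
        cdir.mkdir(exist_ok=True)
        hpcs = select_hpcs(
            coll, sset, labels, compound,
            purity_threshold=config.purity_threshold,
            min_mean_silhouette=config.min_mean_silhouette,
            sequence_weighted=config.sequence_weighted,
        )
        hpc_tables[compound] = hpcs
        write_hpc_csv(hpcs, compound, cdir / "hpcs.csv")
        manifest.stage_counts[f"{compound}/n_hpcs"] = len(hpcs)

        votes = tally_votes(hpcs, coll)
        known = labels.labels_for(compound)
        seq_of = dict(zip(sset.structure_ids, sset.sequence_ids))
        train = [
            (v, known[seq_of[v.structure_id]])
            for v in votes
            if seq_of[v.structure_id] in known and v.total > 0
        ]
        preds: list[Prediction]
        try:
            model = train_decision_boundary(
                [v for v, _ in train], [y for _, y in train],
                C=config.svm_C, seed=config.seed,
            )
            preds = predict(model, votes)
        except DegenerateModelError:
            majority = bool(
                sum(known.values()) * 2 >= len(known)
            ) if known else False
            manifest.warnings.append(
                f"{compound}: single-class training set; majority-label fallback"
            )
            preds = [
                Prediction(
                    id=v.structure_id,
                    predicted_label=(majority if v.total > 0 else None),
                    decision_value=(1.0 if majority else -1.0) if v.total else float("nan"),
                    confidence=0.5 if v.total else float("nan"),
                    votes_false=v.votes.get(False, 0),
                    votes_true=v.votes.get(True, 0),
                )
                for v in votes
            ]
        rows = [
            (p.id, "structure", p, known.get(seq_of[p.id])) for p in preds
        ]
        seq_preds = _aggregate(preds, seq_of)
        rows += [(p.id, "sequence", p, known.get(p.id)) for p in seq_preds]
        write_predictions_csv(rows, cdir / "predictions.csv")
        manifest.stage_counts[f"{compound}/n_no_evidence"] = sum(
            1 for p in preds if p.predicted_label is None
        )

        if config.run_cv:
            try:
                plan = build_identity_folds(aligned, config.cv_identity_threshold)
                report = cross_validate(
                    sset, labels, compound, plan, coll,
                    purity_threshold=config.purity_threshold,
                    min_mean_silhouette=config.min_mean_silhouette,
                    sequence_weighted=config.sequence_weighted,
                    svm_C=config.svm_C,
                    ef_fraction=config.ef_fraction,
                    seed=config.seed,
                )
                _write_eval(report, cdir / "evaluation.json")
            except ValueError as exc:
                manifest.warnings.append(f"{compound}: cross-validation skipped ({exc})")
        manifest.timings_s[f"{compound}"] = round(time.time() - t0, 3)

    report = report_cross_family(hpc_tables)
    write_cross_family_csv(report, outdir / "cross_family.csv")
    manifest.stage_counts["total_true_hpcs"] = report["total_true_hpcs"]
    manifest.stage_counts["total_cross_family"] = report["total_cross_family"]
    manifest.timings_s["total"] = round(time.time() - t_start, 3)
    manifest.write(outdir / "manifest.json")
    return manifest


def _aggregate(preds, seq_of):
    from .prediction import aggregate_to_sequence

    return aggregate_to_sequence(preds, {p.id: seq_of[p.id] for p in preds})


def _write_eval(report: EvalReport, path: Path) -> None:
    payload = {
        "compound_id": report.compound_id,
        "roc_auc": round(report.roc_auc, 6),
        "pr_auc": round(report.pr_auc, 6),
        "ef": round(report.ef, 6),
        "ef_max": round(report.ef_max, 6),
        "ef_fraction": report.ef_fraction,
        "n_pos": report.n_pos,
        "n_neg": report.n_neg,
        "n_no_evidence": report.n_no_evidence,
        "n_skipped_folds": report.n_skipped_folds,
        "per_sequence": [
            {
                "sequence_id": seq,
                "truth": bool(truth),
                "decision_value": round(p.decision_value, 6),
                "confidence": round(p.confidence, 6),
                "predicted_label": p.label_text,
            }
            for seq, truth, p in sorted(report.predictions)
        ],
    }
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    os.replace(tmp, path)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("ccorps")
    except Exception:
        return "unknown"
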