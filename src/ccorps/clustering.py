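"""Embedding and clustering of per-subset distance-matrix rows.

Each row of a subset's distance matrix describes one structure by its
dissimilarity to every other structure; the rows are highly redundant, so
they are projected to a few principal components before clustering.  A
Gaussian mixture is then fitted for a range of component counts and
covariance families, the model is chosen by BIC, and cluster cohesion is
scored with silhouettes in the embedding space.

Overrepresentation of sequences with many structures is corrected at the
embedding stage: the principal axes are fitted with per-row weights equal
to 1/(number of structures sharing the row's sequence), so a sequence with
a hundred crystal structures shapes the axes no more than a singleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .distance import DistanceMatrix, PharmMatrix, distance_matrix
from .io_model import AlignedStructureSet

__all__ = [
    "Embedding",
    "SubsetClustering",
    "ClusteringCollection",
    "embed_rows",
    "cluster_gmm",
    "silhouettes",
    "cluster_subset",
    "compute_all_clusterings",
    "subset_seed",
]

#: covariance families tried during model selection, simplest first
DEFAULT_COVARIANCES = ("spherical", "diag", "full")
DEFAULT_K_MAX = 25
DEFAULT_N_INIT = 2
#: consecutive BIC non-improvements before the K scan stops for a family
DEFAULT_BIC_PATIENCE = 2


@dataclass
class Embedding:
    subset: tuple[int, ...]
    coordinates: np.ndarray  # (N, d)
    explained_variance_fraction: float
    d: int


@dataclass
class SubsetClustering:
    subset: tuple[int, ...]
    assignments: np.ndarray  # (N,) ints in 0..K-1
    K: int
    per_point_silhouette: np.ndarray  # (N,)
    per_cluster_mean_silhouette: np.ndarray  # (K,)
    model_descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = np.bincount(self.assignments, minlength=self.K)
        if sizes.sum() != len(self.assignments):
            raise ValueError("cluster sizes must sum to N")


def embed_rows(
    dm: DistanceMatrix | np.ndarray,
    variance_target: float = 0.90,
    d_max: int = 10,
    row_weights: np.ndarray | None = None,
) -> Embedding:
    """Principal-component projection of the distance-matrix rows.

    ``d`` is the smallest dimensionality whose cumulative explained variance
    reaches ``variance_target``, capped at ``d_max`` and floored at 1.  When
    ``row_weights`` is given the axes are fitted on the weighted mean and
    weighted covariance (overrepresentation correction); all rows are then
    projected.  Component signs follow a canonical convention (the loading
    with the largest magnitude is positive) so results are reproducible to
    the byte.
    """
    if isinstance(dm, DistanceMatrix):
        rows, subset = dm.matrix, dm.subset
    else:
        rows, subset = np.asarray(dm, dtype=float), ()
    n = rows.shape[0]
    if n < 2:
        raise ValueError("at least two rows are required")
    if row_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(row_weights, dtype=float)
        w = w / w.sum()
    mean = w @ rows
    x = rows - mean
    cov = (x * w[:, None]).T @ x
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0.0:
        # all rows identical: a single dimension of zeros
        return Embedding(tuple(subset), np.zeros((n, 1)), 1.0, 1)
    cum = np.cumsum(evals) / total
    d = int(np.searchsorted(cum, variance_target) + 1)
    d = max(1, min(d, d_max, n))
    comps = evecs[:, :d]
    # canonical sign: largest-|loading| entry of each component is positive
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    comps = comps * flip
    coords = x @ comps
    return Embedding(tuple(subset), coords, float(cum[d - 1]), d)


def cluster_gmm(
    e: Embedding,
    k_max: int = DEFAULT_K_MAX,
    covariance_types: Sequence[str] = DEFAULT_COVARIANCES,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
    bic_patience: int | None = DEFAULT_BIC_PATIENCE,
) -> SubsetClustering:
    """Fit Gaussian mixtures over a K/covariance grid and select by BIC.

    Assignments are maximum-posterior.  Ties in BIC resolve to the smaller
    K, then to the simpler covariance family (the candidate grid is scanned
    in that order and only strict improvements replace the incumbent).
    ``bic_patience`` stops a family's K scan after that many consecutive
    non-improvements; pass None to scan every K.
    """
    x = e.coordinates
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two points to cluster")
    k_hi = min(k_max, n)
    best = None
    best_bic = np.inf
    failures = []
    for cov in covariance_types:
        family_best = np.inf
        stale = 0
        for k in range(1, k_hi + 1):
            try:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=cov,
                    n_init=n_init,
                    init_params="k-means++",
                    random_state=seed,
                    reg_covar=1e-6,
                ).fit(x)
            except Exception as exc:  # singular fits on degenerate data
                failures.append((cov, k, str(exc)))
                continue
            bic = gm.bic(x)
            if bic < best_bic - 1e-9:
                best_bic = bic
                best = (gm, cov, k)
            if bic < family_best - 1e-9:
                family_best = bic
                stale = 0
            else:
                stale += 1
                if bic_patience is not None and stale >= bic_patience:
                    break
    if best is None:
        raise RuntimeError(f"all mixture fits failed: {failures[:3]}")
    gm, cov, k = best
    raw = gm.predict(x)
    # relabel clusters by first appearance so output is order-canonical
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
    assignments = np.array([remap[lab] for lab in raw])
    K = len(remap)
    per_point, per_cluster = silhouettes(e, assignments)
    return SubsetClustering(
        subset=e.subset,
        assignments=assignments,
        K=K,
        per_point_silhouette=per_point,
        per_cluster_mean_silhouette=per_cluster,
        model_descriptor={
            "covariance_type": cov,
            "k_selected": K,
            "bic": float(best_bic),
            "embedding_d": e.d,
            "seed": seed,
        },
    )


def silhouettes(
    e: Embedding | np.ndarray, assignments: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point and per-cluster-mean silhouettes (Euclidean, embedding space).

    Conventions: a single cluster gives all zeros; points in singleton
    clusters score zero.
    """
    x = e.coordinates if isinstance(e, Embedding) else np.asarray(e, float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    K = int(assignments.max()) + 1 if len(assignments) else 0
    n = x.shape[0]
    if len(labels) <= 1 or n <= len(labels):
        per_point = np.zeros(n)
    else:
        from sklearn.metrics import silhouette_samples

        per_point = silhouette_samples(x, assignments)
        sizes = np.bincount(assignments, minlength=K)
        per_point[sizes[assignments] == 1] = 0.0
    per_cluster = np.array(
        [per_point[assignments == k].mean() if (assignments == k).any() else 0.0
         for k in range(K)]
    )
    return per_point, per_cluster


# ---------------------------------------------------------------------------
# bulk computation over all subsets


@dataclass
class ClusteringCollection:
    """All subset clusterings of one dataset in compact array form.

    ``assignments`` is (N, S): cluster id of structure i in subset s.
    ``cluster_mean_sil`` is (S, K_cap) with NaN past each subset's K.
    Rows follow the structure order of the originating set.
    """

    subsets: list[tuple[int, ...]]
    structure_ids: list[str]
    assignments: np.ndarray  # (N, S) int16
    n_clusters: np.ndarray  # (S,)
    point_silhouette: np.ndarray  # (N, S) float32
    cluster_mean_sil: np.ndarray  # (S, K_cap) float32, NaN padded
    descriptors: list[dict]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def clustering(self, s: int) -> SubsetClustering:
        K = int(self.n_clusters[s])
        return SubsetClustering(
            subset=self.subsets[s],
            assignments=self.assignments[:, s].astype(int),
            K=K,
            per_point_silhouette=self.point_silhouette[:, s].astype(float),
            per_cluster_mean_silhouette=self.cluster_mean_sil[s, :K].astype(float),
            model_descriptor=self.descriptors[s],
        )

    def save(self, path) -> None:
        import json

        np.savez_compressed(
            path,
            subsets=np.array(self.subsets),
            structure_ids=np.array(self.structure_ids),
            assignments=self.assignments,
            n_clusters=self.n_clusters,
            point_silhouette=self.point_silhouette,
            cluster_mean_sil=self.cluster_mean_sil,
            descriptors=np.array(
                [json.dumps(d, sort_keys=True) for d in self.descriptors]
            ),
        )

    @classmethod
    def load(cls, path) -> "ClusteringCollection":
        import json

        z = np.load(path, allow_pickle=False)
        return cls(
            subsets=[tuple(int(c) for c in row) for row in z["subsets"]],
            structure_ids=[str(s) for s in z["structure_ids"]],
            assignments=z["assignments"],
            n_clusters=z["n_clusters"],
            point_silhouette=z["point_silhouette"],
            cluster_mean_sil=z["cluster_mean_sil"],
            descriptors=[json.loads(str(s)) for s in z["descriptors"]],
        )


def subset_seed(master_seed: int, subset_index: int) -> int:
    """Deterministic per-subset seed, independent of worker scheduling."""
    return (master_seed * 1_000_003 + subset_index * 7_919 + 12_345) % (2**31 - 1)


def cluster_subset(
    sset: AlignedStructureSet,
    subset: Sequence[int],
    matrix: PharmMatrix,
    w_struct: float = 1.0,
    w_pharm: float = 1.0,
    variance_target: float = 0.90,
    d_max: int = 10,
    seed: int = 0,
    weighted_embedding: bool = True,
    **gmm_kwargs,
) -> SubsetClustering:
    """Distance matrix -> embedding -> GMM for one column subset."""
    dm = distance_matrix(sset, subset, matrix, w_struct, w_pharm)
    weights = sset.structure_weights() if weighted_embedding else None
    emb = embed_rows(dm, variance_target, d_max, row_weights=weights)
    return cluster_gmm(emb, seed=seed, **gmm_kwargs)


def compute_all_clusterings(
    sset: AlignedStructureSet,
    subsets: Sequence[Sequence[int]],
    matrix: PharmMatrix,
    seed: int = 0,
    n_jobs: int = 1,
    **kwargs,
) -> ClusteringCollection:
    """Cluster every subset; embarrassingly parallel and scheduling-invariant.

    Each subset uses a seed derived from the master seed and its index, so
    results are identical for any ``n_jobs``.
    """
    subsets = [tuple(s) for s in subsets]

    def one(i: int) -> SubsetClustering:
        return cluster_subset(
            sset, subsets[i], matrix, seed=subset_seed(seed, i), **kwargs
        )

    if n_jobs == 1:
        results = [one(i) for i in range(len(subsets))]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(one)(i) for i in range(len(subsets))
        )
    n = len(sset)
    S = len(subsets)
    k_cap = max(r.K for r in results)
    assignments = np.zeros((n, S), dtype=np.int16)
    n_clusters = np.zeros(S, dtype=np.int32)
    point_sil = np.zeros((n, S), dtype=np.float32)
    mean_sil = np.full((S, k_cap), np.nan, dtype=np.float32)
    for s, r in enumerate(results):
        assignments[:, s] = r.assignments
        n_clusters[s] = r.K
        point_sil[:, s] = r.per_point_silhouette
        mean_sil[s, : r.K] = r.per_cluster_mean_silhouette
    return ClusteringCollection(
        subsets=subsets,
        structure_ids=sset.structure_ids,
        assignments=assignments,
        n_clusters=n_clusters,
        point_silhouette=point_sil,
        cluster_mean_sil=mean_sil,
        descriptors=[r.model_descriptor for r in results],
    )
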