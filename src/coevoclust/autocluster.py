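"""Automated cluster definition: PCA, optimal-k voting, and k-means.

The automation replaces the manual reading of heatmaps and score plots:
each distance matrix (strict and combined) is embedded by a PCA of its rows
(each gene's distance profile), the first three principal components are
kept, a battery of cluster-validity indices votes on the optimal number of
clusters k (2..5) over Ward-linkage candidate partitions, and k-means with
the winning k — or a fixed k = 3 backup when the vote fails — produces the
final gene groups.  Genes sharing a cluster with the core enzyme(s) are the
"detected" co-evolved genes.

:class:`DistanceMatrixClusterer` packages the per-matrix pipeline as a
scikit-learn estimator (``fit(X)`` on a d x d distance matrix, fitted
attributes with trailing underscores); the module-level functions are thin
wrappers kept for script-style use.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from ._indices import EXCLUDED_INDICES, IMPLEMENTED_INDICES, compute_index_votes
from .coevo import combine_matrices
from .treedist import DistanceMatrixSet

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "ClusterResult",
    "PipelineConfig",
    "DistanceMatrixClusterer",
    "pca_scores",
    "index_votes",
    "optimal_k",
    "kmeans_cluster",
    "predict_clusters",
    "detected_genes",
    "cluster_table",
]


@dataclass
class Embedding:
    """First principal components of one distance matrix's row profiles."""

    gene_ids: list[str]
    scores: np.ndarray             # (d, n_components)
    variance_explained: np.ndarray  # fractions, non-increasing
    source: str = "strict"


@dataclass
class ClusterResult:
    """A k-means partition of the genes of one distance matrix."""

    source: str
    k: int
    assignment: dict[str, int]     # gene_id -> cluster label in 1..k
    votes: dict[str, int]
    method: str                    # "predicted" | "fallback3"
    seed: int | None = None


@dataclass
class PipelineConfig:
    """Knobs of the automated pipeline, with the published defaults."""

    n_components: int = 3
    k_max: int = 5
    k_min: int = 2
    fallback_k: int = 3
    top_hits: int = 20
    min_proteomes: int = 25
    seed: int = 0
    aggregate: str = "union"       # union | intersection | strict | combined
    combination: str = "sum"

    def __post_init__(self) -> None:
        if not (self.k_min <= self.fallback_k <= self.k_max):
            raise ValueError("need k_min <= fallback_k <= k_max")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


def _impute_column_mean(m: np.ndarray) -> np.ndarray:
    """Replace NaN by the column mean of the finite entries (logged)."""
    m = np.array(m, dtype=float)
    nan_mask = ~np.isfinite(m)
    if nan_mask.any():
        logger.warning(
            "imputing %d NA distance entries with column means before PCA",
            int(nan_mask.sum()),
        )
        col_mean = np.nanmean(np.where(np.isfinite(m), m, np.nan), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.nonzero(nan_mask)
        m[idx] = col_mean[idx[1]]
    return m


def pca_scores(
    matrix: np.ndarray,
    n_components: int = 3,
    gene_ids: list[str] | None = None,
    source: str = "strict",
) -> Embedding:
    """Project the rows of a distance matrix onto principal components.

    Rows are the observations (one distance profile per gene); columns are
    centred but not scaled.  The sign of each component is fixed so that its
    largest-magnitude loading is positive.  With fewer than ``n_components``
    informative directions (small d or degenerate geometry) the missing
    score columns are zero with zero explained variance.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"distance matrix must be square, got {m.shape}")
    d = m.shape[0]
    if d < 3:
        raise ValueError("PCA for clustering needs at least 3 genes")
    m = _impute_column_mean(m)
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(d)]

    centred = m - m.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    n_eff = min(n_components, len(s))

    scores = np.zeros((d, n_components))
    var = np.zeros(n_components)
    for comp in range(n_eff):
        load = vt[comp]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
            u[:, comp] = -u[:, comp]
        scores[:, comp] = u[:, comp] * s[comp]
        var[comp] = s[comp] ** 2 / total if total > 0 else 0.0
    return Embedding(
        gene_ids=list(ids), scores=scores, variance_explained=var, source=source
    )


def _ward_partitions(x: np.ndarray, k_lo: int, k_hi: int) -> dict[int, np.ndarray]:
    """Ward/Euclidean candidate partitions for every k in [k_lo, k_hi]."""
    z = linkage(x, method="ward")
    return {
        k: fcluster(z, t=k, criterion="maxclust")
        for k in range(k_lo, k_hi + 1)
        if k <= x.shape[0]
    }


def index_votes(
    embedding: Embedding, k_min: int = 2, k_max: int = 5
) -> dict[str, int]:
    """Optimal-k vote of each validity index on Ward partitions of the scores.

    ``k_max`` is capped at d - 1 (with a warning) when the matrix is small.
    The result maps index name to its preferred k; undefined indices abstain
    and are simply absent.
    """
    x = embedding.scores
    d = x.shape[0]
    if k_max > d - 1:
        logger.warning("k_max %d capped to d-1 = %d", k_max, d - 1)
        k_max = d - 1
    if k_min > k_max:
        return {}
    parts = _ward_partitions(x, max(1, k_min - 1), min(k_max + 1, d))
    return compute_index_votes(x, parts, k_min, k_max)


def optimal_k(votes: dict[str, int]) -> int | None:
    """Majority rule over index votes; ties break toward the smaller k.

    Returns None (the backup trigger) when the vote set is empty.
    """
    if not votes:
        return None
    counts = Counter(votes.values())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def kmeans_cluster(
    embedding: Embedding,
    k: int,
    seed: int | None = 0,
    method: str = "predicted",
    votes: dict[str, int] | None = None,
    n_init: int = 25,
) -> ClusterResult:
    """k-means (k-means++ init, 25 restarts) on the PCA scores.

    Deterministic given (embedding, k, seed); labels are 1-based.
    """
    d = embedding.scores.shape[0]
    if k < 1 or k > d - 1:
        raise ValueError(f"k={k} outside [1, d-1={d - 1}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(embedding.scores) + 1
    return ClusterResult(
        source=embedding.source,
        k=k,
        assignment=dict(zip(embedding.gene_ids, (int(l) for l in labels))),
        votes=dict(votes or {}),
        method=method,
        seed=seed,
    )


class DistanceMatrixClusterer(ClusterMixin, BaseEstimator):
    """Automated gene clustering of one distance matrix.

    ``fit(X)`` takes a symmetric d x d distance matrix (NaN allowed; imputed
    by column means), embeds its rows by PCA, lets the validity-index
    battery vote on k over Ward candidate partitions, and runs k-means on
    the first ``n_components`` principal components with the winning k; if
    the vote fails the fixed ``fallback_k`` backup is used.

    Parameters
    ----------
    n_components : int, default 3
        Principal components kept for clustering.
    k_min, k_max : int, defaults 2 and 5
        Range of the optimal-k search (k_max capped at d - 1).
    fallback_k : int, default 3
        Cluster count of the backup when the prediction fails (capped at
        d - 1).
    n_init : int, default 25
        k-means restarts.
    random_state : int or None
        Seed for the k-means initialisations.

    Attributes
    ----------
    labels_ : ndarray of shape (d,)
        1-based cluster labels.
    k_ : int
        Number of clusters used.
    method_ : str
        ``"predicted"`` or ``"fallback3"``.
    votes_ : dict
        Per-index preferred k (empty when every index abstained).
    embedding_ : ndarray of shape (d, n_components)
        PCA scores that were clustered.
    variance_explained_ : ndarray
        Fraction of variance per kept component.
    """

    def __init__(
        self,
        n_components: int = 3,
        k_min: int = 2,
        k_max: int = 5,
        fallback_k: int = 3,
        n_init: int = 25,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.k_min = k_min
        self.k_max = k_max
        self.fallback_k = fallback_k
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square distance matrix")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 genes")
        self.n_features_in_ = X.shape[1]

        emb = pca_scores(X, n_components=self.n_components)
        self.embedding_ = emb.scores
        self.variance_explained_ = emb.variance_explained

        try:
            self.votes_ = index_votes(emb, self.k_min, self.k_max)
        except Exception as exc:  # any unrecoverable numerical error -> backup
            logger.warning("optimal-k estimation failed (%s); using backup", exc)
            self.votes_ = {}
        k = optimal_k(self.votes_)
        if k is None:
            self.method_ = "fallback3"
            k = min(self.fallback_k, X.shape[0] - 1)
            logger.warning("optimal-k vote empty; falling back to k=%d", k)
        else:
            self.method_ = "predicted"
        result = kmeans_cluster(
            emb, k, seed=self.random_state, method=self.method_,
            votes=self.votes_, n_init=self.n_init,
        )
        self.k_ = k
        self.labels_ = np.array([result.assignment[g] for g in emb.gene_ids])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def predict_clusters(
    matrices: DistanceMatrixSet, cfg: PipelineConfig | None = None
) -> tuple[ClusterResult, ClusterResult]:
    """Run the automated clustering on the strict and the combined matrix.

    The two embeddings are clustered separately and both results returned;
    how they are aggregated into one detected set is decided later (see
    :func:`detected_genes`).  Requires d >= 4 genes.
    """
    cfg = cfg or PipelineConfig()
    if matrices.n_genes < 4:
        raise ValueError(
            "automated clustering needs at least 4 genes; "
            "produce manual outputs instead"
        )
    if matrices.combined is None:
        matrices.combined = combine_matrices(
            matrices.strict, matrices.evolutionary, method=cfg.combination
        )

    results = []
    for source in ("strict", "combined"):
        est = DistanceMatrixClusterer(
            n_components=cfg.n_components,
            k_min=cfg.k_min,
            k_max=cfg.k_max,
            fallback_k=cfg.fallback_k,
            random_state=cfg.seed,
        )
        matrix = getattr(matrices, source)
        try:
            est.fit(matrix)
        except Exception as exc:
            raise RuntimeError(f"clustering of the {source} matrix failed") from exc
        results.append(
            ClusterResult(
                source=source,
                k=est.k_,
                assignment=dict(
                    zip(matrices.gene_ids, (int(l) for l in est.labels_))
                ),
                votes=est.votes_,
                method=est.method_,
                seed=cfg.seed,
            )
        )
    return results[0], results[1]


def _detected_one(result: ClusterResult, core_ids: set[str]) -> set[str]:
    unknown = core_ids - set(result.assignment)
    if unknown:
        raise ValueError(f"unknown core gene ids: {sorted(unknown)}")
    core_clusters = {result.assignment[c] for c in core_ids}
    return {
        g for g, lab in result.assignment.items()
        if lab in core_clusters and g not in core_ids
    }


def detected_genes(
    results: ClusterResult | tuple | list,
    core_ids: set[str],
    aggregate: str = "union",
) -> set[str]:
    """Genes sharing a cluster with at least one core gene (cores excluded).

    With both the strict- and combined-matrix results supplied, ``aggregate``
    decides how the two detected sets merge: ``union`` (default),
    ``intersection``, ``strict``, or ``combined``.
    """
    if not core_ids:
        raise ValueError("core_ids must be non-empty")
    core_ids = set(core_ids)
    if isinstance(results, ClusterResult):
        return _detected_one(results, core_ids)
    by_source = {r.source: r for r in results}
    if aggregate in ("strict", "combined"):
        return _detected_one(by_source[aggregate], core_ids)
    sets = [_detected_one(r, core_ids) for r in results]
    if aggregate == "union":
        return set().union(*sets)
    if aggregate == "intersection":
        return set.intersection(*sets)
    raise ValueError(f"unknown aggregation {aggregate!r}")


def cluster_table(results: tuple | list) -> pd.DataFrame:
    """Long-format cluster-definition table (one row per gene and matrix)."""
    rows = []
    for r in results:
        for gene, lab in r.assignment.items():
            rows.append(
                {
                    "gene_id": gene,
                    "source_matrix": r.source,
                    "cluster": lab,
                    "method": r.method,
                    "k": r.k,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "source_matrix", "cluster", "method", "k"])
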