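"""Phenotype discovery: 2-D manifold projection + resampled consensus clustering.

Embeddings are projected to two dimensions with UMAP, then clustered by
consensus over resampled Ward-linkage runs: each of ``n_iterations``
iterations subsamples 80% of observations without replacement, cuts the
Ward dendrogram at every K in the candidate range, and records
co-cluster indicators.  The consensus value of a pair is its co-cluster
count divided by its co-sampling count; pairs never co-sampled stay
undefined.  K is selected from the per-K consensus-CDF areas: the
largest K whose relative AUC gain over K-1 still exceeds a threshold
(the CDF "plateau" criterion).  Final labels come from average-linkage
clustering of the consensus dissimilarity, with per-sample confidence =
mean consensus with co-members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

__all__ = ["ProjectionConfig", "project", "ConsensusClusterer", "ConsensusResult",
           "consensus_cdf_auc", "select_k", "assign_labels", "cluster_metrics"]


@dataclass
class ProjectionConfig:
    n_neighbors: int = 30
    min_dist: float = 0.1
    metric: str = "euclidean"
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


def project(embedding: np.ndarray, config: ProjectionConfig | None = None) -> np.ndarray:
    """UMAP projection to ``n_components`` dimensions (seed-deterministic)."""
    import umap  # heavy import (numba JIT) deferred to first use

    config = config or ProjectionConfig()
    x = np.asarray(embedding, dtype=float)
    if len(x) < config.n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 rows to project")
    reducer = umap.UMAP(n_neighbors=config.n_neighbors, min_dist=config.min_dist,
                        metric=config.metric, n_components=config.n_components,
                        random_state=config.seed)
    return np.asarray(reducer.fit_transform(x), dtype=float)


@dataclass
class ConsensusResult:
    k_range: tuple
    consensus: dict = field(default_factory=dict)    # K -> (n, n) matrix with NaN
    cdf_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 101))
    cdfs: dict = field(default_factory=dict)         # K -> CDF values on grid
    aucs: dict = field(default_factory=dict)
    delta_aucs: dict = field(default_factory=dict)   # K -> relative AUC gain
    ambiguity: dict = field(default_factory=dict)    # K -> CDF(0.9) - CDF(0.1)
    k_selected: int | None = None
    stable: bool = True
    labels: np.ndarray | None = None
    confidence: np.ndarray | None = None


def consensus_cdf_auc(consensus: np.ndarray,
                      grid: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical CDF of defined off-diagonal upper-triangle consensus values
    and its area under the curve."""
    iu = np.triu_indices(len(consensus), k=1)
    vals = consensus[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.ones_like(grid), 1.0
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
    auc = float(np.sum(np.diff(grid) * cdf[1:]))
    return cdf, auc


def select_k(result: ConsensusResult, delta_auc_threshold: float = 0.025,
             ambiguity_threshold: float = 0.02) -> int:
    """Select K from the consensus CDFs.

    Two CDF summaries are computed for every K: the area under the CDF
    (and its relative gain over K-1, ``delta_aucs``) and the ambiguity —
    the CDF mass strictly between 0.1 and 0.9, i.e. the fraction of
    pairs whose co-clustering is inconsistent across resamples (0 for an
    ideal block-diagonal consensus matrix).  K* is the largest K whose
    partition is still crisp (ambiguity <= ``ambiguity_threshold``):
    beyond the true cluster number, resampled dendrogram cuts split
    clusters inconsistently and ambiguity jumps, which is also where the
    CDF area gain plateaus.  The raw AUC-gain rule alone cannot be
    thresholded reliably — over-splitting keeps inflating the AUC by
    moving pair mass toward zero, so its gains stay material for every
    K > K_true — hence the crispness criterion arbitrates and
    ``delta_aucs`` is reported for inspection.  With no crisp K at all
    (e.g. one homogeneous blob) the result is flagged unstable and K
    falls back to the smallest candidate.
    """
    ks = sorted(result.aucs)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least 2 values")
    deltas = {}
    for prev, k in zip(ks[:-1], ks[1:]):
        a_prev = result.aucs[prev]
        deltas[k] = (result.aucs[k] - a_prev) / a_prev if a_prev > 0 else 0.0
    result.delta_aucs = deltas
    grid = result.cdf_grid
    i_lo = int(np.searchsorted(grid, 0.1, side="right") - 1)
    i_hi = int(np.searchsorted(grid, 0.9, side="right") - 1)
    result.ambiguity = {k: float(result.cdfs[k][i_hi] - result.cdfs[k][i_lo])
                        for k in ks}
    crisp = [k for k in ks if result.ambiguity[k] <= ambiguity_threshold]
    if crisp:
        result.stable = True
        return max(crisp)
    result.stable = False
    return ks[0]


def assign_labels(consensus: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut average-linkage clustering of (1 - consensus) at ``k``.

    Undefined entries are imputed with column means; confidence per
    sample is its mean consensus with co-members.
    """
    import warnings as _warnings

    c = consensus.copy()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(np.where(np.isfinite(c), c, np.nan), axis=0)
        overall = np.nanmean(col_means)
    col_means = np.where(np.isfinite(col_means), col_means,
                         overall if np.isfinite(overall) else 0.5)
    nan_mask = ~np.isfinite(c)
    c[nan_mask] = np.broadcast_to(col_means, c.shape)[nan_mask]
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    conf = np.empty(len(labels))
    for i in range(len(labels)):
        members = np.flatnonzero(labels == labels[i])
        members = members[members != i]
        conf[i] = c[i, members].mean() if len(members) else 1.0
    return labels, np.clip(conf, 0.0, 1.0)


class ConsensusClusterer(BaseEstimator, ClusterMixin):
    """Resampled Ward consensus clustering with CDF-based K selection.

    Fitted attributes: ``result_`` (per-K consensus matrices, CDFs and
    AUCs), ``k_selected_``, ``labels_`` (1..K*), ``confidence_``.
    """

    def __init__(self, k_range: tuple = (2, 3, 4, 5, 6, 7, 8),
                 n_iterations: int = 100, sample_fraction: float = 0.8,
                 linkage_method: str = "ward",
                 delta_auc_threshold: float = 0.025,
                 ambiguity_threshold: float = 0.02,
                 random_state: int | None = None):
        self.k_range = k_range
        self.n_iterations = n_iterations
        self.sample_fraction = sample_fraction
        self.linkage_method = linkage_method
        self.delta_auc_threshold = delta_auc_threshold
        self.ambiguity_threshold = ambiguity_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        n = len(x)
        if n < 20:
            raise ValueError("need at least 20 observations")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must lie in (0, 1]")
        m = int(np.floor(self.sample_fraction * n))
        ks = [k for k in self.k_range if k < m]
        skipped = [k for k in self.k_range if k >= m]
        if skipped:
            import warnings
            warnings.warn(f"k values {skipped} >= subsample size {m}; skipped")
        rng = np.random.default_rng(self.random_state)

        co_count = {k: np.zeros((n, n)) for k in ks}
        sample_count = np.zeros((n, n))
        for _ in range(self.n_iterations):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            z = linkage(x[idx], method=self.linkage_method)
            sample_count[np.ix_(idx, idx)] += 1.0
            for k in ks:
                labels = fcluster(z, t=k, criterion="maxclust")
                same = labels[:, None] == labels[None, :]
                co_count[k][np.ix_(idx, idx)] += same
        result = ConsensusResult(k_range=tuple(ks))
        with np.errstate(invalid="ignore", divide="ignore"):
            for k in ks:
                cons = co_count[k] / sample_count
                cons[sample_count == 0] = np.nan
                result.consensus[k] = cons
                cdf, auc = consensus_cdf_auc(cons, result.cdf_grid)
                result.cdfs[k] = cdf
                result.aucs[k] = auc
        result.k_selected = select_k(result, self.delta_auc_threshold,
                                     self.ambiguity_threshold)
        labels, conf = assign_labels(result.consensus[result.k_selected],
                                     result.k_selected)
        result.labels = labels
        result.confidence = conf
        self.result_ = result
        self.k_selected_ = result.k_selected
        self.labels_ = labels
        self.confidence_ = conf
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_metrics(points: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin scores."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("cluster metrics need at least 2 clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 members")
    points = np.asarray(points, dtype=float)
    return {
        "silhouette": float(silhouette_score(points, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(points, labels)),
        "davies_bouldin": float(davies_bouldin_score(points, labels)),
    }
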