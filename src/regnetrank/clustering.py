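"""Transcriptional-wave discovery: PCA + k-means under five distance
metrics, with silhouette-based selection of metric and cluster number.

k-means under non-Euclidean metrics is defined through a per-metric feature
space: Euclidean clusters the rows as-is; Manhattan uses L1 assignment with
component-wise median centroids; Pearson standardizes rows to zero mean and
unit norm so that 1 - r equals squared Euclidean distance / 2 exactly
(centroids are re-standardized each Lloyd step); Spearman and Kendall first
rank-transform the rows (exact for Spearman, a documented approximation for
Kendall).  Silhouette widths are always computed on the metric's own
distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

METRICS = ("euclidean", "manhattan", "kendall", "pearson", "spearman")


@dataclass
class ClusteringConfig:
    metrics: tuple[str, ...] = METRICS
    k_range: tuple[int, ...] = tuple(range(2, 13))
    variance_target: float = 0.75
    max_pcs: int = 30
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        if min(self.k_range) < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance target must be in (0, 1]")


@dataclass
class WaveClustering:
    labels: pd.Series  # TF -> cluster id
    metric: str
    k: int
    silhouette_grid: pd.DataFrame  # rows metric, columns k, average widths
    cluster_profiles: pd.DataFrame  # cluster x cell-type mean profile


def pca_reduce(
    z_matrix: pd.DataFrame, config: ClusteringConfig | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project TFs onto leading principal components.

    Retains min(max_pcs, smallest m whose cumulative explained variance
    reaches the target); returns the reduced matrix and the full cumulative
    variance curve.
    """
    config = config or ClusteringConfig()
    n_comp = min(z_matrix.shape[0], z_matrix.shape[1], config.max_pcs)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(z_matrix.to_numpy(dtype=float))
    cum = pca.explained_variance_ratio_.cumsum()
    reached = np.nonzero(cum >= config.variance_target - 1e-12)[0]
    m = int(reached[0]) + 1 if len(reached) else n_comp
    m = min(m, config.max_pcs)
    reduced = pd.DataFrame(
        scores[:, :m], index=z_matrix.index, columns=[f"PC{i+1}" for i in range(m)]
    )
    return reduced, cum


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows: 1 - pearson(x, y) = ||u - v||^2 / 2."""
    c = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return c / norms

def metric_features(X: np.ndarray, metric: str) -> np.ndarray:
    if metric in ("euclidean", "manhattan"):
        return np.asarray(X, dtype=float)
    if metric == "pearson":
        return _standardize_rows(np.asarray(X, dtype=float))
    if metric in ("spearman", "kendall"):
        return _standardize_rows(_rank_rows(np.asarray(X, dtype=float)))
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_distance(X: np.ndarray | pd.DataFrame, metric: str) -> np.ndarray:
    """Row-by-row distance matrix; correlation metrics use d = 1 - r."""
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if metric == "manhattan":
        return squareform(pdist(X, metric="cityblock"))
    if metric == "pearson":
        r = np.corrcoef(X)
        return 1.0 - np.clip(r, -1.0, 1.0)
    if metric == "spearman":
        r = np.corrcoef(_rank_rows(X))
        return 1.0 - np.clip(r, -1.0, 1.0)
    if metric == "kendall":
        n = X.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                tau = stats.kendalltau(X[i], X[j]).statistic
                if np.isnan(tau):
                    tau = 0.0
                d[i, j] = d[j, i] = 1.0 - tau
        return d
    raise ValueError(f"unknown metric {metric!r}")


def _assign(F: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    if metric == "manhattan":
        d = np.abs(F[:, None, :] - centroids[None, :, :]).sum(axis=2)
    else:
        d = ((F[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def _update(F: np.ndarray, labels: np.ndarray, k: int, metric: str) -> np.ndarray:
    centroids = np.empty((k, F.shape[1]))
    empty = []
    for c in range(k):
        members = F[labels == c]
        if len(members) == 0:
            empty.append(c)
            continue
        if metric == "manhattan":
            centroids[c] = np.median(members, axis=0)
        else:
            centroids[c] = members.mean(axis=0)
    # empty cluster: re-seed from the point farthest from the filled centroids
    if empty:
        filled = [c for c in range(k) if c not in empty]
        d = _assign_dist(F, centroids[filled], metric).min(axis=1)
        for c in empty:
            j = int(d.argmax())
            centroids[c] = F[j]
            d[j] = -np.inf
    if metric in ("pearson", "spearman", "kendall"):
        centroids = _standardize_rows(centroids)
    return centroids


def _assign_dist(F, centroids, metric) -> np.ndarray:
    diff = F[:, None, :] - centroids[None, :, :]
    if metric == "manhattan":
        return np.abs(diff).sum(axis=2)
    return (diff**2).sum(axis=2)


def _point_costs(F, centroids, labels, metric) -> np.ndarray:
    diff = F - centroids[labels]
    if metric == "manhattan":
        return np.abs(diff).sum(axis=1)
    return (diff**2).sum(axis=1)


def kmeans_cluster(
    X: np.ndarray | pd.DataFrame,
    k: int,
    metric: str = "pearson",
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd's algorithm in the metric's feature space; best of ``restarts``
    seeded initializations by within-cluster cost.  Deterministic under seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    F = metric_features(X, metric)
    rng = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(max(1, restarts)):
        centroids = F[rng.choice(n, size=k, replace=False)]
        labels = _assign(F, centroids, metric)
        for _it in range(max_iter):
            centroids = _update(F, labels, k, metric)
            new_labels = _assign(F, centroids, metric)
            if (new_labels == labels).all():
                break
            labels = new_labels
        cost = _point_costs(F, centroids, labels, metric).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels.copy()
    return best_labels


def silhouette_select(
    X: pd.DataFrame, config: ClusteringConfig | None = None
) -> WaveClustering:
    """Grid over (metric, k); pick the clustering with the highest average
    silhouette width, computed on each metric's own distance matrix."""
    config = config or ClusteringConfig()
    Xv = X.to_numpy(dtype=float)
    grid = pd.DataFrame(
        np.nan, index=list(config.metrics), columns=list(config.k_range)
    )
    best = (-np.inf, "", 0, None)
    for metric in config.metrics:
        D = pairwise_distance(Xv, metric)
        D = np.maximum(D, 0.0)
        np.fill_diagonal(D, 0.0)
        for k in config.k_range:
            if k > len(X):
                continue
            labels = kmeans_cluster(Xv, k, metric, config.restarts, config.seed)
            if len(np.unique(labels)) < 2:
                continue
            width = float(silhouette_score(D, labels, metric="precomputed"))
            grid.loc[metric, k] = width
            if width > best[0]:
                best = (width, metric, k, labels)
    if best[3] is None:
        raise ValueError("no valid (metric, k) grid point")
    _, metric, k, labels = best
    label_series = pd.Series(labels, index=X.index, name="cluster")
    profiles = X.groupby(label_series).mean()
    profiles.index.name = "cluster"
    return WaveClustering(
        labels=label_series,
        metric=metric,
        k=k,
        silhouette_grid=grid,
        cluster_profiles=profiles,
    )


def hierarchical_cluster_samples(
    z_matrix: pd.DataFrame, metric: str = "pearson", linkage: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the sample (column) vectors.

    Columns are pre-sorted lexicographically so dendrogram tie-breaking is
    deterministic.  Returns the scipy linkage matrix and the leaf order as
    column labels.
    """
    if z_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    cols = sorted(z_matrix.columns)
    X = z_matrix[cols].to_numpy(dtype=float).T
    D = pairwise_distance(X, metric)
    Z = hierarchy.linkage(squareform(np.maximum(D, 0.0), checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    return Z, [cols[i] for i in order]
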