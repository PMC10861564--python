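"""Global analyses of label-enrichment time courses.

Compounds are rows of a trajectory matrix (replicate-mean metric per time
point, default nmol 13C product formed — deliberately not z-scored, since
pool-size scaling is what makes the metric comparable across compounds).
k-means, average-linkage hierarchical clustering and PCA group compounds by
how fast and how much they take up label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "TrajectoryMatrix",
    "build_trajectories",
    "kmeans_cluster",
    "pca_project",
    "hierarchical_cluster",
    "KMeansResult",
    "PCAResult",
    "HierarchicalResult",
]

DEFAULT_K = 3
DEFAULT_SEED = 0


@dataclass
class TrajectoryMatrix:
    """Compound x time matrix of replicate means with per-cell SDs."""

    values: pd.DataFrame  # index compounds, columns time_h
    sd: pd.DataFrame

    @property
    def compounds(self) -> List[str]:
        return list(self.values.index)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def build_trajectories(
    metrics: pd.DataFrame,
    metric: str = "nmol_labeled",
    zscore: bool = False,
) -> TrajectoryMatrix:
    """Pivot a long-format metrics table into compound x time trajectories.

    Replicates are averaged per compound x time; compounds observed at
    fewer than two time points are dropped with a warning.
    """
    sub = metrics[metrics["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    g = sub.groupby(["compound", "time_h"])["value"]
    means = g.mean().unstack("time_h")
    sds = g.std().unstack("time_h").fillna(0.0)
    keep = means.notna().sum(axis=1) >= 2
    if (~keep).any():
        warnings.warn(
            f"dropping compounds with <2 time points: {list(means.index[~keep])}",
            stacklevel=2,
        )
    means, sds = means[keep], sds[keep]
    means = means.ffill(axis=1).fillna(0.0)
    if zscore:
        mu = means.mean(axis=1)
        sig = means.std(axis=1).replace(0.0, 1.0)
        means = means.sub(mu, axis=0).div(sig, axis=0)
    return TrajectoryMatrix(values=means, sd=sds)


@dataclass
class KMeansResult:
    labels: pd.Series  # compound -> cluster id (0 = largest-magnitude centroid)
    centroids: pd.DataFrame  # cluster x time
    inertia: float
    silhouette: Optional[float]
    k: int
    seed: int


def kmeans_cluster(
    matrix: TrajectoryMatrix, k: int = DEFAULT_K, seed: int = DEFAULT_SEED, n_init: int = 10
) -> KMeansResult:
    """Seed-deterministic k-means with clusters renumbered canonically.

    Cluster ids are reassigned by descending centroid magnitude (L2 norm),
    so cluster 0 is always the fastest/highest-labeling group regardless of
    k-means' internal label order.
    """
    X = matrix.as_array()
    if not (1 <= k <= X.shape[0]):
        raise ValueError(f"k={k} outside 1..{X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    order = np.argsort(-np.linalg.norm(km.cluster_centers_, axis=1), kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in km.labels_])
    centroids = km.cluster_centers_[order]
    sil = None
    if 1 < k < X.shape[0]:
        try:
            sil = float(silhouette_score(X, labels))
        except ValueError:
            sil = None
    return KMeansResult(
        labels=pd.Series(labels, index=matrix.compounds, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=matrix.values.columns),
        inertia=float(km.inertia_),
        silhouette=sil,
        k=k,
        seed=seed,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # compound x (PC1, PC2)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca_project(matrix: TrajectoryMatrix, n_components: int = 2) -> PCAResult:
    """Mean-centered PCA of the trajectories with canonical component signs.

    Each component's sign is flipped so its largest-magnitude loading is
    positive, making scores reproducible across SVD implementations.
    Rank-deficient input is fine; missing variance shows up as zero
    explained-variance entries.
    """
    X = matrix.as_array()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 compounds")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    total_var = (s**2).sum()
    evr = (s**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    comps = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.compounds, columns=cols),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(comps, index=cols, columns=matrix.values.columns),
    )


@dataclass
class HierarchicalResult:
    linkage: np.ndarray
    labels: pd.Series


def hierarchical_cluster(
    matrix: TrajectoryMatrix,
    k: Optional[int] = DEFAULT_K,
    height: Optional[float] = None,
    method: str = "average",
    metric: str = "euclidean",
) -> HierarchicalResult:
    """Agglomerative clustering (average linkage, Euclidean by default).

    The tree is cut at ``k`` clusters (or at ``height``); labels are
    renumbered by descending cluster-mean magnitude like k-means.
    """
    X = matrix.as_array()
    if X.shape[0] < 2:
        raise ValueError("hierarchical clustering needs at least 2 compounds")
    Z = sch.linkage(X, method=method, metric=metric)
    if height is not None:
        raw = sch.fcluster(Z, t=height, criterion="distance")
    else:
        raw = sch.fcluster(Z, t=k or DEFAULT_K, criterion="maxclust")
    ids = np.unique(raw)
    mags = [np.linalg.norm(X[raw == i].mean(axis=0)) for i in ids]
    order = ids[np.argsort(-np.asarray(mags), kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in raw])
    return HierarchicalResult(
        linkage=Z, labels=pd.Series(labels, index=matrix.compounds, name="cluster")
    )
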