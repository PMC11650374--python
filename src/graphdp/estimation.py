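"""Posterior summarization and clustering evaluation.

Because mixture atoms are global, component labels are comparable across
groups and all observations are pooled: the posterior similarity matrix
(PSM) collects pairwise co-clustering frequencies over retained draws, and
the point estimate is the retained draw whose association matrix is closest
to the PSM in squared Frobenius distance (the least-squares criterion).
External agreement is measured by the Hubert-Arabie adjusted Rand index;
internal quality by the Calinski-Harabasz, Davies-Bouldin, and silhouette
indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.cluster import KMeans

from .gdp_prior import GroupedDataset
from .gibbs_sampler import PosteriorSamples

__all__ = [
    "ClusteringResult",
    "posterior_similarity",
    "dahl_estimate",
    "adjusted_rand",
    "internal_validation",
    "kmeans_baseline",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # (N,) cluster of each pooled observation
    group_of: np.ndarray  # (N,) group label of each pooled observation
    psm: np.ndarray  # (N, N) co-clustering probabilities
    chosen_draw: int  # index of the selected posterior draw

    def labels_by_group(self) -> dict:
        return {
            j: self.labels[self.group_of == j] for j in np.unique(self.group_of)
        }


def posterior_similarity(samples: PosteriorSamples) -> np.ndarray:
    """Pairwise co-clustering frequencies over retained draws (pooled)."""
    z = np.asarray(samples.z)
    if z.ndim != 2 or z.shape[0] == 0:
        raise ValueError("need at least one retained draw with assignments")
    n_draws, N = z.shape
    psm = np.zeros((N, N))
    for d in range(n_draws):
        psm += z[d][:, None] == z[d][None, :]
    psm /= n_draws
    return psm


def dahl_estimate(samples: PosteriorSamples) -> ClusteringResult:
    """Least-squares point clustering: the draw closest to the PSM.

    Minimizes ||A_d - PSM||_F^2 over retained draws d, where A_d is the 0/1
    association matrix of draw d; ties break toward the earliest draw.
    """
    psm = posterior_similarity(samples)
    z = np.asarray(samples.z)
    n_draws = z.shape[0]
    best, best_dist = 0, np.inf
    for d in range(n_draws):
        A = z[d][:, None] == z[d][None, :]
        dist = float(((A - psm) ** 2).sum())
        if dist < best_dist - 1e-12:
            best, best_dist = d, dist
    return ClusteringResult(
        labels=z[best].copy(),
        group_of=samples.group_of.copy(),
        psm=psm,
        chosen_draw=best,
    )


def adjusted_rand(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("labelings differ in length")
    return float(_skm.adjusted_rand_score(a, b))


def internal_validation(data: GroupedDataset, labels) -> dict:
    """Calinski-Harabasz, Davies-Bouldin, and silhouette on pooled observations.

    Higher Calinski-Harabasz and silhouette are better; lower Davies-Bouldin
    is better.
    """
    X, _ = data.pooled()
    labels = np.asarray(labels).ravel()
    if labels.size != X.shape[0]:
        raise ValueError("labels do not match the pooled dataset")
    if np.unique(labels).size < 2:
        raise ValueError("internal validation requires at least 2 clusters")
    return {
        "calinski_harabasz": float(_skm.calinski_harabasz_score(X, labels)),
        "davies_bouldin": float(_skm.davies_bouldin_score(X, labels)),
        "silhouette": float(_skm.silhouette_score(X, labels)),
    }


def kmeans_baseline(data: GroupedDataset, k: int, seed: int = 0) -> np.ndarray:
    """Pooled k-means labeling (the non-Bayesian comparison baseline)."""
    X, _ = data.pooled()
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of observations")
    if k == X.shape[0]:
        return np.arange(X.shape[0])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)
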