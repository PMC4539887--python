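"""Shared hard-clustering backends: ward, kmeans, pam, spectral.

Used both for clustering features (correlation geometry) and patients
(Euclidean geometry on standardized coordinates).  All backends return an
integer label per row and are deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans, SpectralClustering

from .datatypes import ValidationError

ALGORITHMS = ("ward", "kmeans", "pam", "spectral")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def pam_labels(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by alternating assignment /
    within-cluster medoid updates.  Fully deterministic (ties resolved by
    lowest index).
    """
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        # gain of adding candidate c: total reduction in nearest-medoid distance
        gains = np.maximum(dmin[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for j in range(k):
            members = np.where(assign == j)[0]
            if members.size == 0:
                new_medoids.append(medoids[j])
                continue
            cost = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(cost)]))
        if sorted(new_medoids) == sorted(medoids):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def cluster_rows(
    x: np.ndarray,
    algorithm: str,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
    corr: np.ndarray | None = None,
    n_init: int = 10,
) -> np.ndarray:
    """Cluster the rows of ``x`` into ``k`` groups.

    ``metric="correlation"`` clusters in 1 - Pearson distance (``corr`` may be
    supplied precomputed); for kmeans the rows are standardized first, which
    makes squared Euclidean distance proportional to correlation distance.
    Spectral clustering uses a ``(1+r)/2`` affinity under the correlation
    metric and a median-bandwidth Gaussian affinity otherwise.
    """
    n = x.shape[0]
    if not (2 <= k <= n - 1):
        raise ValidationError(f"k={k} out of range [2, {n - 1}]")
    if algorithm not in ALGORITHMS:
        raise ValidationError(f"unknown algorithm {algorithm!r}")

    if metric == "correlation":
        if corr is None:
            corr = np.corrcoef(x)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        coords = _standardize_rows(x)
    elif metric == "euclidean":
        dist = None
        coords = x
    else:
        raise ValidationError(f"unknown metric {metric!r}")

    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        return km.fit_predict(coords)

    if dist is None:
        dist = squareform(pdist(coords))

    if algorithm == "ward":
        condensed = squareform(dist, checks=False)
        z = linkage(condensed, method="ward")
        return fcluster(z, t=k, criterion="maxclust") - 1

    if algorithm == "pam":
        return pam_labels(dist, k)

    # spectral
    if metric == "correlation":
        affinity = (1.0 + corr) / 2.0
    else:
        d2 = dist**2
        bw = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
        affinity = np.exp(-d2 / bw)
    np.fill_diagonal(affinity, 1.0)
    sc = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        random_state=seed,
        assign_labels="kmeans",
    )
    return sc.fit_predict(affinity)
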