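"""Phase 2: cluster geometry and the neighborhood profile similarity matrix.

Each omic's current similarity matrix A is clustered (spectral clustering on
the affinity by default), every patient is represented by its row of A (its
similarity profile), and cluster geometry — centroids v_c, per-member
centroid distances, per-cluster mean distances — is computed in that space.
From this geometry two quantities reweight A into the neighborhood matrix
Abar:

* inter-cluster separation
  ``D(ci, cj) = exp(beta * ||v_i - v_j||^2 / (eta + 1))`` with the
  normalizer ``eta = (mean_dist_i + mean_dist_j + ||v_i - v_j||) / 3``
  (so D >= 1, equal to 1 for i == j);
* the neighborhood similarity
  ``Abar[i,j] = 2 A[i,j]^2 / ( D(ci,cj) * (mu + mean_dist_ci + mean_dist_cj) )``.

Pairs inside tight, well-separated clusters are boosted relative to pairs
split across distant clusters. ``mu > 0`` keeps the denominator away from
zero when all members coincide with their centroids. Alternative parses of
both denominators are selectable for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans, SpectralClustering

from .datatypes import (
    ClusterAssignment,
    ClusterGeometry,
    ClusterPairSeparation,
    SimilarityMatrix,
    SYMMETRY_TOL,
)

__all__ = [
    "spectral_clusters",
    "kmeans_row_clusters",
    "cluster_geometry",
    "inter_cluster_separation",
    "separation_matrix",
    "neighborhood_matrix",
]


def _check_clusterable(a: SimilarityMatrix, k: int) -> None:
    n = a.n_samples
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    if np.abs(a.values - a.values.T).max(initial=0.0) > SYMMETRY_TOL:
        raise ValueError("affinity matrix must be symmetric")


def spectral_clusters(a: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of an affinity matrix.

    Deterministic for a fixed seed (the embedding's K-means step is seeded).
    """
    _check_clusterable(a, k)
    model = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    labels = model.fit_predict(a.values)
    return ClusterAssignment(list(a.sample_ids), labels, k)


def kmeans_row_clusters(a: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """K-means on the rows of the matrix (each patient = its similarity profile)."""
    _check_clusterable(a, k)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(a.values)
    return ClusterAssignment(list(a.sample_ids), labels, k)


def cluster_geometry(a: SimilarityMatrix, ca: ClusterAssignment) -> ClusterGeometry:
    """Centroids and member-to-centroid distances in similarity-profile space.

    Patient coordinates are the rows of ``a.values``; each centroid is the
    mean of its members' rows. Singleton clusters get mean distance 0.
    """
    if list(a.sample_ids) != list(ca.sample_ids):
        raise ValueError("similarity matrix and assignment refer to different samples")
    rep = a.values
    k = ca.k
    n, d = rep.shape
    centroids = np.zeros((k, d))
    sizes = np.zeros(k, dtype=int)
    for c in range(k):
        members = ca.members(c)
        sizes[c] = members.size
        if members.size:
            centroids[c] = rep[members].mean(axis=0)
    centroid_dists = np.linalg.norm(rep - centroids[ca.labels], axis=1)
    mean_dist = np.zeros(k)
    for c in range(k):
        members = ca.members(c)
        if members.size:
            mean_dist[c] = centroid_dists[members].mean()
    return ClusterGeometry(rep, centroids, sizes, centroid_dists, mean_dist)


def _d_value(dist: float, eta: float, beta: float, eq3_parse: str) -> float:
    if eq3_parse == "normalized_exponent":
        return float(np.exp(beta * dist**2 / (eta + 1.0)))
    if eq3_parse == "outer_division":
        return float(np.exp(beta * dist**2) / (eta + 1.0))
    raise ValueError(f"unknown eq3_parse {eq3_parse!r}")


def inter_cluster_separation(
    g: ClusterGeometry,
    i: int,
    j: int,
    beta: float = 0.5,
    eq3_parse: str = "normalized_exponent",
) -> ClusterPairSeparation:
    """Separation D(ci, cj) between two clusters and its normalizer eta.

    ``eta`` averages the two clusters' mean member-to-centroid distances and
    their centroid distance, damping the exponent for large, spread-out
    clusters; ``i == j`` gives D = 1 exactly.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    dist = float(np.linalg.norm(g.centroids[i] - g.centroids[j]))
    eta = (g.mean_centroid_dist[i] + g.mean_centroid_dist[j] + dist) / 3.0
    return ClusterPairSeparation(d_value=_d_value(dist, eta, beta, eq3_parse), eta=float(eta))


def separation_matrix(
    g: ClusterGeometry,
    beta: float = 0.5,
    eq3_parse: str = "normalized_exponent",
) -> np.ndarray:
    """K x K matrix of pairwise cluster separations D."""
    k = g.n_clusters
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = inter_cluster_separation(g, i, j, beta, eq3_parse).d_value
    return out


def neighborhood_matrix(
    a: SimilarityMatrix,
    g: ClusterGeometry,
    ca: ClusterAssignment,
    beta: float = 0.5,
    mu: float = 1.0,
    eq2_parse: str = "multiplicative",
    eq3_parse: str = "normalized_exponent",
) -> SimilarityMatrix:
    """Reweight A by cluster geometry into the neighborhood matrix Abar.

    With the default (multiplicative) parse,
    ``Abar[i,j] = 2 A[i,j]^2 / ( D(ci,cj) * (mu + md[ci] + md[cj]) )`` where
    ``md`` is the per-cluster mean member-to-centroid distance; the additive
    variant uses ``D * mu + md[ci] + md[cj]``. With mu = 1 every entry is
    bounded by 2 A[i,j]^2 <= 2.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0 (singularity guard)")
    if list(a.sample_ids) != list(ca.sample_ids):
        raise ValueError("similarity matrix and assignment refer to different samples")
    d_mat = separation_matrix(g, beta, eq3_parse)
    labels = ca.labels
    d_pair = d_mat[labels[:, None], labels[None, :]]
    md_pair = g.mean_centroid_dist[labels[:, None]] + g.mean_centroid_dist[labels[None, :]]
    if eq2_parse == "multiplicative":
        denom = d_pair * (mu + md_pair)
    elif eq2_parse == "additive":
        denom = d_pair * mu + md_pair
    else:
        raise ValueError(f"unknown eq2_parse {eq2_parse!r}")
    values = 2.0 * a.values**2 / denom
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        sample_ids=list(a.sample_ids),
        values=values,
        role="neighborhood",
        omic_name=a.omic_name,
    )
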