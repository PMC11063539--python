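"""Phase 3: cross-omic message passing, integration, and final clustering.

One fusion step updates each omic's similarity matrix using every *other*
omic's matrix, sandwiched by an operator derived from its own neighborhood
matrix:

.. math:: A^{o}_{new} = \\sum_{o' \\neq o} R^{o} \\, A^{o'} \\, R^{oT}

(for three omics this is the literal two-term update). With the default
``anchored`` operator, ``R = (I + rownorm(offdiag(Abar))) / 2``: half of
every patient's message mass stays on itself and the other half is
distributed over its neighbors in proportion to the neighborhood weights,
whose squared-similarity/separation structure acts as a soft
nearest-neighbor selection. The identity anchor is what lets fine
cross-omic distinctions survive the sandwich; without it the update either
concentrates onto the largest entries (scalar rescaling) or diffuses to a
flat matrix (dense smoothing) within a few iterations. The ``raw``
operator uses the neighborhood matrix itself and reproduces the literal
triple-product arithmetic.

Between iterations each updated matrix is renormalized — by default as a
kernel (``D^-1/2 A D^-1/2``, restoring the unit self-similarity the
Phase-1 kernel has), keeping the iteration numerically stable over the
default seven rounds; max-entry and row-stochastic rescaling are
selectable variants. After the last iteration the per-omic matrices are
averaged elementwise into the integrated matrix, whose rows are clustered
by K-means to produce the final subtype assignment.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette

from .datatypes import (
    ClusterAssignment,
    FusionConfig,
    FusionResult,
    OmicsMatrix,
    SimilarityMatrix,
)
from .neighborhood import (
    cluster_geometry,
    kmeans_row_clusters,
    neighborhood_matrix,
    spectral_clusters,
)
from .similarity import pairwise_similarity

__all__ = ["fusion_step", "integrate", "final_kmeans", "run_icluf"]


def _check_aligned(matrices: list[SimilarityMatrix]) -> None:
    if len(matrices) < 2:
        raise ValueError("message passing needs at least two omic layers")
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.n_samples != matrices[0].n_samples or list(m.sample_ids) != list(ids):
            raise ValueError("similarity matrices are not sample-aligned")


def _anchored_operator(abar: np.ndarray) -> np.ndarray:
    off = abar.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1, keepdims=True)
    # an isolated patient (all-zero row) keeps all its mass on itself
    safe = np.where(row_sums > 0, row_sums, 1.0)
    return (np.eye(len(abar)) + off / safe) / 2.0


def _renormalize(m: np.ndarray, method: str) -> np.ndarray:
    if method == "kernel":
        d = np.sqrt(np.diag(m))
        d = np.where(d > 0, d, 1.0)
        return m / np.outer(d, d)
    if method == "max":
        peak = m.max()
        return m / peak if peak > 0 else m
    if method == "row":
        sums = m.sum(axis=1, keepdims=True)
        return m / np.where(sums > 0, sums, 1.0)
    raise ValueError(f"unknown rescale method {method!r}")


def fusion_step(
    a_list: list[SimilarityMatrix],
    abar_list: list[SimilarityMatrix],
    operator: str = "anchored",
    rescale: bool = True,
    rescale_method: str = "kernel",
    combine: str = "sum",
) -> list[SimilarityMatrix]:
    """One message-passing update of every omic's similarity matrix.

    ``operator="raw"`` with ``rescale=False`` computes the unmodified
    triple-product sum ``sum_{o' != o} Abar_o A_{o'} Abar_o^T``;
    ``combine="mean"`` averages over the other omics instead of summing.
    Outputs are symmetrized as ``(M + M^T)/2`` to absorb floating-point
    drift.
    """
    _check_aligned(a_list)
    _check_aligned(abar_list)
    if len(a_list) != len(abar_list):
        raise ValueError("a_list and abar_list must pair up omic by omic")
    if combine not in ("sum", "mean"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if operator not in ("anchored", "raw"):
        raise ValueError(f"unknown operator {operator!r}")
    out: list[SimilarityMatrix] = []
    n_other = len(a_list) - 1
    for o, abar in enumerate(abar_list):
        b = _anchored_operator(abar.values) if operator == "anchored" else abar.values
        acc = np.zeros_like(b)
        for o2, a in enumerate(a_list):
            if o2 == o:
                continue
            acc += b @ a.values @ b.T
        if combine == "mean":
            acc /= n_other
        if rescale:
            acc = _renormalize(acc, rescale_method)
        acc = (acc + acc.T) / 2.0
        out.append(
            SimilarityMatrix(
                sample_ids=list(abar.sample_ids),
                values=acc,
                role="fused",
                omic_name=abar.omic_name,
            )
        )
    return out


def integrate(a_list: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise mean of the per-omic matrices (role ``integrated``)."""
    _check_aligned(a_list)
    mean = np.mean([m.values for m in a_list], axis=0)
    return SimilarityMatrix(
        sample_ids=list(a_list[0].sample_ids),
        values=mean,
        role="integrated",
        omic_name="integrated",
    )


def final_kmeans(integrated: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """K-means (k-means++, 10 restarts) on the integrated matrix rows."""
    n = integrated.n_samples
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(integrated.values)
    return ClusterAssignment(list(integrated.sample_ids), labels, k)


def _trace_silhouette(a_list: list[SimilarityMatrix], k: int, seed: int) -> float:
    integ = integrate(a_list)
    labels = final_kmeans(integ, k, seed).labels
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(_sk_silhouette(integ.values, labels, metric="euclidean"))


def run_icluf(layers: list[OmicsMatrix], config: FusionConfig) -> FusionResult:
    """Run the full three-phase pipeline on preprocessed, aligned layers.

    Phase 1 builds each omic's kernel similarity matrix once. Every
    iteration then re-derives Phase 2 (clustering, geometry, neighborhood
    matrix) from the *current* per-omic matrices and applies the Phase 3
    message-passing update. Finally the matrices are averaged and K-means
    assigns the subtypes. The silhouette of a K-clustering of the integrated
    matrix is recorded after every iteration so convergence can be
    monitored; it is never used to stop early.
    """
    if len(layers) < 2:
        raise ValueError("at least two omic layers required")
    ids = layers[0].sample_ids
    for layer in layers[1:]:
        if list(layer.sample_ids) != list(ids):
            raise ValueError("layers are not sample-aligned; run align_cohort first")
    cluster = spectral_clusters if config.phase2_clusterer == "spectral" else kmeans_row_clusters

    a_list = [
        pairwise_similarity(layer, alpha=config.alpha, squared=config.kernel_squared)
        for layer in layers
    ]
    trace: list[float] = []
    for it in range(1, config.iterations + 1):
        abar_list = []
        for a in a_list:
            ca = cluster(a, config.k, config.seed)
            geom = cluster_geometry(a, ca)
            abar_list.append(
                neighborhood_matrix(
                    a,
                    geom,
                    ca,
                    beta=config.beta,
                    mu=config.mu,
                    eq2_parse=config.eq2_parse,
                    eq3_parse=config.eq3_parse,
                )
            )
        a_list = fusion_step(
            a_list,
            abar_list,
            operator=config.message_operator,
            rescale=config.rescale_each_iteration,
            rescale_method=config.rescale_method,
            combine=config.fusion_combine,
        )
        for a in a_list:
            if not np.all(np.isfinite(a.values)):
                raise FloatingPointError(f"non-finite similarity values at iteration {it}")
        trace.append(_trace_silhouette(a_list, config.k, config.seed))

    integrated = integrate(a_list)
    assignment = final_kmeans(integrated, config.k, config.seed)
    return FusionResult(
        integrated=integrated,
        assignment=assignment,
        per_iteration_silhouette=trace,
        final_per_omic=a_list,
    )
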