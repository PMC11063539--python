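"""Core data containers shared across the pipeline.

Every stage of the fusion pipeline passes one of these types to the next:
omic feature matrices (:class:`OmicsMatrix`), square patient-patient
similarity matrices (:class:`SimilarityMatrix`), clusterings
(:class:`ClusterAssignment`) and their geometry (:class:`ClusterGeometry`),
survival data (:class:`SurvivalTable`), and the run configuration
(:class:`FusionConfig`). All containers validate their invariants at
construction so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "SimilarityMatrix",
    "ClusterAssignment",
    "ClusterGeometry",
    "ClusterPairSeparation",
    "FusionConfig",
    "FusionResult",
    "SYMMETRY_TOL",
]

#: absolute tolerance used when checking matrix symmetry
SYMMETRY_TOL = 1e-10

_SIMILARITY_ROLES = ("original", "neighborhood", "fused", "integrated")


def _find_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class OmicsMatrix:
    """One omic layer: a samples x features real matrix with identifiers.

    Parameters
    ----------
    omic_name
        Label of the modality, e.g. ``"mRNA"``, ``"miRNA"``, ``"methylation"``.
    sample_ids, feature_ids
        Ordered unique identifiers for rows and columns.
    values
        Real matrix of shape ``(n_samples, n_features)``. Missing entries are
        represented as ``NaN``.
    """

    omic_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.values.size == 0:
            raise ValueError(f"omic {self.omic_name!r}: empty matrix")
        for ids, kind in ((self.sample_ids, "sample"), (self.feature_ids, "feature")):
            dup = _find_duplicate(ids)
            if dup is not None:
                raise ValueError(f"omic {self.omic_name!r}: duplicate {kind} id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        """Samples-in-rows DataFrame with ids as index/columns."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, omic_name: str) -> "OmicsMatrix":
        return cls(
            omic_name=omic_name,
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class SurvivalTable:
    """Right-censored survival data: per-sample time and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        dup = _find_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id {dup!r} in survival table")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event must be one value per sample")
        if np.any(self.time < 0) or np.any(~np.isfinite(self.time)):
            raise ValueError("survival times must be finite and >= 0")
        ev = np.asarray(self.event, dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        self.event = ev.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "SurvivalTable":
        """Restrict to `ids`, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return SurvivalTable(list(ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative patient-patient matrix, tagged by role.

    Roles: ``original`` (Phase-1 kernel output; unit diagonal, entries <= 1),
    ``neighborhood`` (cluster-geometry reweighted), ``fused`` (after a
    message-passing update), ``integrated`` (cross-omic average).
    """

    sample_ids: list[str]
    values: np.ndarray
    role: str
    omic_name: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {self.values.shape}")
        if self.role not in _SIMILARITY_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_SIMILARITY_ROLES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min(initial=0.0) < -SYMMETRY_TOL:
            raise ValueError("similarity matrix has negative entries")
        self.values = np.clip(self.values, 0.0, None)
        if self.role == "original":
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
                raise ValueError("original similarity must have unit diagonal")
            if self.values.max() > 1.0 + 1e-9:
                raise ValueError("original similarity entries must be <= 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class ClusterAssignment:
    """Per-sample integer cluster labels in ``{0..k-1}``."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample required")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError(f"labels must lie in [0, {self.k})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


@dataclass
class ClusterGeometry:
    """Centroid geometry of a clustering in a chosen coordinate space.

    ``representation[i]`` is patient *i*'s coordinate vector (by default the
    row of the current similarity matrix, i.e. the patient's similarity
    profile). ``centroids[c]`` is the mean of cluster *c*'s member vectors;
    ``centroid_dists[i]`` is patient *i*'s Euclidean distance to its own
    cluster centroid; ``mean_centroid_dist[c]`` averages those over cluster
    *c*'s members (0 for singletons).
    """

    representation: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    centroid_dists: np.ndarray
    mean_centroid_dist: np.ndarray

    def __post_init__(self) -> None:
        self.representation = np.asarray(self.representation, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.centroid_dists = np.asarray(self.centroid_dists, dtype=float)
        self.mean_centroid_dist = np.asarray(self.mean_centroid_dist, dtype=float)
        n = self.representation.shape[0]
        if self.sizes.sum() != n:
            raise ValueError("cluster sizes must sum to the number of samples")
        if np.any(self.centroid_dists < 0) or np.any(self.mean_centroid_dist < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class ClusterPairSeparation:
    """Inter-cluster separation D(ci, cj) and its normalizer eta."""

    d_value: float
    eta: float

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.d_value < 1.0 - 1e-12:
            raise ValueError("separation D must be >= 1")


@dataclass
class FusionConfig:
    """All tunable parameters of a fusion run.

    alpha : kernel bandwidth of the Gaussian profile-similarity kernel
        (default 1.5; lower values spread the similarity scores more).
    beta : inter-cluster separation gain (recommended range 0.1-1;
        default 0.5).
    mu : singularity guard added to the neighborhood denominator
        (default 1.0; must stay positive).
    k : number of clusters, used for both the per-iteration spectral step
        and the final K-means.
    iterations : number of message-passing rounds (default 7).
    seed : seed for every stochastic step (spectral K-means phase, K-means).
    rescale_each_iteration : renormalize each updated matrix between
        iterations (default True); the method is set by ``rescale_method``.
    rescale_method : "kernel" (default; symmetric D^-1/2 A D^-1/2
        normalization restoring unit self-similarity), "max" (divide by the
        maximum entry), or "row" (row-stochastic then symmetrized).
    message_operator : "anchored" (default; the sandwich operator is
        (I + rownorm(offdiag(Abar)))/2, half the mass anchored on self so
        the neighborhood weights act as soft nearest-neighbor selection) or
        "raw" (the literal neighborhood matrix).
    kernel_squared : use exp(-alpha * d^2) (default) vs exp(-alpha * d).
    eq2_parse : "multiplicative" (default) -> denominator
        D * (mu + mean_i + mean_j); "additive" -> D * mu + mean_i + mean_j.
    eq3_parse : "normalized_exponent" (default) ->
        exp(beta * d^2 / (eta + 1)); "outer_division" ->
        exp(beta * d^2) / (eta + 1).
    phase2_clusterer : "spectral" (default) or "kmeans" (K-means on matrix
        rows).
    fusion_combine : "sum" (default; literal multi-omic extension of the
        three-omic update) or "mean" over the other omics.
    """

    k: int
    alpha: float = 1.5
    beta: float = 0.5
    mu: float = 1.0
    iterations: int = 7
    seed: int = 0
    rescale_each_iteration: bool = True
    rescale_method: str = "kernel"
    message_operator: str = "anchored"
    kernel_squared: bool = True
    eq2_parse: str = "multiplicative"
    eq3_parse: str = "normalized_exponent"
    phase2_clusterer: str = "spectral"
    fusion_combine: str = "sum"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0 (it guards against a vanishing denominator)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.rescale_method not in ("kernel", "max", "row"):
            raise ValueError(f"unknown rescale_method {self.rescale_method!r}")
        if self.message_operator not in ("anchored", "raw"):
            raise ValueError(f"unknown message_operator {self.message_operator!r}")
        if self.eq2_parse not in ("multiplicative", "additive"):
            raise ValueError(f"unknown eq2_parse {self.eq2_parse!r}")
        if self.eq3_parse not in ("normalized_exponent", "outer_division"):
            raise ValueError(f"unknown eq3_parse {self.eq3_parse!r}")
        if self.phase2_clusterer not in ("spectral", "kmeans"):
            raise ValueError(f"unknown phase2_clusterer {self.phase2_clusterer!r}")
        if self.fusion_combine not in ("sum", "mean"):
            raise ValueError(f"unknown fusion_combine {self.fusion_combine!r}")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "alpha": self.alpha,
            "beta": self.beta,
            "mu": self.mu,
            "iterations": self.iterations,
            "seed": self.seed,
            "rescale_each_iteration": self.rescale_each_iteration,
            "rescale_method": self.rescale_method,
            "message_operator": self.message_operator,
            "kernel_squared": self.kernel_squared,
            "eq2_parse": self.eq2_parse,
            "eq3_parse": self.eq3_parse,
            "phase2_clusterer": self.phase2_clusterer,
            "fusion_combine": self.fusion_combine,
        }


@dataclass
class FusionResult:
    """Output of a full fusion run."""

    integrated: SimilarityMatrix
    assignment: ClusterAssignment
    per_iteration_silhouette: list[float] = field(default_factory=list)
    final_per_omic: list[SimilarityMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.integrated.role != "integrated":
            raise ValueError("integrated matrix must carry role='integrated'")
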