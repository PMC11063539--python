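"""Synthetic multiomic cohorts with planted subtypes and matched survival.

The generator plants K patient groups and distributes their signal across
omic layers. Each omic sees the groups through a *merge map*: clusters
mapped to the same merged group are indistinguishable in that layer, which
lets complementary designs be built where no single omic resolves the full
structure but the ensemble does. Informative features get a
group-dependent mean offset (``separation``, in units of the within-group
standard deviation); all other features are pure noise. Features are drawn
at per-feature s.d. ``0.5/sqrt(n_features)``, which puts the expected
within-group squared profile distance at 0.5 and within-group kernel
similarities near ``exp(-0.75)`` — the operating regime of the default
bandwidth, mimicking bounded methylation beta values or normalized
expression scales.

Survival is exponential per planted group with independent exponential
right-censoring calibrated so the expected censored fraction equals the
requested rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ClusterAssignment, OmicsMatrix, SurvivalTable

__all__ = [
    "OmicSpec",
    "SimulationSpec",
    "generate_multiomic",
    "generate_survival",
    "strong_signal_spec",
    "complementary_spec",
    "single_signal_spec",
]


@dataclass
class OmicSpec:
    """How one omic layer expresses the planted structure.

    ``merge_map`` (length K, one merged-group id per planted cluster)
    defines which clusters the omic can tell apart; ``None`` means the
    identity (all K distinguishable). ``n_informative`` defaults to a
    quarter of the features; 0 (or ``separation = 0``) gives a pure-noise
    layer. ``log_normal`` exponentiates the values to mimic
    expression-scale data.
    """

    n_features: int = 60
    n_informative: int | None = None
    separation: float = 6.0
    merge_map: list[int] | None = None
    log_normal: bool = False

    def __post_init__(self) -> None:
        if self.n_informative is None:
            self.n_informative = max(1, self.n_features // 4)
        if self.n_features < 1 or not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features, n_features >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort."""

    n_per_cluster: list[int]
    omic_specs: dict[str, OmicSpec]
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_cluster or any(n < 1 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be positive counts")
        if not self.omic_specs:
            raise ValueError("at least one omic spec required")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        k = len(self.n_per_cluster)
        for name, spec in self.omic_specs.items():
            if spec.merge_map is not None:
                mm = list(spec.merge_map)
                if len(mm) != k or any(g < 0 for g in mm):
                    raise ValueError(
                        f"omic {name!r}: merge_map must assign each of the {k} "
                        "clusters a nonnegative merged-group id"
                    )

    @property
    def k(self) -> int:
        return len(self.n_per_cluster)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_cluster))


def _merged_view(merge_map: list[int] | None, k: int) -> np.ndarray:
    if merge_map is None:
        return np.arange(k)
    # relabel merged groups to a contiguous 0..G-1 range
    mm = np.asarray(merge_map, dtype=int)
    _, contiguous = np.unique(mm, return_inverse=True)
    return contiguous


def generate_multiomic(spec: SimulationSpec) -> tuple[list[OmicsMatrix], ClusterAssignment]:
    """Draw the cohort: one OmicsMatrix per spec entry plus the true labels.

    Each omic gets its own deterministic child of the spec's seed (indexed
    by position), so adding an omic never perturbs the others. Missing
    entries (NaN) are planted uniformly at random at ``missing_fraction``.
    """
    k = spec.k
    labels = np.repeat(np.arange(k), spec.n_per_cluster)
    n = labels.size
    sample_ids = [f"S{i:04d}" for i in range(n)]
    layers: list[OmicsMatrix] = []
    for omic_idx, (name, ospec) in enumerate(spec.omic_specs.items()):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(omic_idx,)))
        view = _merged_view(ospec.merge_map, k)
        n_groups = int(view.max()) + 1
        scale = 0.5 / np.sqrt(ospec.n_features)
        pattern = np.zeros((n_groups, ospec.n_features))
        for j in range(ospec.n_informative):
            pattern[j % n_groups, j] = ospec.separation
        values = scale * (pattern[view[labels]] + rng.standard_normal((n, ospec.n_features)))
        if ospec.log_normal:
            values = np.exp(values)
        if spec.missing_fraction > 0:
            mask = rng.random(values.shape) < spec.missing_fraction
            values = values.copy()
            values[mask] = np.nan
        feature_ids = [f"{name}_f{j:04d}" for j in range(ospec.n_features)]
        layers.append(OmicsMatrix(name, sample_ids, feature_ids, values))
    truth = ClusterAssignment(sample_ids, labels, k)
    return layers, truth


def generate_survival(
    labels: ClusterAssignment,
    hazards: list[float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival per cluster with calibrated right-censoring.

    Event times are exponential with the cluster's hazard. Censoring times
    are independent exponentials whose hazard is chosen per cluster as
    ``censor_rate / (1 - censor_rate) * hazard``, which makes the marginal
    probability of censoring exactly ``censor_rate``.
    """
    hazards = [float(h) for h in hazards]
    if len(hazards) != labels.k or any(h <= 0 for h in hazards):
        raise ValueError("one positive hazard per cluster required")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lam = np.asarray(hazards)[labels.labels]
    t_event = rng.exponential(1.0 / lam)
    if censor_rate == 0.0:
        return SurvivalTable(list(labels.sample_ids), t_event, np.ones(len(lam), dtype=int))
    gamma = censor_rate / (1.0 - censor_rate) * lam
    t_censor = rng.exponential(1.0 / gamma)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return SurvivalTable(list(labels.sample_ids), time, event)


def strong_signal_spec(
    n_per_cluster: tuple[int, ...] = (20, 20, 20),
    separation: float = 6.0,
    seed: int = 0,
) -> SimulationSpec:
    """Three omics all carrying the same well-separated K-group structure."""
    return SimulationSpec(
        n_per_cluster=list(n_per_cluster),
        omic_specs={
            "mRNA": OmicSpec(separation=separation),
            "miRNA": OmicSpec(n_features=40, n_informative=10, separation=separation),
            "methylation": OmicSpec(separation=separation),
        },
        seed=seed,
    )


def complementary_spec(
    n_per_cluster: tuple[int, int, int] = (20, 20, 20),
    separation: float = 6.0,
    seed: int = 0,
) -> SimulationSpec:
    """Complementary design: no single omic resolves all three groups.

    The first omic merges clusters {0,1}, the second merges {1,2}, the
    third is pure noise; only the fused view separates all three.
    """
    return SimulationSpec(
        n_per_cluster=list(n_per_cluster),
        omic_specs={
            "mRNA": OmicSpec(separation=separation, merge_map=[0, 0, 1]),
            "miRNA": OmicSpec(separation=separation, merge_map=[0, 1, 1]),
            "methylation": OmicSpec(n_informative=0, separation=0.0),
        },
        seed=seed,
    )


def single_signal_spec(
    signal_omic: str = "methylation",
    n_per_cluster: tuple[int, ...] = (25, 25, 25),
    separation: float = 6.0,
    seed: int = 0,
) -> SimulationSpec:
    """Only one omic layer carries the cluster signal; the rest are noise."""
    omics = {}
    for name in ("mRNA", "miRNA", "methylation"):
        if name == signal_omic:
            omics[name] = OmicSpec(separation=separation)
        else:
            omics[name] = OmicSpec(n_informative=0, separation=0.0)
    if signal_omic not in omics:
        omics[signal_omic] = OmicSpec(separation=separation)
    return SimulationSpec(n_per_cluster=list(n_per_cluster), omic_specs=omics, seed=seed)
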