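"""Cluster-quality and survival-difference metrics.

Partition agreement (adjusted Rand index, Fowlkes-Mallows), cluster
homogeneity (silhouette on the integrated matrix), the K-sample log-rank
test for survival differences between predicted subtypes, Kaplan-Meier
step functions per cluster, and log-rank tests over every subset of
clusters of a requested size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    silhouette_score as _sk_silhouette,
)

from .datatypes import ClusterAssignment, SimilarityMatrix, SurvivalTable

__all__ = [
    "adjusted_rand_index",
    "fowlkes_mallows",
    "silhouette_score",
    "logrank_test",
    "km_curves",
    "cluster_subset_survival",
    "EvaluationReport",
    "evaluate",
]


def _check_same_samples(a: ClusterAssignment, b: ClusterAssignment) -> None:
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("cluster assignments refer to different samples or orders")


def adjusted_rand_index(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    _check_same_samples(a, b)
    return float(adjusted_rand_score(a.labels, b.labels))


def fowlkes_mallows(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Geometric mean of pairwise precision and recall between partitions."""
    _check_same_samples(a, b)
    return float(fowlkes_mallows_score(a.labels, b.labels))


def silhouette_score(
    integrated: SimilarityMatrix,
    ca: ClusterAssignment,
    space: str = "euclidean",
) -> float:
    """Mean silhouette of the clustering over the integrated matrix.

    ``space="euclidean"`` (default) measures Euclidean distance between
    matrix rows — the same representation the final K-means clusters.
    ``space="dissimilarity"`` instead uses ``max(S) - S`` as a precomputed
    dissimilarity.
    """
    if list(integrated.sample_ids) != list(ca.sample_ids):
        raise ValueError("matrix and assignment refer to different samples")
    if len(np.unique(ca.labels)) < 2:
        raise ValueError("silhouette requires at least two nonempty clusters")
    if space == "euclidean":
        return float(_sk_silhouette(integrated.values, ca.labels, metric="euclidean"))
    if space == "dissimilarity":
        diss = integrated.values.max() - integrated.values
        np.fill_diagonal(diss, 0.0)
        return float(_sk_silhouette(diss, ca.labels, metric="precomputed"))
    raise ValueError(f"unknown silhouette space {space!r}")


def logrank_test(surv: SurvivalTable, ca: ClusterAssignment) -> tuple[float, int, float]:
    """K-sample log-rank test of survival differences between clusters.

    Returns ``(chi2 statistic, degrees of freedom, p-value)`` where the
    statistic compares observed vs expected event counts per group on the
    pooled risk set, with K-1 degrees of freedom. Ties at identical event
    times are handled with the standard hypergeometric variance.
    """
    if list(surv.sample_ids) != list(ca.sample_ids):
        raise ValueError("survival table and assignment refer to different samples")
    groups = np.unique(ca.labels)
    if groups.size < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    if surv.event.sum() == 0:
        raise ValueError("log-rank test needs at least one observed event")
    res = multivariate_logrank_test(surv.time, ca.labels, surv.event)
    df = int(groups.size - 1)
    return float(res.test_statistic), df, float(res.p_value)


def km_curves(surv: SurvivalTable, ca: ClusterAssignment) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate per cluster.

    Returns a tidy table with columns ``group, time, n_at_risk, n_events,
    survival`` (one row per distinct event/censoring time per group),
    survival non-increasing from 1.
    """
    if list(surv.sample_ids) != list(ca.sample_ids):
        raise ValueError("survival table and assignment refer to different samples")
    rows = []
    for g in np.unique(ca.labels):
        mask = ca.labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        tbl = kmf.event_table
        surv_fn = kmf.survival_function_.iloc[:, 0]
        for t in tbl.index:
            rows.append(
                {
                    "group": int(g),
                    "time": float(t),
                    "n_at_risk": int(tbl.loc[t, "at_risk"]),
                    "n_events": int(tbl.loc[t, "observed"]),
                    "survival": float(surv_fn.loc[t]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "time", "n_at_risk", "n_events", "survival"])


def cluster_subset_survival(
    surv: SurvivalTable,
    ca: ClusterAssignment,
    subset_sizes: list[int],
) -> dict[tuple[int, ...], float]:
    """Log-rank p-value for every combination of clusters of each size.

    For k clusters and a subset size s < k this restricts the cohort to each
    of the C(k, s) cluster combinations and runs the log-rank test, mapping
    the combination tuple to its p-value (raw, unadjusted).
    """
    present = sorted(int(g) for g in np.unique(ca.labels))
    k = len(present)
    out: dict[tuple[int, ...], float] = {}
    for size in subset_sizes:
        if not 2 <= size < k:
            raise ValueError(f"subset size {size} must satisfy 2 <= size < k={k}")
        for combo in itertools.combinations(present, size):
            mask = np.isin(ca.labels, combo)
            ids = [s for s, m in zip(ca.sample_ids, mask) if m]
            sub_surv = surv.subset(ids)
            labels = ca.labels[mask]
            relabel = {g: i for i, g in enumerate(combo)}
            sub_ca = ClusterAssignment(ids, np.array([relabel[g] for g in labels]), len(combo))
            _, _, p = logrank_test(sub_surv, sub_ca)
            out[combo] = p
    return out


@dataclass
class EvaluationReport:
    """Bundle of cluster-quality and survival metrics for one clustering."""

    silhouette: float | None = None
    ari: float | None = None
    fm: float | None = None
    logrank_stat: float | None = None
    logrank_df: int | None = None
    logrank_p: float | None = None
    per_pair_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "silhouette": self.silhouette,
            "ari": self.ari,
            "fm": self.fm,
            "logrank_stat": self.logrank_stat,
            "logrank_df": self.logrank_df,
            "logrank_p": self.logrank_p,
        }
        if self.per_pair_p:
            d["per_subset_p"] = {"+".join(map(str, k)): v for k, v in self.per_pair_p.items()}
        return d


def evaluate(
    ca: ClusterAssignment,
    integrated: SimilarityMatrix | None = None,
    truth: ClusterAssignment | None = None,
    surv: SurvivalTable | None = None,
    subset_sizes: list[int] | None = None,
) -> EvaluationReport:
    """Compute whichever metrics the supplied inputs allow."""
    report = EvaluationReport()
    if integrated is not None:
        report.silhouette = silhouette_score(integrated, ca)
    if truth is not None:
        report.ari = adjusted_rand_index(ca, truth)
        report.fm = fowlkes_mallows(ca, truth)
    if surv is not None:
        stat, df, p = logrank_test(surv, ca)
        report.logrank_stat, report.logrank_df, report.logrank_p = stat, df, p
        if subset_sizes:
            report.per_pair_p = cluster_subset_survival(surv, ca, subset_sizes)
    return report
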