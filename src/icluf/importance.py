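"""Per-omic contribution analysis via random-forest Gini importance.

A seeded random forest is trained per omic layer to predict the fused
subtype labels; the mean-impurity-decrease (Gini) importance of each
feature is collected, the top quartile of features per omic is summed, and
the sums are min-max normalized across omics so the most and least
informative layers map to 1 and 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datatypes import ClusterAssignment, OmicsMatrix

__all__ = ["gini_importance", "omic_contribution", "ImportanceReport", "plot_contributions"]


def gini_importance(
    m: OmicsMatrix,
    labels: ClusterAssignment,
    seed: int = 0,
    n_trees: int = 500,
) -> dict[str, float]:
    """Gini importance of every feature for predicting the cluster labels.

    Trains a seeded random forest (``n_trees`` trees, sqrt-features per
    split) classifying samples into their clusters; returns the normalized
    mean-impurity-decrease score per feature (nonnegative, summing to ~1).
    """
    if list(m.sample_ids) != list(labels.sample_ids):
        raise ValueError("omic matrix and labels refer to different samples")
    if np.unique(labels.labels).size < 2:
        raise ValueError("importance needs at least two classes in the labels")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(m.values, labels.labels)
    return dict(zip(m.feature_ids, (float(v) for v in forest.feature_importances_)))


@dataclass
class ImportanceReport:
    """Per-feature scores plus raw and normalized per-omic contributions."""

    per_feature: dict[str, dict[str, float]]
    per_omic_raw: dict[str, float]
    per_omic_normalized: dict[str, float]
    top_fraction: float = 0.25
    forest_params: dict = field(
        default_factory=lambda: {"n_trees": 500, "max_features": "sqrt"}
    )

    def to_dict(self) -> dict:
        return {
            "top_fraction": self.top_fraction,
            "forest_params": self.forest_params,
            "per_omic_raw": self.per_omic_raw,
            "per_omic_normalized": self.per_omic_normalized,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def omic_contribution(
    reports: dict[str, dict[str, float]],
    top_fraction: float = 0.25,
) -> ImportanceReport:
    """Aggregate per-feature Gini scores into per-omic contributions.

    Per omic, features are sorted by score descending and the top
    ``ceil(top_fraction * n_features)`` (so small omics keep at least one
    feature) are summed into the raw contribution; raw contributions are
    min-max normalized across omics.
    """
    if len(reports) < 2:
        raise ValueError("min-max normalization needs at least two omics")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    raw: dict[str, float] = {}
    for omic, scores in reports.items():
        if not scores:
            raise ValueError(f"omic {omic!r} has no feature scores")
        ordered = sorted(scores.values(), reverse=True)
        n_top = math.ceil(top_fraction * len(ordered))
        raw[omic] = float(sum(ordered[:n_top]))
    lo, hi = min(raw.values()), max(raw.values())
    span = hi - lo
    if span == 0:
        normalized = {omic: 0.0 for omic in raw}
    else:
        normalized = {omic: (v - lo) / span for omic, v in raw.items()}
    return ImportanceReport(
        per_feature=reports,
        per_omic_raw=raw,
        per_omic_normalized=normalized,
        top_fraction=top_fraction,
    )


def plot_contributions(report: ImportanceReport, path: str | Path) -> None:
    """Bar chart of normalized per-omic contributions (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    omics = list(report.per_omic_normalized)
    values = [report.per_omic_normalized[o] for o in omics]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(omics), 3.2))
    ax.bar(omics, values, color="#4878a8")
    ax.set_ylabel("normalized contribution")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
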