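"""Reading, filtering and cohort alignment of omic matrices and survival data.

The preprocessing contract is fixed: layers are first restricted to the
samples present in *every* omic (and the survival table, if given), sorted
into one canonical order, and only then filtered for features whose
zero-or-missing fraction exceeds the threshold — so missingness fractions
always refer to the analysis cohort.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix, SurvivalTable

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_survival_table",
    "write_survival_table",
    "filter_features_by_missingness",
    "align_cohort",
    "preprocess_cohort",
]

log = logging.getLogger(__name__)

_TRUTHY = {"true", "t", "yes", "y", "1", "1.0", "dead", "event"}
_FALSY = {"false", "f", "no", "n", "0", "0.0", "alive", "censored"}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = _sniff_sep(path)
    # round_trip parsing so written matrices read back bit-identically
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def read_omics_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    omic_name: str = "omic",
    sep: str | None = None,
) -> OmicsMatrix:
    """Read a delimited omic matrix (header row + id column).

    ``orientation="samples_in_columns"`` transposes the file so the returned
    matrix is always samples x features. Non-numeric cells become missing
    (NaN). Duplicate ids or an empty matrix are rejected.
    """
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path, sep)
    if df.size == 0:
        raise ValueError(f"{path}: empty matrix")
    if orientation == "samples_in_columns":
        df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    return OmicsMatrix.from_frame(df, omic_name=omic_name)


def write_omics_matrix(m: OmicsMatrix, path: str | Path, sep: str = ",") -> None:
    # %.17g round-trips doubles exactly
    m.to_frame().to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def read_survival_table(
    path: str | Path,
    id_col: str = "sample_id",
    time_col: str = "time",
    event_col: str = "event",
    sep: str | None = None,
) -> SurvivalTable:
    """Read a survival table; event may be coded 0/1 or TRUE/FALSE-like.

    Rows violating the invariants (negative time, uninterpretable event)
    are reported with their 1-based data row number.
    """
    df = pd.read_csv(path, sep=sep or _sniff_sep(path), float_precision="round_trip")
    for col in (id_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ids = [str(s) for s in df[id_col]]
    time = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    event = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df[event_col]):
        token = str(raw).strip().lower()
        if token in _TRUTHY:
            event[i] = 1.0
        elif token in _FALSY:
            event[i] = 0.0
        else:
            event[i] = np.nan
    for i in range(len(df)):
        row = i + 1
        if not np.isfinite(time[i]) or time[i] < 0:
            raise ValueError(f"{path}: row {row}: invalid survival time {df[time_col].iloc[i]!r}")
        if not np.isfinite(event[i]):
            raise ValueError(f"{path}: row {row}: event {df[event_col].iloc[i]!r} not in {{0,1}}")
    return SurvivalTable(ids, time, event)


def write_survival_table(surv: SurvivalTable, path: str | Path, sep: str = ",") -> None:
    surv.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def filter_features_by_missingness(
    m: OmicsMatrix,
    max_bad_fraction: float = 0.20,
    impute: str = "mean",
) -> OmicsMatrix:
    """Drop features with too many zero-or-missing entries; impute the rest.

    A feature is dropped when its count of entries that are missing OR
    exactly zero strictly exceeds ``max_bad_fraction * n_samples`` ("more
    than" the threshold, so an exact-boundary feature is retained).
    Remaining missing entries are handled per ``impute``:

    - ``"mean"`` (default): feature-wise observed mean,
    - ``"zero"``: replaced by 0,
    - ``"fail"``: any remaining missing value raises.
    """
    if not 0.0 <= max_bad_fraction <= 1.0:
        raise ValueError("max_bad_fraction must be in [0, 1]")
    if impute not in ("mean", "zero", "fail"):
        raise ValueError(f"unknown impute mode {impute!r}")
    bad = np.isnan(m.values) | (m.values == 0.0)
    keep = bad.sum(axis=0) <= max_bad_fraction * m.n_samples
    if not keep.any():
        raise ValueError(
            f"omic {m.omic_name!r}: every feature exceeds the zero-or-missing "
            f"threshold of {max_bad_fraction:.0%} of samples"
        )
    values = m.values[:, keep].copy()
    if np.isnan(values).any():
        if impute == "fail":
            raise ValueError(f"omic {m.omic_name!r}: missing values remain after filtering")
        if impute == "mean":
            col_mean = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = col_mean[idx[1]]
        else:
            values = np.nan_to_num(values, nan=0.0)
    feature_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(m.omic_name, list(m.sample_ids), feature_ids, values)


def align_cohort(
    layers: Sequence[OmicsMatrix],
    surv: SurvivalTable | None = None,
) -> tuple[list[OmicsMatrix], SurvivalTable | None]:
    """Restrict all inputs to their common samples, in one canonical order.

    The shared order is the lexicographic sort of the intersection of sample
    ids across all layers (and the survival table, if supplied), so matrices
    across omics are row-aligned by construction. The number of samples
    dropped from each input is logged.
    """
    if len(layers) < 2:
        raise ValueError("cohort alignment needs at least two omic layers")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if surv is not None:
        common &= set(surv.sample_ids)
    if not common:
        raise ValueError("no samples shared across all inputs")
    order = sorted(common)
    aligned: list[OmicsMatrix] = []
    for layer in layers:
        pos = {s: i for i, s in enumerate(layer.sample_ids)}
        idx = [pos[s] for s in order]
        dropped = layer.n_samples - len(order)
        log.info("align: omic %s dropped %d of %d samples", layer.omic_name, dropped, layer.n_samples)
        aligned.append(OmicsMatrix(layer.omic_name, order, list(layer.feature_ids), layer.values[idx]))
    surv_out = None
    if surv is not None:
        log.info("align: survival dropped %d of %d samples", surv.n_samples - len(order), surv.n_samples)
        surv_out = surv.subset(order)
    return aligned, surv_out


def preprocess_cohort(
    layers: Sequence[OmicsMatrix],
    surv: SurvivalTable | None = None,
    max_bad_fraction: float = 0.20,
    impute: str = "mean",
    zscore: bool = False,
) -> tuple[list[OmicsMatrix], SurvivalTable | None, dict]:
    """Full preprocessing: align, then filter each layer, with a JSON report.

    ``zscore`` optionally standardizes each retained feature to zero mean /
    unit variance after imputation (off by default: no per-feature scaling
    is applied unless requested).
    """
    aligned, surv_out = align_cohort(layers, surv)
    report: dict = {
        "n_samples": aligned[0].n_samples,
        "samples_dropped": {
            layer.omic_name: layer.n_samples - aligned[0].n_samples for layer in layers
        },
        "features_dropped": {},
    }
    if surv is not None:
        report["samples_dropped"]["survival"] = surv.n_samples - aligned[0].n_samples
    out: list[OmicsMatrix] = []
    for layer in aligned:
        filtered = filter_features_by_missingness(layer, max_bad_fraction, impute)
        report["features_dropped"][layer.omic_name] = layer.n_features - filtered.n_features
        if zscore:
            values = filtered.values
            sd = values.std(axis=0)
            sd[sd == 0] = 1.0
            filtered = OmicsMatrix(
                filtered.omic_name,
                list(filtered.sample_ids),
                list(filtered.feature_ids),
                (values - values.mean(axis=0)) / sd,
            )
        out.append(filtered)
    return out, surv_out, report


def write_preprocess_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
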