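"""Benchmark aggregation: representative values, scaled scores, weighted ranks.

The raw material is a long-form metric table with one row per
(method, dataset, pattern, replicate, metric). Summarisation proceeds in
three steps:

1. collapse replicates to a representative value (median over replicates
   for silver standards, mean over FOVs for gold, mean for rare-type AUPR);
2. per grouping (abundance pattern, data source, or metric), take the grand
   mean of each metric across datasets, min-max scale it across methods
   (inverting error-type metrics so 1 is always best) and combine the
   scaled metrics by geometric mean;
3. rank methods per criterion (1 = best, ties share the average rank) and
   order them by the weighted rank sum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "ERROR_METRICS",
    "BenchmarkSummary",
    "validate_metric_table",
    "representative_value",
    "summary_scores",
    "aggregate_rankings",
]

TABLE_COLUMNS = ["method", "dataset", "pattern", "replicate", "metric", "value"]

#: Metrics where lower is better; their min-max scaled values are inverted.
ERROR_METRICS = frozenset({"rmse", "jsd"})

_GEOMEAN_FLOOR = 1e-6

_REP_MODES = {
    "median_over_replicates": "median",
    "mean_over_replicates": "mean",
    "mean_over_fovs": "mean",
}

_GROUPINGS = {
    "per_pattern": "pattern",
    "per_data_source": "dataset",
    "per_metric": "metric",
}


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table missing columns {missing}")
    key = ["method", "dataset", "pattern", "replicate", "metric"]
    if table.duplicated(subset=key).any():
        raise ValueError("metric table has duplicate (method, dataset, pattern, replicate, metric) rows")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("metric values must be finite")
    return table


def representative_value(
    table: pd.DataFrame, mode: str = "median_over_replicates"
) -> pd.DataFrame:
    """Collapse replicates to one row per (method, dataset, pattern, metric)."""
    if mode not in _REP_MODES:
        raise ValueError(f"mode must be one of {sorted(_REP_MODES)}")
    validate_metric_table(table)
    if table.empty:
        raise ValueError("metric table is empty")
    agg = _REP_MODES[mode]
    out = (
        table.groupby(["method", "dataset", "pattern", "metric"], as_index=False)["value"]
        .agg(agg)
    )
    return out


def summary_scores(
    table: pd.DataFrame,
    grouping: str = "per_pattern",
    error_metrics: frozenset = ERROR_METRICS,
) -> pd.DataFrame:
    """Min-max scaled geometric-mean score per method per grouping.

    Within each grouping value, each metric's grand mean (across datasets)
    is min-max scaled across methods; error metrics (RMSE, JSD) are
    inverted after scaling so 1 is always best; the geometric mean of the
    scaled metrics gives the score. With ``grouping='per_metric'`` the
    score is the scaled metric itself (grand mean across all datasets).
    Zero spread in a metric gives every method a scaled value of 1, with a
    warning, rather than a division by zero.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPINGS)}")
    validate_metric_table(table)
    if table["method"].nunique() < 2:
        raise ValueError("min-max scaling needs at least 2 methods")
    group_col = _GROUPINGS[grouping]

    # grand mean of each metric per method within the grouping
    grand = (
        table.groupby([group_col, "method", "metric"], as_index=False)["value"].mean()
        if group_col != "metric"
        else table.groupby(["metric", "method"], as_index=False)["value"].mean()
    )

    records = []
    for gval, sub in grand.groupby(group_col):
        wide = sub.pivot_table(index="method", columns="metric", values="value")
        scaled = pd.DataFrame(index=wide.index)
        for metric in wide.columns:
            col = wide[metric]
            spread = col.max() - col.min()
            if spread == 0:
                warnings.warn(
                    f"metric {metric!r} has zero spread across methods in "
                    f"group {gval!r}; scaled value set to 1",
                    stacklevel=2,
                )
                s = pd.Series(1.0, index=col.index)
            else:
                s = (col - col.min()) / spread
                if metric in error_metrics:
                    s = 1.0 - s
            scaled[metric] = s
        floored = scaled.clip(lower=_GEOMEAN_FLOOR)
        if (scaled < _GEOMEAN_FLOOR).any().any():
            warnings.warn(
                f"geometric-mean floor {_GEOMEAN_FLOOR} applied in group {gval!r}",
                stacklevel=2,
            )
        score = np.exp(np.log(floored).mean(axis=1))
        for method, sc in score.items():
            records.append({"group": gval, "method": method, "score": float(sc)})
    out = pd.DataFrame(records)
    out.attrs["grouping"] = grouping
    return out


@dataclass
class BenchmarkSummary:
    """Per-criterion ranks, weighted totals, and the final method ordering."""

    ranks: pd.DataFrame  # method x criterion
    weights: pd.Series  # per criterion
    total_rank: pd.Series  # per method
    ordering: list  # best first


def aggregate_rankings(
    criterion_scores: pd.DataFrame | Mapping[str, Mapping[str, float]],
    weights: Mapping[str, float] | None = None,
) -> BenchmarkSummary:
    """Weighted rank aggregation across criteria.

    ``criterion_scores`` is a method x criterion table of scores where
    higher is better. Methods are ranked per criterion (1 = best, average
    ranks on ties); the total is the weighted rank sum and the final
    ordering is ascending in the total with deterministic lexicographic
    tie-breaking on the method name.
    """
    scores = pd.DataFrame(criterion_scores)
    if scores.isna().any().any():
        holes = [
            f"{m}/{c}"
            for m in scores.index
            for c in scores.columns
            if pd.isna(scores.loc[m, c])
        ]
        raise ValueError(f"missing scores for: {holes}")
    if weights is None:
        weights = {c: 1.0 for c in scores.columns}
    w = pd.Series(weights, dtype=float)
    missing_w = [c for c in scores.columns if c not in w.index]
    if missing_w:
        raise ValueError(f"missing weights for criteria: {missing_w}")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    w = w.loc[scores.columns]

    ranks = scores.rank(axis=0, ascending=False, method="average")
    total = (ranks * w).sum(axis=1)
    ordering = total.to_frame("total").assign(name=total.index).sort_values(
        ["total", "name"]
    ).index.tolist()
    return BenchmarkSummary(ranks=ranks, weights=w, total_rank=total, ordering=ordering)
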