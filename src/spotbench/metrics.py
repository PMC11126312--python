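"""Evaluation statistics for cell-type proportion predictions.

Three complementary views of accuracy:

* RMSE — per spot, ``sqrt(mean_z (p_known - p_pred)^2)`` over the Z cell
  types; numerically how close the proportions are. Because Z enters the
  formula, RMSE is not comparable across datasets with different Z.
* JSD — Jensen-Shannon divergence between the known and predicted
  proportion vectors, with base-2 logarithms so values lie in [0, 1];
  ``JSD(p||q) = KL(p||m)/2 + KL(q||m)/2`` with ``m = (p+q)/2``.
* AUPR — area under the precision-recall curve after binarising the truth
  (a type is present in a spot iff its true proportion exceeds zero).
  Micro-averaging pools all spot x type pairs into one curve; the
  per-cell-type variant scores one type's column, which is how rare-type
  detection is assessed.

Dataset-level RMSE/JSD are means over spots. ``sample_level_jsd`` supports
case-study evaluation against proportions measured by another technology:
each dataset is collapsed to its mean composition and all cross pairs are
compared. ``stability_jsd`` compares two predictions for the same spots
obtained from different reference datasets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .containers import ProportionMatrix

__all__ = [
    "MetricReport",
    "rmse",
    "jsd",
    "jsd_vectors",
    "micro_aupr",
    "celltype_aupr",
    "sample_level_jsd",
    "stability_jsd",
    "metric_report",
]


def _align(known: ProportionMatrix, predicted: ProportionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Align predicted to known by spot and cell-type ids; error on mismatch."""
    pred = predicted.reorder_columns(known.cell_type_ids)
    if known.n_spots != pred.n_spots:
        raise ValueError(
            f"spot counts differ ({known.n_spots} vs {pred.n_spots})"
        )
    if list(known.spot_ids) != list(pred.spot_ids):
        pos = {s: i for i, s in enumerate(pred.spot_ids)}
        try:
            order = [pos[s] for s in known.spot_ids]
        except KeyError as e:
            raise ValueError(f"spot id {e.args[0]!r} missing from prediction") from None
        pred = ProportionMatrix(pred.values[order], known.spot_ids, pred.cell_type_ids)
    return known.values, pred.values


def rmse(known: ProportionMatrix, predicted: ProportionMatrix) -> tuple[np.ndarray, float]:
    """Per-spot root-mean-square error over cell types, and its mean."""
    k, p = _align(known, predicted)
    per_spot = np.sqrt(np.mean((k - p) ** 2, axis=1))
    return per_spot, float(per_spot.mean())


def _kl_base2(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Row-wise KL(p||m) in bits with 0*log(0/.) := 0."""
    mask = p > 0  # wherever p > 0 the mixture m is also > 0
    ratio = np.ones_like(p)
    np.divide(p, m, out=ratio, where=mask)
    terms = np.zeros_like(p)
    np.multiply(p, np.log2(ratio), out=terms, where=mask)
    return terms.sum(axis=1)


def jsd_vectors(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise base-2 Jensen-Shannon divergence of probability vectors."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    for name, a in (("first", p), ("second", q)):
        sums = a.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-6:
            raise ValueError(f"{name} argument rows must sum to 1")
    m = 0.5 * (p + q)
    return 0.5 * _kl_base2(p, m) + 0.5 * _kl_base2(q, m)


def jsd(known: ProportionMatrix, predicted: ProportionMatrix) -> tuple[np.ndarray, float]:
    """Per-spot base-2 Jensen-Shannon divergence, and its mean over spots."""
    k, p = _align(known, predicted)
    per_spot = jsd_vectors(k, p)
    return per_spot, float(per_spot.mean())


def micro_aupr(known: ProportionMatrix, predicted: ProportionMatrix) -> float:
    """Micro-averaged AUPR of presence detection.

    Truth is binarised at zero (present iff proportion > 0); all spot x
    cell-type pairs are pooled into a single step-wise precision-recall
    curve. Raises when the pooled labels are all-positive or all-negative,
    where the curve is undefined.
    """
    k, p = _align(known, predicted)
    labels = (k > 0).ravel()
    scores = p.ravel()
    if labels.all() or not labels.any():
        raise ValueError(
            "micro-averaged AUPR undefined: pooled presence labels are all "
            f"{'positive' if labels.all() else 'negative'}"
        )
    return float(average_precision_score(labels, scores))


def celltype_aupr(
    known: ProportionMatrix, predicted: ProportionMatrix, cell_type: str
) -> float:
    """AUPR of one cell type's presence across spots (rare-type protocol)."""
    k, p = _align(known, predicted)
    if cell_type not in list(known.cell_type_ids):
        raise ValueError(f"unknown cell type {cell_type!r}")
    z = list(known.cell_type_ids).index(cell_type)
    labels = k[:, z] > 0
    if not labels.any():
        raise ValueError(f"cell type {cell_type!r} present in no spot; AUPR undefined")
    if labels.all():
        return 1.0
    return float(average_precision_score(labels, p[:, z]))


def _collapse(mat: ProportionMatrix, order: Sequence[str]) -> np.ndarray:
    v = mat.reorder_columns(order).values.mean(axis=0)
    return v / v.sum()


def sample_level_jsd(
    prediction_sets: Sequence[ProportionMatrix],
    reference_sets: Sequence[ProportionMatrix],
) -> tuple[np.ndarray, float]:
    """Pairwise JSD between collapsed mean compositions of two groups.

    Each dataset is reduced to its mean cell-type proportion vector
    (renormalised); the JSD is computed for every (prediction, reference)
    pair and the mean reported. Passing the same group on both sides and
    averaging the off-diagonal entries yields the biological-variation
    reference value.
    """
    if not prediction_sets or not reference_sets:
        raise ValueError("both groups must be non-empty")
    order = list(prediction_sets[0].cell_type_ids)
    preds = np.vstack([_collapse(m, order) for m in prediction_sets])
    refs = np.vstack([_collapse(m, order) for m in reference_sets])
    pairwise = np.empty((len(preds), len(refs)))
    for i, pv in enumerate(preds):
        for j, rv in enumerate(refs):
            pairwise[i, j] = jsd_vectors(pv, rv)[0]
    return pairwise, float(pairwise.mean())


def stability_jsd(
    pred_a: ProportionMatrix, pred_b: ProportionMatrix
) -> tuple[np.ndarray, float]:
    """Per-spot JSD between predictions from two different references."""
    return jsd(pred_a, pred_b)


@dataclass
class MetricReport:
    """Bundle of the three core metrics for one (truth, prediction) pair."""

    rmse: float
    jsd: float
    aupr: float
    per_spot_rmse: np.ndarray
    per_spot_jsd: np.ndarray
    n_spots: int
    n_cell_types: int


def metric_report(known: ProportionMatrix, predicted: ProportionMatrix) -> MetricReport:
    per_rmse, mean_rmse = rmse(known, predicted)
    per_jsd, mean_jsd = jsd(known, predicted)
    return MetricReport(
        rmse=mean_rmse,
        jsd=mean_jsd,
        aupr=micro_aupr(known, predicted),
        per_spot_rmse=per_rmse,
        per_spot_jsd=per_jsd,
        n_spots=known.n_spots,
        n_cell_types=known.n_cell_types,
    )
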