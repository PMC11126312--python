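"""Reference predictors included in every benchmark run.

Two baselines bracket the difficulty of a deconvolution task: non-negative
least squares (NNLS) on a cell-type signature matrix — the simplest
regression model that any dedicated method should beat — and random
proportions drawn from a symmetric Dirichlet, whose metric values define
the floor of uninformed prediction.
"""
from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls as _lawson_hanson_nnls

from .containers import AnnotatedReference, ProportionMatrix, SignatureMatrix

__all__ = [
    "build_signature",
    "nnls_deconvolve",
    "dirichlet_null",
    "average_null_metric",
]


def build_signature(ref: AnnotatedReference, cpm: bool = False) -> SignatureMatrix:
    """Average raw expression profile per cell type (gene x type).

    With ``cpm=True`` each cell is scaled to counts-per-million before
    averaging; the default keeps raw-count means.
    """
    counts = ref.counts.astype(float)
    if cpm:
        totals = counts.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        counts = counts / totals * 1e6
    types = ref.cell_types
    X = np.column_stack(
        [counts[:, np.flatnonzero(ref.cell_type == t)].mean(axis=1) for t in types]
    )
    return SignatureMatrix(X=X, gene_ids=ref.gene_ids, cell_type_ids=np.asarray(types, dtype=object))


def nnls_deconvolve(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    signature: SignatureMatrix,
    spot_ids: Sequence[str] | None = None,
) -> ProportionMatrix:
    """Per-spot Lawson-Hanson NNLS deconvolution against a signature.

    For each spot y the coefficients solve ``min ||y - X b||_2, b >= 0``
    over the genes shared between the spots and the signature (aligned by
    name, in signature order); proportions are ``b / sum(b)``. A spot with
    an all-zero solution falls back to the uniform vector with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    gene_ids = list(gene_ids)
    if spot_ids is None:
        spot_ids = [f"spot_{i:05d}" for i in range(counts.shape[0])]
    spot_pos = {g: i for i, g in enumerate(gene_ids)}
    shared = [g for g in signature.gene_ids.tolist() if g in spot_pos]
    if not shared:
        raise ValueError("no shared genes between spots and signature")
    sig_pos = {g: i for i, g in enumerate(signature.gene_ids.tolist())}
    X = signature.X[[sig_pos[g] for g in shared], :]
    Y = counts[:, [spot_pos[g] for g in shared]]

    Z = X.shape[1]
    props = np.empty((Y.shape[0], Z))
    fallback = 0
    for s in range(Y.shape[0]):
        beta, _ = _lawson_hanson_nnls(X, Y[s])
        total = beta.sum()
        if total <= 0:
            props[s] = np.full(Z, 1.0 / Z)
            fallback += 1
        else:
            props[s] = beta / total
    if fallback:
        warnings.warn(
            f"{fallback} spot(s) had an all-zero NNLS solution; "
            "uniform proportions substituted",
            stacklevel=2,
        )
    return ProportionMatrix(
        values=props, spot_ids=spot_ids, cell_type_ids=signature.cell_type_ids
    )


def dirichlet_null(
    n_spots: int,
    cell_type_ids: Sequence[str],
    alpha: float = 1.0,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    spot_ids: Sequence[str] | None = None,
) -> list[ProportionMatrix]:
    """Random-proportion null: ``n_iterations`` independent draws.

    Every row of every draw is a symmetric Dirichlet(alpha) sample over the
    cell types. Evaluation averages each metric over the iterations (see
    :func:`average_null_metric`), giving the chance-level reference value.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(cell_type_ids) < 1:
        raise ValueError("need at least one cell type")
    if rng is None:
        rng = np.random.default_rng()
    if spot_ids is None:
        spot_ids = [f"spot_{i:05d}" for i in range(n_spots)]
    Z = len(cell_type_ids)
    return [
        ProportionMatrix(
            values=rng.dirichlet(np.full(Z, alpha), size=n_spots),
            spot_ids=spot_ids,
            cell_type_ids=np.asarray(list(cell_type_ids), dtype=object),
        )
        for _ in range(n_iterations)
    ]


def average_null_metric(
    truth: ProportionMatrix,
    null_draws: Sequence[ProportionMatrix],
    metric: Callable[[ProportionMatrix, ProportionMatrix], float],
) -> float:
    """Metric value of the null baseline: the metric averaged over draws."""
    if not null_draws:
        raise ValueError("need at least one null draw")
    return float(np.mean([metric(truth, d) for d in null_draws]))
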