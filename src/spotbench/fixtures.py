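"""Synthetic annotated references and reference preprocessing.

The fixture generator produces an annotated single-cell count matrix from an
overdispersed (gamma-Poisson, i.e. negative binomial) count model with
planted marker genes per cell type, so that every downstream component can
be exercised without real data. The preprocessing functions implement the
reference curation applied before simulation: dropping ambiguous labels,
removing small cell types, keeping genes expressed in a minimum fraction of
cells of at least one type, and a stratified half/half split into a
spot-generation half and a deconvolution half.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .containers import AnnotatedReference, SegmentedImagingDataset

__all__ = [
    "FixtureConfig",
    "generate_reference",
    "filter_reference",
    "split_reference",
    "generate_imaging_fixture",
]


@dataclass
class FixtureConfig:
    """Parameters of the negative-binomial fixture model.

    Each cell type receives ``n_markers_per_type`` disjoint marker genes
    whose mean expression is inflated by ``marker_fold_change`` in cells of
    that type. Counts are gamma-Poisson: per-gene, per-cell rate drawn from
    Gamma(shape=1/dispersion, scale=mean*dispersion), then Poisson.
    """

    n_cell_types: int = 5
    n_cells_per_type: int = 100
    n_genes: int = 200
    n_markers_per_type: int = 10
    marker_fold_change: float = 8.0
    base_mean: float = 2.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "n_cells_per_type", "n_genes", "n_markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "n_markers_per_type x n_cell_types exceeds n_genes; "
                "marker blocks must be disjoint"
            )


def generate_reference(config: FixtureConfig) -> AnnotatedReference:
    """Draw an annotated reference from the fixture model.

    Deterministic given ``config.seed``; cells are grouped by type in
    column order with balanced type sizes.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    types = [f"type_{i:02d}" for i in range(config.n_cell_types)]
    mean = np.full((G, config.n_cell_types), config.base_mean)
    for z in range(config.n_cell_types):
        lo = z * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        mean[lo:hi, z] *= config.marker_fold_change

    blocks = []
    labels = []
    for z, t in enumerate(types):
        m = np.broadcast_to(mean[:, z][:, None], (G, config.n_cells_per_type))
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, m / shape)
        blocks.append(rng.poisson(lam))
        labels.extend([t] * config.n_cells_per_type)

    counts = np.concatenate(blocks, axis=1).astype(np.int64)
    n_cells = counts.shape[1]
    return AnnotatedReference(
        counts=counts,
        gene_ids=[f"gene_{g:04d}" for g in range(G)],
        cell_ids=[f"cell_{c:05d}" for c in range(n_cells)],
        cell_type=np.asarray(labels, dtype=object),
    )


def filter_reference(
    ref: AnnotatedReference,
    min_cells_per_type: int = 25,
    min_expr_fraction: float = 0.10,
    exclude_labels: Iterable[str] = (),
) -> AnnotatedReference:
    """Curate a reference before simulation or signature building.

    Cells whose label is in ``exclude_labels`` are dropped first (ambiguous
    annotations). Cell types with fewer than ``min_cells_per_type`` cells
    are removed (strictly fewer: a type with exactly the threshold count is
    kept). A gene survives iff it is expressed (count > 0) in at least
    ``min_expr_fraction`` of the cells of at least one surviving type; the
    boundary is inclusive. Gene and cell order of survivors is preserved.
    """
    if not 0 <= min_expr_fraction <= 1:
        raise ValueError("min_expr_fraction must be in [0, 1]")
    blocked = set(exclude_labels)
    keep_cell = ~np.isin(ref.cell_type, list(blocked)) if blocked else np.ones(ref.n_cells, bool)

    labels = ref.cell_type[keep_cell]
    kept_types = [t for t in sorted(set(labels.tolist())) if np.sum(labels == t) >= min_cells_per_type]
    if not kept_types:
        raise ValueError("no cell type survives the minimum-cells filter")
    keep_cell &= np.isin(ref.cell_type, kept_types)
    out = ref.subset_cells(np.flatnonzero(keep_cell))

    expressed = out.counts > 0
    keep_gene = np.zeros(out.n_genes, dtype=bool)
    for t in kept_types:
        cols = np.flatnonzero(out.cell_type == t)
        frac = expressed[:, cols].mean(axis=1)
        keep_gene |= frac >= min_expr_fraction
    if not keep_gene.any():
        raise ValueError("no gene survives the expression-fraction filter")
    return out.subset_genes(np.flatnonzero(keep_gene))


def split_reference(
    ref: AnnotatedReference, seed: int
) -> tuple[AnnotatedReference, AnnotatedReference]:
    """Stratified half/half split into (generation, deconvolution) halves.

    Within each cell type the cells are shuffled and partitioned into
    disjoint halves of sizes ceil(k/2) and floor(k/2); the larger half goes
    to the generation side. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gen_idx: list[int] = []
    dec_idx: list[int] = []
    for t in ref.cell_types:
        idx = np.flatnonzero(ref.cell_type == t)
        if len(idx) < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells; cannot split")
        perm = rng.permutation(idx)
        half = (len(idx) + 1) // 2
        gen_idx.extend(perm[:half].tolist())
        dec_idx.extend(perm[half:].tolist())
    return ref.subset_cells(np.sort(gen_idx)), ref.subset_cells(np.sort(dec_idx))


def generate_imaging_fixture(
    config: FixtureConfig,
    fov_width_um: float = 206.0,
    fov_height_um: float = 206.0,
    n_cells: int | None = None,
    n_fovs: int = 1,
    seed: int | None = None,
) -> SegmentedImagingDataset:
    """Segmented-imaging stand-in: fixture cells with uniform 2-D centroids.

    Counts and labels follow the same model as :func:`generate_reference`;
    centroids are uniform on the FOV rectangle, independently per FOV.
    """
    if fov_width_um <= 0 or fov_height_um <= 0:
        raise ValueError("FOV dimensions must be positive")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    ref = generate_reference(config)
    total = ref.n_cells if n_cells is None else int(n_cells)

    if total == 0:
        empty = np.zeros(0)
        return SegmentedImagingDataset(
            counts=np.zeros((ref.n_genes, 0), dtype=np.int64),
            gene_ids=ref.gene_ids,
            cell_ids=[],
            centroid_x=empty,
            centroid_y=empty,
            cell_type=np.asarray([], dtype=object),
            fov_id=np.asarray([], dtype=object),
        )

    pick = rng.choice(ref.n_cells, size=total, replace=total > ref.n_cells)
    sub = ref.subset_cells(pick)
    fovs = np.asarray([f"fov_{i % n_fovs:02d}" for i in range(total)], dtype=object)
    return SegmentedImagingDataset(
        counts=sub.counts,
        gene_ids=sub.gene_ids,
        cell_ids=[f"cell_{c:05d}" for c in range(total)],
        centroid_x=rng.uniform(0, fov_width_um, size=total),
        centroid_y=rng.uniform(0, fov_height_um, size=total),
        cell_type=sub.cell_type,
        fov_id=fovs,
    )
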