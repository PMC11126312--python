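"""Core data containers shared across the toolkit.

All containers are plain dataclasses over numpy arrays with light validation.
Count matrices follow the single-cell convention of genes in rows for
references and imaging data, and the spatial convention of spots in rows for
spot-level datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedReference",
    "SegmentedImagingDataset",
    "ProportionMatrix",
    "SignatureMatrix",
    "SyntheticSpotDataset",
]

PROPORTION_TOL = 1e-6


def _as_str_array(x: Sequence[str]) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass
class AnnotatedReference:
    """A gene x cell count matrix with one cell-type label per cell.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Row and column identifiers.
    cell_type
        One label per cell, aligned with ``cell_ids``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.cell_type = _as_str_array(self.cell_type)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} columns")
        if len(self.cell_type) != n_cells:
            raise ValueError("need exactly one cell-type label per cell")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list:
        """Sorted unique cell-type labels (deterministic column order)."""
        return sorted(set(self.cell_type.tolist()))

    def type_indices(self) -> dict:
        """Map cell-type label -> integer indices of its cells."""
        out: dict = {}
        for t in self.cell_types:
            out[t] = np.flatnonzero(self.cell_type == t)
        return out

    def subset_cells(self, idx: np.ndarray) -> "AnnotatedReference":
        idx = np.asarray(idx)
        return AnnotatedReference(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_type=self.cell_type[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "AnnotatedReference":
        idx = np.asarray(idx)
        return AnnotatedReference(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            cell_type=self.cell_type,
        )


@dataclass
class SegmentedImagingDataset:
    """Segmented cells from imaging-based spatial data.

    Counts are genes x cells; centroids are in micrometres unless a pixel
    scale is applied downstream. ``fov_id`` groups cells into fields of view
    that are pooled independently.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    centroid_x: np.ndarray
    centroid_y: np.ndarray
    cell_type: np.ndarray
    fov_id: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.cell_type = _as_str_array(self.cell_type)
        self.fov_id = _as_str_array(self.fov_id)
        self.centroid_x = np.asarray(self.centroid_x, dtype=float)
        self.centroid_y = np.asarray(self.centroid_y, dtype=float)
        n_genes, n_cells = self.counts.shape
        for name, arr in [
            ("cell_ids", self.cell_ids),
            ("centroid_x", self.centroid_x),
            ("centroid_y", self.centroid_y),
            ("cell_type", self.cell_type),
            ("fov_id", self.fov_id),
        ]:
            if len(arr) != n_cells:
                raise ValueError(f"{name} length {len(arr)} != {n_cells} cells")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        coords = np.concatenate([self.centroid_x, self.centroid_y])
        if coords.size and (not np.all(np.isfinite(coords)) or np.any(coords < 0)):
            raise ValueError("centroids must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "SegmentedImagingDataset":
        idx = np.asarray(idx)
        return SegmentedImagingDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            centroid_x=self.centroid_x[idx],
            centroid_y=self.centroid_y[idx],
            cell_type=self.cell_type[idx],
            fov_id=self.fov_id[idx],
        )


@dataclass
class ProportionMatrix:
    """Spot x cell-type proportions; rows are probability vectors.

    Used both for ground truth and for method predictions. Rows must be
    non-negative and sum to 1 within ``1e-6``; all-zero rows are rejected.
    """

    values: np.ndarray
    spot_ids: np.ndarray
    cell_type_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spot_ids = _as_str_array(self.spot_ids)
        self.cell_type_ids = _as_str_array(self.cell_type_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D spot x cell-type matrix")
        if self.values.shape != (len(self.spot_ids), len(self.cell_type_ids)):
            raise ValueError("id lists do not match matrix shape")
        if np.any(self.values < 0):
            raise ValueError("proportions must be non-negative")
        sums = self.values.sum(axis=1)
        if self.values.shape[0] and np.max(np.abs(sums - 1.0)) > PROPORTION_TOL:
            bad = np.flatnonzero(np.abs(sums - 1.0) > PROPORTION_TOL)
            raise ValueError(
                f"{len(bad)} rows do not sum to 1 within {PROPORTION_TOL} "
                f"(first: {self.spot_ids[bad[0]]!r} sums to {sums[bad[0]]:.6g})"
            )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.spot_ids, name="spot_id"),
            columns=list(self.cell_type_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            spot_ids=df.index.to_numpy(),
            cell_type_ids=df.columns.to_numpy(),
        )

    def reorder_columns(self, cell_type_ids: Sequence[str]) -> "ProportionMatrix":
        """Return a copy with columns in the given order.

        Raises ``ValueError`` when the requested set of cell types differs
        from the one present — columns are never silently subset.
        """
        wanted = list(cell_type_ids)
        have = list(self.cell_type_ids)
        if sorted(wanted) != sorted(have):
            missing = sorted(set(wanted) - set(have))
            extra = sorted(set(have) - set(wanted))
            raise ValueError(
                f"cell-type sets differ (missing={missing}, extra={extra})"
            )
        pos = {t: i for i, t in enumerate(have)}
        order = [pos[t] for t in wanted]
        return ProportionMatrix(
            values=self.values[:, order],
            spot_ids=self.spot_ids,
            cell_type_ids=np.asarray(wanted, dtype=object),
        )


@dataclass
class SignatureMatrix:
    """Gene x cell-type matrix of mean reference expression per type."""

    X: np.ndarray
    gene_ids: np.ndarray
    cell_type_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_type_ids = _as_str_array(self.cell_type_ids)
        if self.X.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValueError("id lists do not match matrix shape")
        if np.any(self.X < 0):
            raise ValueError("signature must be non-negative")


@dataclass
class SyntheticSpotDataset:
    """A spot-level dataset with known composition.

    Produced either by the simulator (silver standard) or by pooling
    segmented cells inside Visium-sized circles (gold standard). ``counts``
    is spots x genes; ``truth`` carries the per-spot cell-type proportions.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    truth: ProportionMatrix
    region_label: np.ndarray
    n_cells: np.ndarray
    config: dict = field(default_factory=dict)
    spot_centres: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.spot_ids = _as_str_array(self.spot_ids)
        self.region_label = np.asarray(self.region_label)
        self.n_cells = np.asarray(self.n_cells)
        n_spots, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.spot_ids) != n_spots:
            raise ValueError("id lists do not match counts shape")
        if len(self.region_label) != n_spots or len(self.n_cells) != n_spots:
            raise ValueError("per-spot annotations do not match counts shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.truth.n_spots != n_spots:
            raise ValueError("truth does not match number of spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]
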