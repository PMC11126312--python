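"""Gold-standard pseudo-spots: pooling segmented cells in Visium-sized circles.

Circles with the diameter of a 10x Visium spot (55 µm by default) are tiled
on a zero-gap square grid over each field of view; every cell whose
centroid falls inside a circle contributes its counts to that pseudo-spot,
and the cell-type frequencies of the member cells become the ground-truth
proportions. Because the grid pitch equals the diameter, circles are
disjoint and each cell belongs to at most one spot; cells in the gaps
between circles are ignored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import ProportionMatrix, SegmentedImagingDataset, SyntheticSpotDataset

__all__ = ["PoolingConfig", "pool_to_spots"]


@dataclass
class PoolingConfig:
    """Geometry of the pseudo-spot tiling.

    ``um_per_pixel`` converts stored coordinates to micrometres (1.0 when
    coordinates are already in µm; e.g. 0.103 for 103 nm pixels).
    ``grid_origin`` offsets the tiling anchor, which defaults to the
    bounding-box minimum of each FOV's centroids.
    """

    spot_diameter_um: float = 55.0
    um_per_pixel: float = 1.0
    grid_origin: tuple[float, float] = (0.0, 0.0)
    min_cells_per_spot: int = 1

    def __post_init__(self) -> None:
        if self.spot_diameter_um <= 0:
            raise ValueError("spot_diameter_um must be positive")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")


def pool_to_spots(
    imaging: SegmentedImagingDataset,
    config: PoolingConfig | None = None,
    exclude_labels: Iterable[str] = (),
) -> SyntheticSpotDataset:
    """Pool per-cell counts into circle pseudo-spots, one grid per FOV.

    Membership is by centroid: a cell belongs to the circle whose centre is
    within one radius (boundary inclusive). Spots with fewer than
    ``min_cells_per_spot`` member cells are dropped. Returns a spot dataset
    whose region labels are the FOV ids and whose ``spot_centres`` table
    records circle centres in µm.
    """
    if config is None:
        config = PoolingConfig()
    blocked = set(exclude_labels)
    if blocked:
        keep = ~np.isin(imaging.cell_type, list(blocked))
        imaging = imaging.subset_cells(np.flatnonzero(keep))

    d = config.spot_diameter_um
    radius = d / 2.0
    ox, oy = config.grid_origin
    x = imaging.centroid_x * config.um_per_pixel
    y = imaging.centroid_y * config.um_per_pixel
    types = sorted(set(imaging.cell_type.tolist()))
    type_pos = {t: i for i, t in enumerate(types)}

    counts_rows: list[np.ndarray] = []
    truth_rows: list[np.ndarray] = []
    regions: list[str] = []
    n_cells: list[int] = []
    centres: list[tuple[str, float, float, str]] = []

    for fov in sorted(set(imaging.fov_id.tolist())):
        idx = np.flatnonzero(imaging.fov_id == fov)
        fx, fy = x[idx], y[idx]
        x0 = fx.min() + ox
        y0 = fy.min() + oy
        span_x = fx.max() - x0
        span_y = fy.max() - y0
        nx = max(1, math.floor(span_x / d))
        ny = max(1, math.floor(span_y / d))

        # grid-cell index, then the inscribed-circle distance test
        ix = np.floor((fx - x0) / d).astype(int)
        iy = np.floor((fy - y0) / d).astype(int)
        in_grid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        cx = x0 + (ix + 0.5) * d
        cy = y0 + (iy + 0.5) * d
        inside = in_grid & ((fx - cx) ** 2 + (fy - cy) ** 2 <= radius**2 + 1e-12)

        for j in range(nx):
            for i in range(ny):
                member = idx[inside & (ix == j) & (iy == i)]
                if len(member) < config.min_cells_per_spot or len(member) == 0:
                    continue
                counts_rows.append(imaging.counts[:, member].sum(axis=1))
                tv = np.zeros(len(types))
                for t in imaging.cell_type[member]:
                    tv[type_pos[t]] += 1
                truth_rows.append(tv / tv.sum())
                regions.append(str(fov))
                n_cells.append(len(member))
                centres.append(
                    (f"{fov}_spot_{j:02d}_{i:02d}", x0 + (j + 0.5) * d, y0 + (i + 0.5) * d, str(fov))
                )

    n_spots = len(counts_rows)
    spot_ids = [c[0] for c in centres]
    gene_axis = len(imaging.gene_ids)
    counts = (
        np.vstack(counts_rows).astype(np.int64)
        if n_spots
        else np.zeros((0, gene_axis), dtype=np.int64)
    )
    truth = ProportionMatrix(
        values=np.vstack(truth_rows) if n_spots else np.zeros((0, len(types))),
        spot_ids=spot_ids,
        cell_type_ids=np.asarray(types, dtype=object),
    )
    centres_df = pd.DataFrame(centres, columns=["spot_id", "x_um", "y_um", "fov_id"])
    return SyntheticSpotDataset(
        counts=counts,
        gene_ids=imaging.gene_ids,
        spot_ids=spot_ids,
        truth=truth,
        region_label=np.asarray(regions, dtype=object),
        n_cells=np.asarray(n_cells, dtype=int),
        config={
            "spot_diameter_um": d,
            "um_per_pixel": config.um_per_pixel,
            "min_cells_per_spot": config.min_cells_per_spot,
        },
        spot_centres=centres_df,
    )
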