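"""Plain-text readers and writers for all on-disk artifacts.

Counts travel as Matrix Market (.mtx) with TSV id lists; proportions,
region labels, imaging cell tables and metric tables are tab-separated
with header rows; configuration echoes are flat ``key=value`` text.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    AnnotatedReference,
    ProportionMatrix,
    SegmentedImagingDataset,
    SyntheticSpotDataset,
)

__all__ = [
    "read_reference",
    "write_reference",
    "read_imaging",
    "write_imaging",
    "read_spot_dataset",
    "write_spot_dataset",
    "read_proportions",
    "write_proportions",
    "read_keyvalue",
    "write_keyvalue",
]


def _write_counts(counts: np.ndarray, path: Path) -> None:
    spio.mmwrite(str(path), sparse.coo_matrix(np.asarray(counts)))


def _read_counts(path: Path) -> np.ndarray:
    return np.asarray(spio.mmread(str(path)).todense()).astype(np.int64)


def write_reference(ref: AnnotatedReference, outdir: str | Path) -> None:
    """Write counts.mtx (genes x cells), genes.tsv and cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_counts(ref.counts, outdir / "counts.mtx")
    pd.DataFrame({"gene_id": ref.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"cell_id": ref.cell_ids, "cell_type": ref.cell_type}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_reference(indir: str | Path) -> AnnotatedReference:
    indir = Path(indir)
    counts = _read_counts(indir / "counts.mtx")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return AnnotatedReference(
        counts=counts,
        gene_ids=genes["gene_id"].astype(str).tolist(),
        cell_ids=cells["cell_id"].astype(str).tolist(),
        cell_type=cells["cell_type"].astype(str).to_numpy(),
    )


def write_imaging(ds: SegmentedImagingDataset, outdir: str | Path) -> None:
    """Write counts.mtx (genes x cells), genes.tsv and a cell table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_counts(ds.counts, outdir / "counts.mtx")
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "x_um": ds.centroid_x,
            "y_um": ds.centroid_y,
            "cell_type": ds.cell_type,
            "fov_id": ds.fov_id,
        }
    ).to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_imaging(indir: str | Path) -> SegmentedImagingDataset:
    indir = Path(indir)
    counts = _read_counts(indir / "counts.mtx")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return SegmentedImagingDataset(
        counts=counts,
        gene_ids=genes["gene_id"].astype(str).tolist(),
        cell_ids=cells["cell_id"].astype(str).tolist(),
        centroid_x=cells["x_um"].to_numpy(float),
        centroid_y=cells["y_um"].to_numpy(float),
        cell_type=cells["cell_type"].astype(str).to_numpy(),
        fov_id=cells["fov_id"].astype(str).to_numpy(),
    )


def write_proportions(matrix: ProportionMatrix, path: str | Path) -> None:
    """Tab-separated spot x cell-type table with a spot_id column."""
    matrix.to_frame().to_csv(Path(path), sep="\t")


def read_proportions(path: str | Path, renormalize: bool = False) -> ProportionMatrix:
    """Read a proportion TSV; validates rather than silently repairing.

    Rows must sum to 1 within 1e-6 unless ``renormalize=True``, in which
    case rows are rescaled (all-zero rows still rejected). Duplicate spot
    ids, negative values and non-numeric cells are errors.
    """
    df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate spot ids: {dups}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("non-numeric cells in proportion table")
    if (values < 0).any():
        raise ValueError("negative proportions in table")
    if renormalize:
        sums = values.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("cannot renormalize all-zero rows")
        values = values / sums
    return ProportionMatrix(
        values=values,
        spot_ids=df.index.astype(str).to_numpy(),
        cell_type_ids=df.columns.astype(str).to_numpy(),
    )


def write_keyvalue(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in config.items():
            fh.write(f"{k}={v}\n")


def read_keyvalue(path: str | Path) -> dict:
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        out[k.strip()] = v.strip()
    return out


def write_spot_dataset(ds: SyntheticSpotDataset, outdir: str | Path) -> None:
    """Write a spot dataset: counts, ids, truth, regions, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_counts(ds.counts, outdir / "counts.mtx")
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"spot_id": ds.spot_ids, "region": ds.region_label, "n_cells": ds.n_cells}
    ).to_csv(outdir / "spots.tsv", sep="\t", index=False)
    write_proportions(ds.truth, outdir / "truth.tsv")
    write_keyvalue(ds.config, outdir / "config.txt")
    if ds.spot_centres is not None:
        ds.spot_centres.to_csv(outdir / "spot_centres.tsv", sep="\t", index=False)


def read_spot_dataset(indir: str | Path) -> SyntheticSpotDataset:
    indir = Path(indir)
    counts = _read_counts(indir / "counts.mtx")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    spots = pd.read_csv(indir / "spots.tsv", sep="\t")
    truth = read_proportions(indir / "truth.tsv")
    centres_path = indir / "spot_centres.tsv"
    centres = pd.read_csv(centres_path, sep="\t") if centres_path.exists() else None
    return SyntheticSpotDataset(
        counts=counts,
        gene_ids=genes["gene_id"].astype(str).tolist(),
        spot_ids=spots["spot_id"].astype(str).to_numpy(),
        truth=truth,
        region_label=spots["region"].to_numpy(),
        n_cells=spots["n_cells"].to_numpy(),
        config=read_keyvalue(indir / "config.txt") if (indir / "config.txt").exists() else {},
        spot_centres=centres,
    )
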