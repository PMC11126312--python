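"""Synthetic Visium-like spot simulation with artificial tissue patterns.

A synthetic dataset is organised into artificial regions; every spot in a
region shares the region's *frequency priors* — the probabilities with
which each cell type is sampled into a spot. The priors are shaped by an
abundance pattern combining three characteristics:

* uniformity: ``uniform`` gives every present type the same prior in a
  region, ``diverse`` draws unequal priors from a symmetric Dirichlet(1);
* region sharing: ``distinct`` confines each cell type to exactly one
  region, ``overlap`` lets types appear in several regions;
* a special role: a *dominant* cell type 5-15x more abundant than every
  other present type, or a *rare* one 5-15x less abundant, in all regions
  or in a single region.

A spot pools n ~ Uniform{cells_min..cells_max} cells drawn from the
region's priors, sums their gene counts, and downsamples the pooled
transcripts without replacement to a per-spot target drawn from
Normal(visium_mean, visium_sd). The realised cell-type fractions of the
sampled cells are recorded as ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .containers import AnnotatedReference, ProportionMatrix, SyntheticSpotDataset

__all__ = [
    "SimConfig",
    "AbundancePattern",
    "FrequencyPriors",
    "PATTERN_REGISTRY",
    "DEFAULT_PATTERNS",
    "build_region_layout",
    "build_frequency_priors",
    "compose_spot",
    "downsample_counts",
    "generate_synthetic_visium",
]


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the standard benchmark settings.

    ``visium_mean``/``visium_sd`` parameterise the per-spot downsampling
    target (counts); ``cells_min``/``cells_max`` bound the number of cells
    pooled per spot; dominant/rare factor ranges bound the abundance ratio
    imposed by the special patterns.
    """

    n_regions: int = 5
    n_spots_min: int = 100
    n_spots_max: int = 200
    visium_mean: float = 20000.0
    visium_sd: float = 5000.0
    cells_min: int = 2
    cells_max: int = 10
    dominant_factor_range: tuple[float, float] = (5.0, 15.0)
    rare_factor_range: tuple[float, float] = (5.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_spots_min > self.n_spots_max or self.n_spots_min < 1:
            raise ValueError("need 1 <= n_spots_min <= n_spots_max")
        if self.cells_min > self.cells_max or self.cells_min < 1:
            raise ValueError("need 1 <= cells_min <= cells_max")
        if self.visium_mean <= 0 or self.visium_sd < 0:
            raise ValueError("visium_mean must be > 0 and visium_sd >= 0")
        for rng_ in (self.dominant_factor_range, self.rare_factor_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("factor ranges must satisfy 0 < lo <= hi")


_UNIFORMITY = ("uniform", "diverse")
_SHARING = ("distinct", "overlap")
_SPECIAL = (
    "none",
    "dominant_all_regions",
    "dominant_one_region",
    "rare_all_regions",
    "rare_one_region",
)


@dataclass(frozen=True)
class AbundancePattern:
    """One combination of the three abundance characteristics."""

    uniformity: str = "diverse"
    region_sharing: str = "overlap"
    special: str = "none"

    def __post_init__(self) -> None:
        if self.uniformity not in _UNIFORMITY:
            raise ValueError(f"uniformity must be one of {_UNIFORMITY}")
        if self.region_sharing not in _SHARING:
            raise ValueError(f"region_sharing must be one of {_SHARING}")
        if self.special not in _SPECIAL:
            raise ValueError(f"special must be one of {_SPECIAL}")


#: The nine benchmark abundance patterns. The registry is an ordinary dict
#: and can be extended or replaced by callers.
PATTERN_REGISTRY: dict[str, AbundancePattern] = {
    "uniform_distinct": AbundancePattern("uniform", "distinct", "none"),
    "diverse_distinct": AbundancePattern("diverse", "distinct", "none"),
    "uniform_overlap": AbundancePattern("uniform", "overlap", "none"),
    "diverse_overlap": AbundancePattern("diverse", "overlap", "none"),
    "dominant_celltype_diverse": AbundancePattern("diverse", "overlap", "dominant_all_regions"),
    "partially_dominant_celltype_diverse": AbundancePattern(
        "diverse", "overlap", "dominant_one_region"
    ),
    "rare_celltype_diverse": AbundancePattern("diverse", "overlap", "rare_all_regions"),
    "regional_rare_celltype_diverse": AbundancePattern("diverse", "overlap", "rare_one_region"),
    "dominant_celltype_uniform": AbundancePattern("uniform", "overlap", "dominant_all_regions"),
}

DEFAULT_PATTERNS: tuple[str, ...] = tuple(PATTERN_REGISTRY)


@dataclass
class FrequencyPriors:
    """Region x cell-type sampling probabilities plus special-type metadata."""

    priors: np.ndarray
    cell_types: np.ndarray
    special_cell_type: str | None = None
    region_of_special: int | None = None

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.cell_types = np.asarray(list(self.cell_types), dtype=object)
        if self.priors.ndim != 2 or self.priors.shape[1] != len(self.cell_types):
            raise ValueError("priors must be region x cell-type")
        if np.any(self.priors < 0):
            raise ValueError("priors must be non-negative")
        sums = self.priors.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValueError("each region's priors must sum to 1")

    @property
    def n_regions(self) -> int:
        return self.priors.shape[0]


def build_region_layout(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the number of spots per region, uniform on the configured bounds."""
    return rng.integers(config.n_spots_min, config.n_spots_max + 1, size=config.n_regions)


def _presence(pattern: AbundancePattern, n_types: int, n_regions: int,
              rng: np.random.Generator) -> np.ndarray:
    """Boolean region x type presence matrix under the sharing characteristic."""
    if pattern.region_sharing == "distinct" and n_regions > n_types:
        raise ValueError(
            f"distinct sharing needs at least one cell type per region "
            f"({n_types} types < {n_regions} regions)"
        )
    present = np.zeros((n_regions, n_types), dtype=bool)
    order = rng.permutation(n_types)
    # near-equal partition of types over regions gives each type a home region
    for i, chunk in enumerate(np.array_split(order, n_regions)):
        present[i, chunk] = True
    if pattern.region_sharing == "overlap":
        for r in range(n_regions):  # with fewer types than regions some homes are empty
            if not present[r].any():
                present[r, rng.integers(n_types)] = True
        for z in range(n_types):
            if n_regions > 1 and rng.random() < 0.5:
                home = int(np.flatnonzero(present[:, z])[0])
                extra = int(rng.choice([r for r in range(n_regions) if r != home]))
                present[extra, z] = True
    return present


def build_frequency_priors(
    pattern: AbundancePattern,
    cell_types: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> FrequencyPriors:
    """Build the region x cell-type sampling probabilities for a dataset.

    Priors are drawn once per dataset so that spots within a region share a
    composition profile. Under a dominant (rare) special, the affected
    region's priors are constructed so that the ratio of the special type's
    prior to every other present type's prior (respectively its inverse)
    falls inside the configured factor range, with an independent factor
    draw per other type under ``diverse`` and a single shared draw under
    ``uniform``.
    """
    types = np.asarray(list(cell_types), dtype=object)
    Z = len(types)
    R = config.n_regions
    if Z < 2:
        raise ValueError("need at least 2 cell types")
    present = _presence(pattern, Z, R, rng)

    priors = np.zeros((R, Z))
    for r in range(R):
        cols = np.flatnonzero(present[r])
        if pattern.uniformity == "uniform":
            priors[r, cols] = 1.0 / len(cols)
        else:
            priors[r, cols] = rng.dirichlet(np.ones(len(cols)))

    special_type: str | None = None
    special_region: int | None = None
    if pattern.special != "none":
        kind, _, scope = pattern.special.partition("_")  # dominant|rare, all_regions|one_region
        lo, hi = (
            config.dominant_factor_range if kind == "dominant" else config.rare_factor_range
        )
        if scope == "one_region":
            special_region = int(rng.integers(R))
            affected = [special_region]
        else:
            affected = list(range(R))
        # the special type must be present (with company) in every affected region
        if scope == "one_region":
            cols = np.flatnonzero(present[special_region])
            if len(cols) < 2:
                extra = int(rng.choice(np.flatnonzero(~present[special_region])))
                present[special_region, extra] = True
                priors[special_region, extra] = 0.0
                cols = np.flatnonzero(present[special_region])
            z_special = int(rng.choice(cols))
        else:
            z_special = int(rng.integers(Z))
            for r in affected:
                present[r, z_special] = True
                if present[r].sum() < 2:
                    extra = int(rng.choice(np.flatnonzero(~present[r])))
                    present[r, extra] = True
        special_type = str(types[z_special])

        for r in affected:
            others = np.flatnonzero(present[r] & (np.arange(Z) != z_special))
            if pattern.uniformity == "uniform":
                factors = np.full(len(others), rng.uniform(lo, hi))
            else:
                factors = rng.uniform(lo, hi, size=len(others))
            row = np.zeros(Z)
            row[z_special] = 1.0
            row[others] = 1.0 / factors if kind == "dominant" else factors
            priors[r] = row / row.sum()

    priors = priors / priors.sum(axis=1, keepdims=True)
    return FrequencyPriors(
        priors=priors,
        cell_types=types,
        special_cell_type=special_type,
        region_of_special=special_region,
    )


def downsample_counts(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Subsample pooled transcripts without replacement to ``target`` total.

    Draws a multivariate hypergeometric sample over genes; if the input
    already totals at most ``target`` it is returned unchanged (counts are
    never inflated).
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total <= target:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(target),
                                           method="marginals")


def compose_spot(
    generation_half: AnnotatedReference,
    region_priors: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    target: int | None = None,
    _groups: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Synthesize one spot under a region's frequency priors.

    Returns ``(gene_counts, truth_proportions, n_cells)``. Each of the n
    cells is drawn by first sampling its type from the priors, then sampling
    a cell of that type uniformly with replacement. Truth proportions are
    the exact sampled-type fractions.
    """
    types = generation_half.cell_types
    priors = np.asarray(region_priors, dtype=float)
    if len(priors) != len(types):
        raise ValueError("priors length does not match reference cell types")
    groups = _groups if _groups is not None else generation_half.type_indices()
    for z, t in enumerate(types):
        if priors[z] > 0 and len(groups[t]) == 0:
            raise ValueError(f"cell type {t!r} has nonzero prior but no cells")

    n = int(rng.integers(config.cells_min, config.cells_max + 1))
    drawn = rng.choice(len(types), size=n, p=priors / priors.sum())
    gene_counts = np.zeros(generation_half.n_genes, dtype=np.int64)
    type_counts = np.zeros(len(types), dtype=np.int64)
    for z in drawn:
        cells = groups[types[z]]
        c = cells[rng.integers(len(cells))]
        gene_counts += generation_half.counts[:, c]
        type_counts[z] += 1
    if target is None:
        target = max(0, round(rng.normal(config.visium_mean, config.visium_sd)))
    gene_counts = downsample_counts(gene_counts, int(target), rng)
    return gene_counts, type_counts / n, n


def generate_synthetic_visium(
    generation_half: AnnotatedReference,
    pattern: AbundancePattern | str,
    config: SimConfig | None = None,
) -> SyntheticSpotDataset:
    """Generate one synthetic replicate: layout, priors, and all spots.

    Fully deterministic given ``config.seed`` (child generators are spawned
    per region so regions are independent streams).
    """
    if isinstance(pattern, str):
        pattern = PATTERN_REGISTRY[pattern]
    if config is None:
        config = SimConfig()
    root = np.random.default_rng(config.seed)
    types = generation_half.cell_types
    layout = build_region_layout(config, root)
    fp = build_frequency_priors(pattern, types, config, root)
    groups = generation_half.type_indices()

    region_rngs = [np.random.default_rng(s) for s in
                   np.random.SeedSequence(config.seed).spawn(config.n_regions)]
    counts_rows: list[np.ndarray] = []
    truth_rows: list[np.ndarray] = []
    region_label: list[int] = []
    n_cells: list[int] = []
    for r, size in enumerate(layout):
        rng = region_rngs[r]
        for _ in range(int(size)):
            gc, tp, n = compose_spot(
                generation_half, fp.priors[r], config, rng, _groups=groups
            )
            counts_rows.append(gc)
            truth_rows.append(tp)
            region_label.append(r)
            n_cells.append(n)

    n_spots = len(counts_rows)
    spot_ids = [f"spot_{i:05d}" for i in range(n_spots)]
    truth = ProportionMatrix(
        values=np.vstack(truth_rows),
        spot_ids=spot_ids,
        cell_type_ids=np.asarray(types, dtype=object),
    )
    cfg = asdict(config)
    cfg.update(
        pattern_uniformity=pattern.uniformity,
        pattern_region_sharing=pattern.region_sharing,
        pattern_special=pattern.special,
        special_cell_type=fp.special_cell_type,
        region_of_special=fp.region_of_special,
    )
    return SyntheticSpotDataset(
        counts=np.vstack(counts_rows),
        gene_ids=generation_half.gene_ids,
        spot_ids=spot_ids,
        truth=truth,
        region_label=np.asarray(region_label),
        n_cells=np.asarray(n_cells),
        config=cfg,
    )
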