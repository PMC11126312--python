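# Methods

This note documents the models and procedures implemented in spotbench,
the parameters that matter, the numerical choices, and what the bundled
fixtures do and do not emulate.

## Synthetic spot simulation (silver standards)

A synthetic dataset is a set of artificial regions; all spots in a region
share that region's *frequency priors* — the probabilities with which
each cell type is sampled into a spot. Generation of one replicate:

1. **Region layout.** `n_regions` (default 5) region sizes are drawn
   uniformly from `[n_spots_min, n_spots_max]` (default [100, 200]),
   giving on average 750 spots per replicate.
2. **Frequency priors.** Presence of types in regions follows the
   region-sharing characteristic: under *distinct*, the (shuffled) type
   list is partitioned near-equally across regions, so each type is
   present in exactly one region; under *overlap*, each type gets a home
   region the same way and, with probability 0.5, one extra region.
   Within a region, *uniform* gives equal priors over present types and
   *diverse* draws them from a symmetric Dirichlet(1) — any exchangeable
   nondegenerate choice would do; Dirichlet(1) matches the convention
   used for the null baseline. A *dominant* (or *rare*) special rebuilds
   the affected region's priors directly: the special type's prior is set
   to 1 and every other present type's prior to `1/f_t` (dominant) or
   `f_t` (rare) with `f_t ~ Uniform[5, 15]` — drawn per other type under
   *diverse*, once per region under *uniform* — then the row is
   renormalised. This construction, rather than multiplying one entry of
   an existing prior vector, guarantees that *every* realized pairwise
   ratio lies inside the configured interval, which a single
   multiplicative bump cannot do when base priors are unequal. For
   `*_one_region` specials one region is chosen at random and the special
   type keeps its ordinary priors elsewhere; if an affected region holds
   fewer than two present types, one extra type is added so the ratio is
   defined.
3. **Spot composition.** `n ~ Uniform{cells_min..cells_max}` (default
   {2..10}); each of the `n` cells is drawn by sampling its type from the
   region priors and then a cell of that type uniformly *with
   replacement* (avoids exhausting small types and makes the truth
   exactly multinomial). Counts are summed gene-wise; the truth is the
   exact sampled fraction per type.
4. **Downsampling.** The per-spot target is
   `round(max(0, Normal(visium_mean, visium_sd)))` (default
   20000 ± 5000). If the pooled total exceeds the target, transcripts are
   subsampled without replacement (multivariate hypergeometric over
   genes); totals at or below the target pass through unchanged — counts
   are never inflated.

Priors are drawn once per dataset (not per spot), so spots within a
region have similar compositions; spots carry region labels but no
spatial coordinates, since the simulator models composition, not
geometry. Seeding uses one root seed with child generators spawned per
region, so replicates are bit-reproducible.

The nine benchmark abundance patterns are kept in `PATTERN_REGISTRY`, an
ordinary dict that callers may extend: the four
uniformity × sharing combinations, dominant and rare specials on the
diverse+overlap base (each in all-regions and one-region form), and a
ninth default — a dominant special on the uniform+overlap base — chosen
because the characteristic system in this package expresses
dominance/rarity and not reference-types-missing-from-spots scenarios.
The standard benchmark grid pairs the nine patterns with seven reference
datasets (63 configurations).

## Gold-standard pooling

Circles of Visium spot diameter (55 µm default) are tiled on a zero-gap
square grid, independently per field of view; with pitch equal to the
diameter the circles are inscribed in the grid squares, so membership is
computed by grid-cell index plus a distance test and no cell can fall in
two circles. Membership is by centroid with a closed boundary
(distance ≤ radius); ties are measure-zero. The grid is anchored at the
per-FOV centroid bounding-box minimum (plus a configurable offset), and
the number of circles per axis is `floor(span/diameter)` — a 206 µm
square field holds 3 × 3 = 9 pseudo-spots — with at least one circle
whenever the FOV contains cells. `um_per_pixel` converts pixel
coordinates (e.g. 103 nm or 810 nm pixels) to µm. Spot counts are the
gene-wise sum over member cells and the truth is the member label
frequencies; spots with fewer than `min_cells_per_spot` cells are
dropped, and a label blocklist can remove cell populations before
pooling. Cells in the gaps between circles are deliberately ignored
(transcript conservation is an inequality).

## Baselines

- **NNLS**: per spot, the Lawson–Hanson solver (scipy) minimises
  `‖Y − Xβ‖₂` with `β ≥ 0`, where `X` holds raw-count mean expression per
  cell type (a CPM flag is available but off by default, since raw means
  are the convention the signature definition implies); proportions are
  `β/Σβ`. Genes are aligned by name intersection between spots and
  signature — requiring identical gene sets would make cross-reference
  stability runs impossible. An all-zero solution (e.g. an empty spot)
  falls back to the uniform vector with a warning.
- **Dirichlet null**: `n_iterations` (default 100) independent matrices
  whose rows are symmetric Dirichlet(α=1) draws over the Z cell types.
  Averaging is done at the *metric* level — each metric is computed per
  iteration and the 100 values averaged — not by averaging the random
  proportions themselves, which would converge to the uniform vector and
  understate the null's error.

## Metrics

RMSE divides by the number of cell types Z inside the square root, so it
is reported together with Z and never compared across datasets with
different Z. JSD uses base-2 logarithms (maximum exactly 1) with
`0·log(0/·) := 0`; coordinates where both vectors are zero contribute
nothing. AUPR binarises the truth at exactly zero and uses the step-wise
(no linear interpolation) precision–recall area as computed by
scikit-learn's `average_precision_score`, pooling all spot × type pairs
for the micro average or one type's column for the per-type variant used
in rare-type evaluation; tied scores collapse into a single threshold.
Degenerate label vectors (all present or all absent) raise an error
rather than returning an arbitrary value. Columns are always aligned by
cell-type name, with an explicit error on set mismatch — silent
subsetting hides prediction/truth mismatches.

`sample_level_jsd` implements case-study-style evaluation: each dataset
is collapsed to its renormalised mean composition and the JSD of every
cross pair is averaged; running one group against itself and averaging
off-diagonal entries gives the biological-variation reference.
`stability_jsd` is the per-spot JSD between two predictions of the same
spots obtained from different references.

## Aggregation

Replicates collapse to a representative value (median over replicates
for silver standards; mean over FOVs for gold-style data; mean for
rare-type AUPR). Within a grouping (abundance pattern, data source, or
metric), each metric's grand mean across datasets is min-max scaled
*across methods* — the only direction that makes scores comparable
between methods — and error metrics (RMSE, JSD) are inverted
(`1 − scaled`) so 1 is uniformly best before the geometric mean;
without the inversion the geometric mean would mix polarities. A floor of
1e-6 keeps a single zero from annihilating the geometric mean (flagged
with a warning); zero spread in a metric scores every method 1, also
flagged, instead of dividing by zero. Final rankings are weighted rank
sums (1 = best, average ranks on ties, weight 0.5 per abundance-pattern
criterion and 1.0 otherwise by convention), with ties in the total broken
lexicographically by method name for determinism. Externally measured
criteria (e.g. runtime of third-party tools, which this package does not
time) can be supplied as additional score columns.

## Fixture generator

The fixture model is gamma–Poisson (negative binomial): per gene and
cell, a rate is drawn from `Gamma(1/dispersion, mean·dispersion)` and
counts from Poisson of that rate, with each cell type's
`n_markers_per_type` disjoint marker genes inflated by
`marker_fold_change` (default 8). Defaults (5 types × 100 cells, 200
genes, base mean 2, dispersion 0.5) give clearly separable types at
desk scale. The generator emulates overdispersed counts with marker
structure and balanced type sizes; it does **not** emulate batch
effects, doublets, ambient RNA, library-size heterogeneity between
types, or realistic marker sparsity. Tests passing on fixtures therefore
demonstrate correctness of the benchmarking machinery, not how real
deconvolution methods will rank on real tissue. Reference curation
(blocklist for ambiguous labels, <25-cell types removed, genes kept iff
expressed in ≥10% — boundary inclusive — of cells of some surviving
type) and the stratified half/half split (the larger half of an
odd-sized type goes to the generation side) run before simulation.

## Problem sizes

The test suite and examples run scaled-down configurations (tens of
spots per region, target counts in the hundreds to low thousands, 20–50
null iterations) chosen so the full suite completes in seconds while
every code path — including the full-default region layout, the
20000-count downsampling check on a deep fixture, and 10,000-spot cell
count bounds — is exercised at the stated sizes. The simulator defaults
themselves are always the full-scale protocol values.

## Known limitations

- The abundance-pattern system covers dominance/rarity specials only;
  scenarios where reference types are absent from the tissue must be
  emulated by subsetting the reference.
- `distinct` requires at least as many cell types as regions.
- Pooling infers FOV extent from the centroid bounding box; a FOV whose
  cells do not span its physical extent yields fewer circles than the
  physical field would.
- NNLS inherits scipy's active-set behaviour on rank-deficient
  signatures; exactly collinear cell types may split weight arbitrarily.
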