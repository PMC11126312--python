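"""Build gold-standard pseudo-spots from a segmented imaging fixture.

Cells with known labels and centroids are pooled inside zero-gap circles
of Visium spot diameter (55 um); a 206 x 206 um field of view holds a
3 x 3 grid of such circles, i.e. nine pseudo-spots.
"""
import spotbench as sb

imaging = sb.generate_imaging_fixture(
    sb.FixtureConfig(n_cell_types=4, n_cells_per_type=250, n_genes=100,
                     n_markers_per_type=5, base_mean=5.0, seed=1),
    fov_width_um=206.0, fov_height_um=206.0, n_cells=1000, n_fovs=2, seed=2,
)
pooled = sb.pool_to_spots(imaging, sb.PoolingConfig(spot_diameter_um=55.0))

print(f"cells in: {imaging.n_cells}  (2 FOVs of 206 x 206 um)")
print(f"pseudo-spots out: {pooled.n_spots}  "
      f"({pooled.spot_centres.groupby('fov_id').size().to_dict()})")
print(f"cells per pseudo-spot: {pooled.n_cells.min()}..{pooled.n_cells.max()}")
print(f"transcripts kept: {pooled.counts.sum()} of {imaging.counts.sum()}")
print("first spot truth:", dict(zip(pooled.truth.cell_type_ids,
                                    pooled.truth.values[0].round(3))))
# Counts drop because only cells whose centroid falls inside a circle are
# pooled; the truth row is the member cells' label frequencies.
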