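"""Simulate a silver-standard replicate with a regional rare cell type.

Builds a fixture single-cell reference, applies the standard curation
(minimum 25 cells per type, genes expressed in >= 10% of cells of some
type), splits it in half stratified by type, and generates one synthetic
replicate under the `regional_rare_celltype_diverse` abundance pattern.
"""
import numpy as np

import spotbench as sb

ref = sb.generate_reference(sb.FixtureConfig(
    n_cell_types=6, n_cells_per_type=80, n_genes=300,
    n_markers_per_type=10, base_mean=60.0, seed=0,
))
ref = sb.filter_reference(ref, min_cells_per_type=25, min_expr_fraction=0.10)
generation_half, deconv_half = sb.split_reference(ref, seed=0)

cfg = sb.SimConfig(seed=0)  # 5 regions, 100-200 spots each, 20000+-5000 counts
ds = sb.generate_synthetic_visium(generation_half, "regional_rare_celltype_diverse", cfg)

print(f"spots: {ds.n_spots}  (regions: {len(set(ds.region_label.tolist()))})")
print(f"cells pooled per spot: {ds.n_cells.min()}..{ds.n_cells.max()}")
print(f"mean counts per spot: {ds.counts.sum(axis=1).mean():.0f}")
print(f"rare cell type: {ds.config['special_cell_type']} "
      f"(region {ds.config['region_of_special']})")
rare = ds.config["special_cell_type"]
col = list(ds.truth.cell_type_ids).index(rare)
in_region = ds.region_label == ds.config["region_of_special"]
region_truth = ds.truth.values[in_region]
others = [z for z in range(region_truth.shape[1])
          if z != col and region_truth[:, z].sum() > 0]
print(f"rare-type mean proportion inside its region:        "
      f"{region_truth[:, col].mean():.4f}")
print(f"mean proportion of the other types present there:   "
      f"{region_truth[:, others].mean():.4f}")
# The rare type is sampled 5-15x less often than each other type present
# in its region, so its mean proportion sits well below theirs.
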