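import numpy as np
import pytest

import spotbench as sb


@pytest.fixture(scope="session")
def small_ref() -> sb.AnnotatedReference:
    """Filtered fixture reference: 5 types x 60 cells, 120 genes."""
    ref = sb.generate_reference(
        sb.FixtureConfig(
            n_cell_types=5, n_cells_per_type=60, n_genes=120,
            n_markers_per_type=8, marker_fold_change=8.0,
            base_mean=2.0, dispersion=0.4, seed=11,
        )
    )
    return sb.filter_reference(ref, min_cells_per_type=25, min_expr_fraction=0.10)


@pytest.fixture(scope="session")
def split_halves(small_ref):
    return sb.split_reference(small_ref, seed=7)


@pytest.fixture(scope="session")
def tiny_sim_config() -> sb.SimConfig:
    """Scaled-down simulator settings for fast tests."""
    return sb.SimConfig(
        n_regions=3, n_spots_min=8, n_spots_max=15,
        visium_mean=1000.0, visium_sd=200.0, seed=5,
    )


def make_proportions(values, cell_types=None, spot_ids=None) -> sb.ProportionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, z = values.shape
    if cell_types is None:
        cell_types = [f"t{i}" for i in range(z)]
    if spot_ids is None:
        spot_ids = [f"s{i}" for i in range(n)]
    return sb.ProportionMatrix(values=values, spot_ids=spot_ids, cell_type_ids=cell_types)
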