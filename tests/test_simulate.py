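"""Spot simulator: layouts, frequency priors, spot composition, downsampling."""
import numpy as np
import pytest

import spotbench as sb


RNG = lambda s=0: np.random.default_rng(s)  # noqa: E731


class TestRegionLayout:
    def test_degenerate_interval(self):
        cfg = sb.SimConfig(n_regions=5, n_spots_min=150, n_spots_max=150)
        sizes = sb.build_region_layout(cfg, RNG())
        assert sizes.tolist() == [150] * 5
        assert sizes.sum() == 750

    def test_sizes_within_bounds(self):
        cfg = sb.SimConfig()
        rng = RNG(1)
        for _ in range(50):
            sizes = sb.build_region_layout(cfg, rng)
            assert sizes.min() >= 100 and sizes.max() <= 200


class TestFrequencyPriors:
    def test_uniform_distinct_partitions_evenly(self):
        cfg = sb.SimConfig(n_regions=3)
        fp = sb.build_frequency_priors(
            sb.AbundancePattern("uniform", "distinct"), [f"t{i}" for i in range(6)], cfg, RNG(2)
        )
        for row in fp.priors:
            nz = row[row > 0]
            assert len(nz) == 2
            assert np.allclose(nz, 0.5)

    def test_distinct_supports_partition_cell_types(self):
        cfg = sb.SimConfig(n_regions=4)
        for seed in range(10):
            fp = sb.build_frequency_priors(
                sb.AbundancePattern("diverse", "distinct"), [f"t{i}" for i in range(9)],
                cfg, RNG(seed),
            )
            support_regions = (fp.priors > 0).sum(axis=0)
            assert np.all(support_regions == 1)  # each type in exactly one region

    def test_distinct_more_regions_than_types_errors(self):
        cfg = sb.SimConfig(n_regions=5)
        with pytest.raises(ValueError, match="distinct"):
            sb.build_frequency_priors(
                sb.AbundancePattern("uniform", "distinct"), ["a", "b"], cfg, RNG()
            )

    def test_rows_sum_to_one(self):
        cfg = sb.SimConfig()
        for name, pattern in sb.PATTERN_REGISTRY.items():
            fp = sb.build_frequency_priors(pattern, [f"t{i}" for i in range(7)], cfg, RNG(3))
            assert np.allclose(fp.priors.sum(axis=1), 1.0, atol=1e-9), name

    def test_dominant_all_regions_ratios_in_range(self):
        cfg = sb.SimConfig()
        for seed in range(20):
            fp = sb.build_frequency_priors(
                sb.PATTERN_REGISTRY["dominant_celltype_diverse"],
                [f"t{i}" for i in range(8)], cfg, RNG(seed),
            )
            z = fp.cell_types.tolist().index(fp.special_cell_type)
            for row in fp.priors:
                others = np.delete(row, z)
                others = others[others > 0]
                ratios = row[z] / others
                assert np.all((ratios >= 5.0 - 1e-9) & (ratios <= 15.0 + 1e-9))

    def test_rare_one_region_ratios_and_scope(self):
        cfg = sb.SimConfig()
        fp = sb.build_frequency_priors(
            sb.PATTERN_REGISTRY["regional_rare_celltype_diverse"],
            [f"t{i}" for i in range(8)], cfg, RNG(4),
        )
        assert fp.region_of_special is not None
        z = fp.cell_types.tolist().index(fp.special_cell_type)
        row = fp.priors[fp.region_of_special]
        others = np.delete(row, z)
        others = others[others > 0]
        ratios = others / row[z]
        assert np.all((ratios >= 5.0 - 1e-9) & (ratios <= 15.0 + 1e-9))

    def test_diverse_priors_unequal(self):
        cfg = sb.SimConfig(n_regions=2)
        fp = sb.build_frequency_priors(
            sb.AbundancePattern("diverse", "overlap"), [f"t{i}" for i in range(6)], cfg, RNG(5)
        )
        for row in fp.priors:
            nz = row[row > 0]
            if len(nz) > 1:
                assert nz.std() > 0

    def test_nine_patterns_registered(self):
        assert len(sb.PATTERN_REGISTRY) == 9
        assert len(sb.DEFAULT_PATTERNS) == 9


class TestComposeSpot:
    def test_concentrated_priors_give_indicator_truth(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        priors = np.zeros(len(gen.cell_types))
        priors[2] = 1.0
        _, truth, n = sb.compose_spot(gen, priors, tiny_sim_config, RNG(0))
        assert truth[2] == 1.0 and truth.sum() == 1.0

    def test_truth_is_probability_with_bounded_support(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        priors = np.full(len(gen.cell_types), 1 / len(gen.cell_types))
        rng = RNG(1)
        for _ in range(20):
            _, truth, n = sb.compose_spot(gen, priors, tiny_sim_config, rng)
            assert truth.sum() == pytest.approx(1.0)
            assert np.count_nonzero(truth) <= n
            assert tiny_sim_config.cells_min <= n <= tiny_sim_config.cells_max

    def test_empty_type_with_prior_errors(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        # a reference lacking one type cannot serve priors defined over all types
        sub = gen.subset_cells(np.flatnonzero(gen.cell_type != gen.cell_types[0]))
        with pytest.raises(ValueError):
            sb.compose_spot(sub, np.ones(len(gen.cell_types)) / len(gen.cell_types),
                            tiny_sim_config, RNG(0))
        # and a nonzero prior whose group has no cells is rejected explicitly
        groups = {t: gen.type_indices()[t] for t in gen.cell_types}
        groups[gen.cell_types[0]] = np.array([], dtype=int)
        with pytest.raises(ValueError, match="no cells"):
            sb.compose_spot(gen, np.ones(len(gen.cell_types)) / len(gen.cell_types),
                            tiny_sim_config, RNG(0), _groups=groups)

    def test_mean_truth_matches_multinomial_oracle(self, split_halves):
        """Law of large numbers: mean truth converges to the priors.

        The oracle draws type counts directly from the multinomial model
        (type-first sampling marginalises to multinomial over types)."""
        gen, _ = split_halves
        Z = len(gen.cell_types)
        priors = np.full(Z, 1 / Z)
        cfg = sb.SimConfig(n_regions=1, visium_mean=1e9, visium_sd=0, seed=0)
        rng = RNG(7)
        n_spots = 3000
        means = np.zeros(Z)
        for _ in range(n_spots):
            _, truth, _ = sb.compose_spot(gen, priors, cfg, rng)
            means += truth
        means /= n_spots

        oracle_rng = RNG(8)
        oracle = np.zeros(Z)
        for _ in range(n_spots):
            n = int(oracle_rng.integers(cfg.cells_min, cfg.cells_max + 1))
            oracle += oracle_rng.multinomial(n, priors) / n
        oracle /= n_spots
        assert np.allclose(means, priors, atol=0.02)
        assert np.allclose(oracle, priors, atol=0.02)
        assert np.allclose(means, oracle, atol=0.03)


class TestDownsample:
    def test_no_upsampling(self):
        counts = np.array([100, 200, 300])
        out = sb.downsample_counts(counts, 20000, RNG(0))
        assert np.array_equal(out, counts)

    def test_exact_total_and_per_gene_bound(self):
        rng = RNG(1)
        counts = rng.integers(0, 500, size=200)
        out = sb.downsample_counts(counts, 20000, rng)
        assert out.sum() == min(20000, counts.sum())
        assert np.all(out <= counts)

    def test_negative_target_errors(self):
        with pytest.raises(ValueError):
            sb.downsample_counts(np.array([1, 2]), -1, RNG(0))

    def test_expectation_matches_binomial_thinning_oracle(self):
        """Hypergeometric mean identity: E[out_g] = in_g * target/total."""
        counts = np.array([300, 200, 100, 0, 400])
        target = 500
        total = counts.sum()
        rng = RNG(2)
        reps = 1000
        acc = np.zeros(len(counts))
        for _ in range(reps):
            acc += sb.downsample_counts(counts, target, rng)
        mean = acc / reps

        oracle_rng = RNG(3)
        oracle = np.zeros(len(counts))
        for _ in range(reps):
            oracle += oracle_rng.binomial(counts, target / total)
        oracle /= reps
        expected = counts * target / total
        assert np.allclose(mean, expected, atol=3.0)
        assert np.allclose(oracle, expected, atol=3.0)


class TestGenerateSyntheticVisium:
    def test_same_seed_identical(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        a = sb.generate_synthetic_visium(gen, "diverse_overlap", tiny_sim_config)
        b = sb.generate_synthetic_visium(gen, "diverse_overlap", tiny_sim_config)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.truth.values, b.truth.values)
        assert np.array_equal(a.region_label, b.region_label)

    def test_truth_conservation_exact_rationals(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        ds = sb.generate_synthetic_visium(gen, "uniform_overlap", tiny_sim_config)
        # truth * n must recover integer sampled-cell counts exactly
        scaled = ds.truth.values * ds.n_cells[:, None]
        assert np.allclose(scaled, np.round(scaled), atol=1e-12)
        assert np.allclose(ds.truth.values.sum(axis=1), 1.0)

    def test_n_cells_within_bounds_and_config_echo(self, split_halves, tiny_sim_config):
        gen, _ = split_halves
        ds = sb.generate_synthetic_visium(gen, "diverse_distinct", tiny_sim_config)
        assert ds.n_cells.min() >= tiny_sim_config.cells_min
        assert ds.n_cells.max() <= tiny_sim_config.cells_max
        assert ds.config["pattern_region_sharing"] == "distinct"

    def test_empirical_truth_recovers_region_priors(self, split_halves):
        """Average truth per region approaches the region's prior vector."""
        gen, _ = split_halves
        cfg = sb.SimConfig(n_regions=2, n_spots_min=400, n_spots_max=400,
                           visium_mean=1e9, visium_sd=0, seed=13)
        ds = sb.generate_synthetic_visium(gen, "diverse_overlap", cfg)
        root = np.random.default_rng(cfg.seed)
        sb.build_region_layout(cfg, root)
        fp = sb.build_frequency_priors(
            sb.PATTERN_REGISTRY["diverse_overlap"], gen.cell_types, cfg, root
        )
        for r in range(cfg.n_regions):
            emp = ds.truth.values[ds.region_label == r].mean(axis=0)
            assert np.allclose(emp, fp.priors[r], atol=4 / np.sqrt(400))
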