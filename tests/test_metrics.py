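"""Metric suite: RMSE, JSD, AUPR (micro and per type), case-study JSDs."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import average_precision_score

import spotbench as sb

from conftest import make_proportions


def brute_force_aupr(labels, scores):
    """Threshold-enumeration PR area with step-wise interpolation."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


@st.composite
def probability_vector(draw, n=4):
    raw = draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n))
    v = np.asarray(raw)
    return v / v.sum()


class TestRMSE:
    def test_exact_values(self):
        cases = [
            ([1, 0, 0, 0], [1, 0, 0, 0], 0.0),
            ([1, 0, 0, 0], [0, 1, 0, 0], np.sqrt(2 / 4)),
            ([0.6, 0.4], [0.5, 0.5], 0.1),
        ]
        for known, pred, expected in cases:
            _, value = sb.rmse(make_proportions(known), make_proportions(pred))
            assert value == pytest.approx(expected, abs=1e-12)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        k = rng.dirichlet(np.ones(5), size=10)
        p = rng.dirichlet(np.ones(5), size=10)
        perm = rng.permutation(5)
        base = sb.rmse(make_proportions(k), make_proportions(p))[1]
        names = [f"t{i}" for i in range(5)]
        permuted = sb.rmse(
            make_proportions(k[:, perm], cell_types=[names[i] for i in perm]),
            make_proportions(p[:, perm], cell_types=[names[i] for i in perm]),
        )[1]
        assert base == pytest.approx(permuted, abs=1e-12)

    def test_mismatched_cell_types_error(self):
        with pytest.raises(ValueError, match="cell-type sets differ"):
            sb.rmse(make_proportions([1.0, 0.0], cell_types=["a", "b"]),
                    make_proportions([1.0, 0.0], cell_types=["a", "c"]))

    def test_spots_aligned_by_id(self):
        k = make_proportions([[1, 0], [0, 1]], spot_ids=["s1", "s2"])
        p = make_proportions([[0, 1], [1, 0]], spot_ids=["s2", "s1"])
        assert sb.rmse(k, p)[1] == pytest.approx(0.0)


class TestJSD:
    def test_exact_values(self):
        assert sb.jsd(make_proportions([0.5, 0.5]), make_proportions([0.5, 0.5]))[1] == 0.0
        assert sb.jsd(make_proportions([1, 0]), make_proportions([0, 1]))[1] == pytest.approx(1.0)
        value = sb.jsd(make_proportions([0.5, 0.5]), make_proportions([1.0, 0.0]))[1]
        assert value == pytest.approx(0.31128, abs=1e-5)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(6), size=20)
        q = rng.dirichlet(np.ones(6), size=20)
        mine = sb.jsd_vectors(p, q)
        oracle = np.array([jensenshannon(a, b, base=2) ** 2 for a, b in zip(p, q)])
        assert np.allclose(mine, oracle, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(probability_vector(), probability_vector())
    def test_symmetry_and_bounds(self, p, q):
        ab = sb.jsd_vectors(p, q)[0]
        ba = sb.jsd_vectors(q, p)[0]
        assert ab == pytest.approx(ba, abs=1e-12)
        assert -1e-12 <= ab <= 1.0 + 1e-12

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sb.jsd_vectors(np.array([0.4, 0.4]), np.array([0.5, 0.5]))


class TestMicroAUPR:
    def test_perfect_ranking_is_one(self):
        k = make_proportions([[0.5, 0.5, 0.0], [0.0, 0.6, 0.4]])
        p = make_proportions([[0.45, 0.55, 0.0], [0.0, 0.5, 0.5]])
        assert sb.micro_aupr(k, p) == pytest.approx(1.0)

    def test_two_point_curve(self):
        # the 2-point curve: a single positive ranked below a negative gives
        # AUPR 0.5 by threshold enumeration
        k = make_proportions([[0.5, 0.0, 0.5]])
        p = make_proportions([[0.2, 0.8, 0.0]])
        # pooled labels (1,0,1), scores (.2,.8,0): check against enumeration
        labels = np.array([1, 0, 1], bool)
        scores = np.array([0.2, 0.8, 0.0])
        assert sb.micro_aupr(k, p) == pytest.approx(brute_force_aupr(labels, scores))
        assert brute_force_aupr([1, 0], [0.2, 0.9]) == pytest.approx(0.5)
        assert average_precision_score([1, 0], [0.2, 0.9]) == pytest.approx(0.5)

    def test_equals_enumeration_oracle_on_small_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n_spots = int(rng.integers(2, 11))
            z = int(rng.integers(2, 6))  # up to 50 pooled pairs
            k = rng.dirichlet(np.ones(z), n_spots)
            k[rng.random(k.shape) < 0.4] = 0
            k = k[k.sum(axis=1) > 0]
            k = k / k.sum(axis=1, keepdims=True)
            if not k.size:
                continue
            labels = (k > 0).ravel()
            if labels.all() or not labels.any():
                continue
            p = rng.dirichlet(np.ones(z), k.shape[0])
            got = sb.micro_aupr(make_proportions(k), make_proportions(p))
            assert got == pytest.approx(brute_force_aupr(labels, p.ravel()), abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        n, z = 500, 4
        k = rng.dirichlet(np.ones(z), n)
        k[rng.random(k.shape) < 0.7] = 0
        keep = k.sum(axis=1) > 0
        k = k[keep] / k[keep].sum(axis=1, keepdims=True)
        p = rng.dirichlet(np.ones(z), k.shape[0])
        prevalence = (k > 0).mean()
        assert sb.micro_aupr(make_proportions(k), make_proportions(p)) == pytest.approx(
            prevalence, abs=0.05
        )

    def test_degenerate_labels_error(self):
        k = make_proportions([[0.5, 0.5]])
        p = make_proportions([[0.4, 0.6]])
        with pytest.raises(ValueError, match="all positive"):
            sb.micro_aupr(k, p)


class TestCelltypeAUPR:
    def test_perfect_detection(self):
        k = make_proportions([[0.9, 0.1], [1.0, 0.0], [0.8, 0.2]])
        p = make_proportions([[0.9, 0.1], [1.0, 0.0], [0.7, 0.3]])
        assert sb.celltype_aupr(k, p, "t1") == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        k = make_proportions([[1, 0], [0.5, 0.5], [0.5, 0.5], [1, 0]])
        p = make_proportions([[0.8, 0.2]] * 4)
        assert sb.celltype_aupr(k, p, "t1") == pytest.approx(0.5)

    def test_hand_enumerated_six_spot_toy(self):
        present = np.array([1, 0, 1, 0, 0, 1], bool)
        score = np.array([0.9, 0.8, 0.3, 0.2, 0.6, 0.1])
        k = np.column_stack([np.where(present, 0.5, 1.0), np.where(present, 0.5, 0.0)])
        p = np.column_stack([1 - score, score])
        got = sb.celltype_aupr(make_proportions(k), make_proportions(p), "t1")
        assert got == pytest.approx(brute_force_aupr(present, score), abs=1e-12)

    def test_no_positives_error(self):
        k = make_proportions([[1.0, 0.0]])
        p = make_proportions([[0.5, 0.5]])
        with pytest.raises(ValueError, match="present in no spot"):
            sb.celltype_aupr(k, p, "t1")


class TestSampleLevelJSD:
    def test_identical_groups_zero(self):
        m = make_proportions([[0.5, 0.5], [0.3, 0.7]])
        pairwise, mean = sb.sample_level_jsd([m], [m])
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_reduces_to_plain_jsd(self):
        a = make_proportions([[0.6, 0.4]])
        b = make_proportions([[0.1, 0.9]])
        _, mean = sb.sample_level_jsd([a], [b])
        expected = sb.jsd_vectors(np.array([0.6, 0.4]), np.array([0.1, 0.9]))[0]
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_two_by_two_toy_matches_direct_evaluation(self):
        preds = [make_proportions([[0.6, 0.4]]), make_proportions([[0.2, 0.8]])]
        refs = [make_proportions([[0.5, 0.5]]), make_proportions([[0.9, 0.1]])]
        pairwise, mean = sb.sample_level_jsd(preds, refs)
        vecs_p = [np.array([0.6, 0.4]), np.array([0.2, 0.8])]
        vecs_r = [np.array([0.5, 0.5]), np.array([0.9, 0.1])]
        expected = np.array(
            [[jensenshannon(a, b, base=2) ** 2 for b in vecs_r] for a in vecs_p]
        )
        assert np.allclose(pairwise, expected, atol=1e-12)
        assert mean == pytest.approx(expected.mean(), abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            sb.sample_level_jsd([], [make_proportions([[1.0, 0.0]])])


class TestStabilityJSD:
    def test_identical_and_symmetric(self):
        rng = np.random.default_rng(5)
        a = make_proportions(rng.dirichlet(np.ones(4), 8))
        b = make_proportions(rng.dirichlet(np.ones(4), 8))
        assert sb.stability_jsd(a, a)[1] == pytest.approx(0.0, abs=1e-12)
        assert sb.stability_jsd(a, b)[1] == pytest.approx(sb.stability_jsd(b, a)[1], abs=1e-12)

    def test_equals_spotwise_jsd(self):
        a = make_proportions([[0.5, 0.5], [1.0, 0.0]])
        b = make_proportions([[0.4, 0.6], [0.9, 0.1]])
        per_spot, mean = sb.stability_jsd(a, b)
        expected = sb.jsd(a, b)
        assert np.allclose(per_spot, expected[0])


def test_metric_report_perfect_prediction():
    rng = np.random.default_rng(6)
    truth = rng.dirichlet(np.ones(4), 12)
    truth[rng.random(truth.shape) < 0.3] = 0
    truth = truth / truth.sum(axis=1, keepdims=True)
    m = make_proportions(truth)
    report = sb.metric_report(m, m)
    assert report.rmse == 0.0
    assert report.jsd == pytest.approx(0.0, abs=1e-12)
    assert report.aupr == pytest.approx(1.0)
    assert (report.n_spots, report.n_cell_types) == (12, 4)
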