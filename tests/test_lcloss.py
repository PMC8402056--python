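import numpy as np
import pytest

from earcount import lcloss as lc

from .oracles import watershed_ridge_oracle


def uniform_map(shape, p_ear):
    s = np.empty(shape + (2,))
    s[..., 1] = p_ear
    s[..., 0] = 1.0 - p_ear
    return s


def perfect_map(shape, ear_pixels):
    """Background everywhere except probability-1 ear at the given pixels."""
    s = np.zeros(shape + (2,))
    s[..., 0] = 1.0
    for r, c in ear_pixels:
        s[r, c] = [0.0, 1.0]
    return s


class TestImageLevel:
    def test_zero_when_both_classes_confident_somewhere(self):
        s = perfect_map((3, 3), [(1, 1)])
        assert lc.image_level_loss(s, [(1, 1)]) == 0.0

    def test_zero_for_empty_image_predicted_empty(self):
        s = uniform_map((3, 3), 0.0)
        assert lc.image_level_loss(s, []) == 0.0

    def test_hand_derived_two_by_two(self):
        s = uniform_map((2, 2), 0.5)
        s[0, 0] = [0.9, 0.1]
        s[1, 1] = [0.2, 0.8]
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert lc.image_level_loss(s, [(0, 1)]) == pytest.approx(expected, abs=1e-12)

    def test_penalizes_ear_when_image_empty(self):
        s = uniform_map((2, 2), 0.3)
        expected = -np.log(0.7) - np.log(1 - 0.3)
        assert lc.image_level_loss(s, []) == pytest.approx(expected, abs=1e-12)


class TestPointLevel:
    def test_zero_at_confident_points(self):
        s = perfect_map((4, 4), [(2, 2), (0, 3)])
        assert lc.point_level_loss(s, [(2, 2), (0, 3)]) == 0.0

    def test_single_half_probability_point(self):
        s = uniform_map((3, 3), 0.5)
        assert lc.point_level_loss(s, [(1, 1)]) == pytest.approx(np.log(2))

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, size=(6, 6))
        s = np.stack([1 - p, p], axis=2)
        points = [(0, 0), (2, 3), (5, 5), (1, 4), (4, 1)]
        expected = sum(-np.log(p[r, c]) for r, c in points)
        assert lc.point_level_loss(s, points) == pytest.approx(expected, rel=1e-12)


class TestWatershed:
    def test_single_point_blobs_contribute_nothing(self):
        s = uniform_map((5, 5), 0.9)
        assert not lc.watershed_boundaries(s, [(2, 2)]).any()

    def test_symmetric_rectangle_splits_at_middle_column(self):
        s = uniform_map((3, 9), 0.8)
        e = lc.watershed_boundaries(s, [(1, 1), (1, 7)])
        rows, cols = np.nonzero(e)
        assert set(cols) == {4} and set(rows) == {0, 1, 2}

    def test_dumbbell_ridge_confined_to_neck(self):
        blob = np.zeros((3, 7), dtype=bool)
        blob[:, :3] = True
        blob[:, 4:] = True
        blob[1, 3] = True
        s = np.zeros((3, 7, 2))
        s[..., 0] = 1.0
        s[blob] = [0.2, 0.8]
        e = lc.watershed_boundaries(s, [(1, 1), (1, 5)])
        assert list(zip(*np.nonzero(e))) == [(1, 3)]

    def test_seed_pixels_never_in_ridge(self):
        s = uniform_map((2, 3), 0.9)
        e = lc.watershed_boundaries(s, [(0, 1), (1, 1)])
        assert not e[0, 1] and not e[1, 1]

    def test_matches_flood_oracle_on_random_small_blobs(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            p = np.where(
                rng.random((5, 5)) < 0.7, rng.uniform(0.55, 0.95, size=(5, 5)), 0.1
            )
            fg = p > 0.5
            if fg.sum() < 2:
                continue
            cells = list(zip(*np.nonzero(fg)))
            seeds = [cells[i] for i in rng.choice(len(cells), 2, replace=False)]
            s = np.stack([1 - p, p], axis=2)
            e = lc.watershed_boundaries(s, seeds)
            assert np.array_equal(e, watershed_ridge_oracle(p, seeds))


class TestSplitAndFalsePositive:
    def test_empty_ridge_gives_zero(self):
        s = uniform_map((4, 4), 0.9)
        labeling = lc.compute_blobs(s, [(1, 1)])
        assert lc.split_loss(s, np.zeros((4, 4), bool), labeling) == 0.0

    def test_confident_background_ridge_gives_zero(self):
        s = perfect_map((3, 3), [(0, 0), (2, 2)])
        labeling = lc.compute_blobs(s, [(0, 0), (2, 2)])
        e = np.zeros((3, 3), bool)
        e[1, 1] = True
        assert lc.split_loss(s, e, labeling) == 0.0

    def test_hand_derived_split_value(self):
        s = uniform_map((3, 9), 0.8)
        labeling = lc.compute_blobs(s, [(1, 1), (1, 7)])
        e = lc.watershed_boundaries(s, [(1, 1), (1, 7)], labeling=labeling)
        s_half = uniform_map((3, 9), 0.5)
        # 3 ridge pixels, alpha = 2 points, -log(0.5) each
        assert lc.split_loss(s_half, e, labeling) == pytest.approx(6 * np.log(2))

    def test_printed_variant_is_mean_background_probability(self):
        s = uniform_map((3, 9), 0.8)
        labeling = lc.compute_blobs(s, [(1, 1), (1, 7)])
        e = lc.watershed_boundaries(s, [(1, 1), (1, 7)], labeling=labeling)
        assert lc.split_loss(s, e, labeling, printed_variant=True) == pytest.approx(0.2)

    def test_no_pointless_blobs_gives_zero(self):
        s = perfect_map((4, 4), [(1, 1)])
        labeling = lc.compute_blobs(s, [(1, 1)])
        assert lc.false_positive_loss(s, labeling) == 0.0

    def test_four_pixel_pointless_blob(self):
        s = np.zeros((4, 4, 2))
        s[..., 0] = 1.0
        s[0:2, 0:2, 0] = np.exp(-1)
        s[0:2, 0:2, 1] = 1 - np.exp(-1)
        labeling = lc.compute_blobs(s, [])
        assert lc.false_positive_loss(s, labeling) == pytest.approx(4.0)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.05, 0.95, size=(8, 8))
        s = np.stack([1 - p, p], axis=2)
        points = [(1, 1)]
        labeling = lc.compute_blobs(s, points)
        fp = [lab for lab, n in labeling.points_per_blob.items() if n == 0]
        expected = sum(
            -np.log(s[r, c, 0])
            for r in range(8)
            for c in range(8)
            if labeling.labels[r, c] in fp
        )
        assert lc.false_positive_loss(s, labeling) == pytest.approx(expected)


class TestTotalLoss:
    def test_perfect_prediction_is_exactly_zero(self):
        s = perfect_map((6, 6), [(1, 1), (4, 4)])
        b = lc.lc_loss(s, [(1, 1), (4, 4)])
        assert (b.image_level, b.point_level, b.split, b.false_positive) == (0, 0, 0, 0)

    def test_total_is_sum_of_terms_on_uniform_fixture(self):
        s = uniform_map((4, 4), 0.5)
        points = [(1, 1), (2, 2)]
        b = lc.lc_loss(s, points)
        assert b.total == pytest.approx(
            b.image_level + b.point_level + b.split + b.false_positive
        )
        # everything is one 16-px blob at p=0.5... ties go to background:
        # no blobs at all, so no split/fp, and the loss is analytic
        assert b.split == 0.0 and b.false_positive == 0.0
        assert b.point_level == pytest.approx(2 * np.log(2))
        assert b.image_level == pytest.approx(np.log(2))

    def test_all_terms_nonnegative_on_random_maps(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(0, 1, size=(7, 7))
            s = np.stack([1 - p, p], axis=2)
            pts = [tuple(q) for q in rng.integers(0, 7, size=(3, 2))]
            b = lc.lc_loss(s, set(pts))
            for term in (b.image_level, b.point_level, b.split, b.false_positive):
                assert term >= 0
                assert b.total >= term - 1e-12

    def test_loss_vanishes_along_perfecting_family(self):
        points = [(1, 1), (4, 4)]
        totals = []
        for eps in (0.3, 0.1, 0.01, 1e-4):
            s = np.zeros((6, 6, 2))
            s[..., 0] = 1.0 - eps
            s[..., 1] = eps
            for r, c in points:
                s[r, c] = [eps, 1.0 - eps]
            totals.append(lc.lc_loss(s, points).total)
        assert all(a > b for a, b in zip(totals, totals[1:]))
        assert totals[-1] < 1e-3


class TestGradient:
    @pytest.mark.parametrize("points", [[], [(1, 1)], [(1, 1), (3, 3), (1, 3)]])
    def test_finite_difference_matches_analytic(self, points):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.2, 0.8, size=(5, 5))
        s = np.stack([1 - p, p], axis=2)
        _, grad = lc.lc_loss_gradient(s, points)
        eps = 1e-7
        for r, c, ch in [(0, 0, 0), (1, 1, 1), (2, 2, 0), (3, 3, 1), (4, 4, 0)]:
            sp, sm = s.copy(), s.copy()
            sp[r, c, ch] += eps
            sm[r, c, ch] -= eps
            fd = (lc.lc_loss(sp, points).total - lc.lc_loss(sm, points).total) / (
                2 * eps
            )
            assert grad[r, c, ch] == pytest.approx(fd, abs=1e-4)

    def test_breakdown_matches_plain_loss(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=(6, 6))
        s = np.stack([1 - p, p], axis=2)
        points = [(2, 2), (4, 1)]
        direct = lc.lc_loss(s, points)
        via_grad, _ = lc.lc_loss_gradient(s, points)
        assert via_grad.total == pytest.approx(direct.total, rel=1e-12)


def test_invalid_probability_maps_rejected():
    with pytest.raises(ValueError, match="H×W×2"):
        lc.check_probability_map(np.zeros((4, 4)))
    bad = np.full((2, 2, 2), 0.8)
    with pytest.raises(ValueError, match="sum to 1"):
        lc.check_probability_map(bad)
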