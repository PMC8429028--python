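"""Component-overlap metric, curves and lesion counting."""

import numpy as np
import pytest

from funduseg.evaluation import (
    ConfusionCounts,
    MatchConfig,
    classify_pixels,
    compute_metrics,
    count_lesions,
    extract_components,
    pr_curve,
    roc_curve,
)
from sigma_oracle import flood_components, sigma_classify

from conftest import make_masks


def random_blob_mask(rng, shape=(32, 32), n_blobs=(0, 4)):
    """A few random rectangles/discs; produces touching and disjoint cases."""
    m = np.zeros(shape, dtype=np.uint8)
    for _ in range(rng.integers(*n_blobs, endpoint=True)):
        r, c = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        h, w = rng.integers(1, 8, size=2)
        m[max(0, r - h):r + h, max(0, c - w):c + w] = 1
    return m


class TestExtractComponents:
    def test_empty_mask_has_no_components(self):
        cs = extract_components(np.zeros((8, 8)))
        assert cs.n_components == 0
        assert not cs.union.any()

    def test_diagonal_pixels_depend_on_connectivity(self):
        m = np.zeros((4, 4))
        m[1, 1] = m[2, 2] = 1
        assert extract_components(m, connectivity=8).n_components == 1
        assert extract_components(m, connectivity=4).n_components == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(30):
            m = random_blob_mask(rng)
            ours = extract_components(m, connectivity)
            oracle = flood_components(m, connectivity)
            assert ours.n_components == len(oracle)
            got = {frozenset(map(tuple, comp)) for comp in
                   (np.argwhere(ours.labels == i) for i in range(1, ours.n_components + 1))}
            assert got == {frozenset(c) for c in oracle}


class TestClassifyPixels:
    def test_perfect_match_is_all_tp(self):
        m = np.zeros((8, 8))
        m[2:5, 2:5] = 1
        counts, raster = classify_pixels(
            extract_components(m), extract_components(m), MatchConfig(sigma=0.2))
        assert (counts.TP, counts.FP, counts.FN) == (9, 0, 0)
        assert counts.total == 64

    def test_sigma_zero_touch_rule(self):
        # one-pixel overlap: at sigma=0 the whole detection becomes TP
        det = np.zeros((12, 12))
        det[0:4, 0:4] = 1
        truth = np.zeros((12, 12))
        truth[3:6, 3:6] = 1
        counts, _ = classify_pixels(
            extract_components(det), extract_components(truth), MatchConfig(sigma=0.0))
        assert counts.TP == 16 + 9 - 1  # both components fully credited
        assert counts.FP == 0 and counts.FN == 0

    def test_worked_example_12x12(self):
        # 2x2 detection vs 3x3 truth, 1-px overlap, sigma=0.2:
        # detection ratio 1/4 > 0.2 -> its 4 px are TP; truth ratio 1/9 <= 0.2
        # -> its 8 non-overlap px are FN
        det = np.zeros((12, 12))
        det[0:2, 0:2] = 1
        truth = np.zeros((12, 12))
        truth[1:4, 1:4] = 1
        counts, raster = classify_pixels(
            extract_components(det), extract_components(truth), MatchConfig(sigma=0.2))
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (4, 0, 8, 132)
        oracle = sigma_classify(det, truth, 0.2)
        assert oracle["counts"] == (4, 0, 8, 132)
        rep = compute_metrics(counts)
        assert rep.sensitivity == pytest.approx(1 / 3)
        assert rep.precision == 1.0
        assert rep.f1 == pytest.approx(0.5)

    @pytest.mark.parametrize("sigma", [0.0, 0.2, 0.5, 1.0])
    def test_matches_literal_oracle_on_random_pairs(self, rng, sigma):
        for _ in range(60):
            det = random_blob_mask(rng)
            truth = random_blob_mask(rng)
            counts, raster = classify_pixels(
                extract_components(det), extract_components(truth),
                MatchConfig(sigma=sigma))
            oracle = sigma_classify(det, truth, sigma)
            assert (counts.TP, counts.FP, counts.FN, counts.TN) == oracle["counts"]
            assert counts.total == det.size

    def test_sigma_monotonicity(self, rng):
        for _ in range(20):
            det, truth = random_blob_mask(rng), random_blob_mask(rng)
            cs_d, cs_t = extract_components(det), extract_components(truth)
            tps = [classify_pixels(cs_d, cs_t, MatchConfig(sigma=s))[0].TP
                   for s in (0.0, 0.2, 0.5, 1.0)]
            assert all(a >= b for a, b in zip(tps, tps[1:]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            classify_pixels(extract_components(np.zeros((4, 4))),
                            extract_components(np.zeros((5, 5))))

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(sigma=1.5)
        with pytest.raises(ValueError):
            MatchConfig(connectivity=6)


class TestComputeMetrics:
    def test_direct_formulas(self):
        rep = compute_metrics(ConfusionCounts(TP=4, FP=0, FN=8, TN=132))
        assert rep.sensitivity == pytest.approx(1 / 3)
        assert rep.precision == 1.0
        assert rep.f1 == pytest.approx(0.5)
        assert rep.accuracy == pytest.approx(136 / 144)

    def test_zero_tp_with_fn_gives_zero_sensitivity(self):
        rep = compute_metrics(ConfusionCounts(TP=0, FP=0, FN=5, TN=10))
        assert rep.sensitivity == 0.0

    def test_all_tn_flags_undefined(self):
        rep = compute_metrics(ConfusionCounts(TN=100))
        assert rep.specificity == 1.0 and rep.accuracy == 1.0
        assert rep.sensitivity == 0.0
        assert "sensitivity" in rep.undefined

    def test_perfect_prediction_all_ones(self):
        rep = compute_metrics(ConfusionCounts(TP=50, TN=50))
        assert (rep.sensitivity, rep.specificity, rep.precision,
                rep.accuracy, rep.f1) == (1, 1, 1, 1, 1)


class TestCurves:
    def test_perfect_scores(self):
        y = np.zeros((20, 20))
        y[5:10, 5:10] = 1
        _, auc = roc_curve(y.astype(float), y)
        _, aupr = pr_curve(y.astype(float), y)
        assert auc == 1.0
        assert aupr == pytest.approx(1.0)

    def test_random_scores_near_chance(self, rng):
        n = 200_000
        y = (rng.random(n) < 0.1).astype(int)
        s = rng.random(n)
        _, auc = roc_curve(s, y)
        assert abs(auc - 0.5) < 0.05
        _, aupr = pr_curve(s, y)
        assert aupr == pytest.approx(y.mean(), rel=0.15)

    def test_score_reversal_flips_auc(self, rng):
        y = (rng.random(5000) < 0.3).astype(int)
        s = rng.random(5000) + 0.5 * y
        _, auc = roc_curve(s, y)
        _, auc_rev = roc_curve(-s, y)
        assert auc + auc_rev == pytest.approx(1.0)

    def test_constant_truth_raises(self):
        with pytest.raises(ValueError):
            roc_curve(np.random.rand(10), np.zeros(10))
        with pytest.raises(ValueError):
            pr_curve(np.random.rand(10), np.zeros(10))


class TestCountLesions:
    def test_empty_masks_count_zero(self):
        masks = make_masks(shape=(16, 16))
        assert list(count_lesions(masks).values()) == [0, 0, 0, 0]

    def test_disjoint_blobs_counted(self):
        m = np.zeros((32, 32))
        for i in range(5):
            m[1 + 6 * i:3 + 6 * i, 1:3] = 1
        masks = make_masks(shape=(32, 32), MA=m)
        assert count_lesions(masks)["MA"] == 5

    def test_merging_blobs_decreases_count(self):
        m = np.zeros((16, 16))
        m[2:4, 2:5] = 1
        m[2:4, 7:10] = 1
        masks = make_masks(shape=(16, 16), HE=m)
        assert count_lesions(masks)["HE"] == 2
        m2 = m.copy()
        m2[2:4, 5:7] = 1  # bridge the gap
        assert count_lesions(make_masks(shape=(16, 16), HE=m2))["HE"] == 1
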