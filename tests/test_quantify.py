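"""Segmentation and metrics tests, with brute-force and library oracles."""

import numpy as np
import pytest

from genodt.quantify import (
    SegmentationError, classify_remodeling, correlate_features,
    otsu_threshold, prediction_metrics, regional_fractions,
)


def brute_force_otsu(x):
    """Independent oracle: exhaustive between-class-variance search."""
    x = np.sort(np.asarray(x, float).ravel())
    best_t, best_sb = None, -1.0
    vals = np.unique(x)
    for i in range(len(vals) - 1):
        t = 0.5 * (vals[i] + vals[i + 1])
        lo, hi = x[x <= t], x[x > t]
        w0, w1 = len(lo) / len(x), len(hi) / len(x)
        sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sb > best_sb:
            best_sb, best_t = sb, t
    return best_t


class TestOtsu:
    def test_bimodal_separation(self):
        x = np.concatenate([np.full(100, 10.0), np.full(100, 100.0)])
        t = otsu_threshold(x)
        assert 10.0 < t < 100.0
        assert np.all((x <= t) == (x == 10.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(30, 5, 200), rng.normal(70, 8, 80)])
        assert otsu_threshold(x) == pytest.approx(brute_force_otsu(x))

    def test_constant_image_errors(self):
        with pytest.raises(SegmentationError, match="degenerate"):
            otsu_threshold(np.full(50, 7.0))

    def test_against_skimage_on_quantized_data(self):
        """Cross-check with the scikit-image reference on integer data."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(60, 10, 400),
                            rng.normal(160, 15, 200)]).round()
        mine = otsu_threshold(x)
        ref = threshold_otsu(x.astype(np.int32), nbins=int(x.max() + 1))
        # same partition of the data regardless of convention
        assert np.array_equal(x <= mine, x <= ref + 0.5) or \
            np.array_equal(x <= mine, x <= ref - 0.5) or \
            np.array_equal(x <= mine, x <= ref)


def _toy_image():
    """Low class {25,35} (mean 30, sd 5), a sizeable scar population and
    probe pixels at the band edges."""
    img = np.zeros((1, 142))
    img[0, :50] = 25.0
    img[0, 50:100] = 35.0
    img[0, 100:140] = 52.0  # >= 30 + 4*5 -> scar
    img[0, 140] = 45.0      # in [40, 50) -> fibrosis
    img[0, 141] = 50.0      # boundary: exactly 4 SD -> scar (inclusive)
    mask = np.ones_like(img, dtype=bool)
    return img, mask


class TestClassify:
    def test_forced_rule_classification(self):
        img, mask = _toy_image()
        seg = classify_remodeling(img, mask)
        assert seg.ref_mean == pytest.approx(30.0)
        assert seg.ref_sd == pytest.approx(5.0)
        assert seg.scar_mask[0, 100]          # 52 >= 50
        assert seg.scar_mask[0, 141]          # exactly 4 SD is scar
        assert seg.fibrosis_mask[0, 140]      # 45 in [40, 50)
        assert not seg.scar_mask[0, 140]
        assert not seg.fibrosis_mask[0, 0]    # 25 is normal

    def test_partition_of_myocardium(self):
        rng = np.random.default_rng(3)
        img = rng.normal(50, 20, (32, 32))
        mask = rng.random((32, 32)) > 0.3
        seg = classify_remodeling(img, mask)
        normal = mask & ~seg.scar_mask & ~seg.fibrosis_mask
        counts = (normal.astype(int) + seg.scar_mask.astype(int) +
                  seg.fibrosis_mask.astype(int))
        assert np.all(counts[mask] == 1)
        assert np.all(counts[~mask] == 0)

    def test_intensity_shift_invariance(self):
        img, mask = _toy_image()
        seg0 = classify_remodeling(img, mask)
        seg1 = classify_remodeling(img + 17.0, mask)
        assert seg1.otsu_threshold == pytest.approx(seg0.otsu_threshold + 17.0)
        assert seg1.ref_mean == pytest.approx(seg0.ref_mean + 17.0)
        assert np.array_equal(seg0.scar_mask, seg1.scar_mask)
        assert np.array_equal(seg0.fibrosis_mask, seg1.fibrosis_mask)

    def test_zero_reference_variance_errors(self):
        img = np.zeros((1, 100))
        img[0, :90] = 30.0
        img[0, 90:] = 100.0
        with pytest.raises(SegmentationError, match="variance"):
            classify_remodeling(img, np.ones_like(img, dtype=bool))


class TestRegionalFractions:
    def test_whole_mask_scar_sums_to_100(self):
        img = np.zeros((6, 6))
        img[:, :3] = 30.0
        img[0, 0] = 25.0  # low-class spread so ref_sd > 0
        img[:, 3:] = 100.0
        mask = np.ones_like(img, dtype=bool)
        seg = classify_remodeling(img, mask)
        regions = np.repeat([[1, 1, 1, 2, 2, 2]], 6, axis=0)
        tab = regional_fractions(seg, regions)
        assert tab["DS_pct"].sum() == pytest.approx(
            100.0 * seg.scar_mask.sum() / mask.sum())

    def test_hand_counted_toy(self):
        """10x10 sheet, hand-countable: low class {28, 32} (mean 30, sd 2),
        15 scar px (44 = 7 SD) in region 1, 25 fibrosis px (36 = 3 SD) in
        region 2; fractions are per total tissue (100 px)."""
        img = np.empty((10, 10))
        flat = np.concatenate([
            np.full(15, 44.0),   # rows 0-1.5 -> region 1 scar
            np.full(15, 28.0),
            np.full(20, 32.0),   # rows 3-4 normal
            np.full(25, 36.0),   # rows 5-7.5 -> region 2 fibrosis
            np.full(15, 28.0),
            np.full(10, 32.0),
        ])
        img[:] = flat.reshape(10, 10)
        mask = np.ones_like(img, dtype=bool)
        regions = np.zeros((10, 10), dtype=int)
        regions[:5] = 1
        regions[5:] = 2
        seg = classify_remodeling(img, mask)
        assert seg.ref_mean == pytest.approx(30.0)
        assert seg.ref_sd == pytest.approx(2.0)
        tab = regional_fractions(seg, regions)
        assert tab.loc[1, "DS_pct"] == pytest.approx(15.0)
        assert tab.loc[2, "DF_pct"] == pytest.approx(25.0)
        assert tab.loc[1, "TFV_pct"] == pytest.approx(15.0)
        assert tab.loc[2, "TFV_pct"] == pytest.approx(25.0)

    def test_empty_region_warns_zero(self):
        img, mask = _toy_image()
        seg = classify_remodeling(img, mask)
        regions = np.ones(img.shape, dtype=int)
        with pytest.warns(UserWarning, match="empty"):
            tab = regional_fractions(seg, regions, region_ids=[1, 2])
        assert tab.loc[2, "TFV_pct"] == 0.0


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        r = correlate_features({"x": x, "y": 2 * x + 1})
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_symmetric_zero(self):
        r = correlate_features({"x": [1.0, 2.0, 3.0], "y": [1.0, 0.0, 1.0]})
        assert r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 9.0])
        # textbook formula
        rx = x - x.mean()
        ry = y - y.mean()
        r_hand = (rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        r = correlate_features({"x": x, "y": y})
        assert r.loc["x", "y"] == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlate_features({"x": [1.0, 2.0, 3.0], "y": [1.0, 1.0, 1.0]})
        assert np.isnan(r.loc["x", "y"])

    def test_requires_three_observations(self):
        with pytest.raises(ValueError):
            correlate_features({"x": [1.0, 2.0], "y": [3.0, 4.0]})


class TestPredictionMetrics:
    UNIVERSE = list("abcdefghi")

    def test_perfect_prediction(self):
        m = prediction_metrics({"a", "b"}, {"a", "b"}, self.UNIVERSE)
        assert (m.sensitivity, m.specificity, m.accuracy, m.f1, m.mcc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)
        assert m.error_rate == 0.0

    def test_hand_computed_confusion(self):
        # TP=2 FP=1 FN=1 TN=5 over a 9-region universe
        m = prediction_metrics({"a", "b", "c"}, {"a", "b", "d"}, self.UNIVERSE)
        assert m.tp == 2 and m.fp == 1 and m.fn == 1 and m.tn == 5
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.accuracy == pytest.approx(7 / 9)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(0.5)

    def test_no_positives_predicted(self):
        m = prediction_metrics(set(), {"a"}, self.UNIVERSE)
        assert m.sensitivity == 0.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            prediction_metrics({"a"}, {"a"}, [])

    def test_accuracy_error_identity_and_oracles(self):
        """100 random region sets: accuracy + error = 1 and F1/MCC agree
        with direct formula evaluation and scikit-learn."""
        from sklearn.metrics import f1_score, matthews_corrcoef
        import math

        rng = np.random.default_rng(11)
        for _ in range(100):
            pred = {r for r in self.UNIVERSE if rng.random() < 0.4}
            obs = {r for r in self.UNIVERSE if rng.random() < 0.4}
            m = prediction_metrics(pred, obs, self.UNIVERSE)
            assert m.accuracy + m.error_rate == pytest.approx(1.0)
            y_true = [r in obs for r in self.UNIVERSE]
            y_pred = [r in pred for r in self.UNIVERSE]
            if any(y_pred) or any(y_true):
                assert m.f1 == pytest.approx(
                    f1_score(y_true, y_pred, zero_division=0))
            denom = math.sqrt((m.tp + m.fp) * (m.tp + m.fn) *
                              (m.tn + m.fp) * (m.tn + m.fn))
            if denom:
                assert m.mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred))
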