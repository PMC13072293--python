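import numpy as np
import pytest

from fluopix.evaluate import (
    RocCurve,
    annotation_overlap,
    detection_mask,
    detection_rate_table,
    embed_qualitative,
    negative_frame_specificity,
    optimal_operating_point,
    roc_curve,
)


def pairwise_auc(scores, labels):
    """Exhaustive O(n^2) oracle: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        s = np.r_[np.ones(5), np.zeros(5)]
        y = np.r_[np.ones(5), np.zeros(5)]
        assert roc_curve(s, y).auc == 1.0

    def test_all_tied_scores(self):
        s = np.full(10, 2.0)
        y = np.r_[np.ones(5), np.zeros(5)]
        assert roc_curve(s, y).auc == 0.5

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            y = np.r_[np.ones(n // 2 + 1), np.zeros(n - n // 2 - 1)]
            s = rng.integers(0, 6, len(y)).astype(float)  # heavy ties
            assert roc_curve(s, y).auc == pytest.approx(pairwise_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.ones(4), np.ones(4))


class TestOperatingPoint:
    def test_perfect_classifier(self):
        s = np.r_[np.ones(6), np.zeros(6)]
        y = np.r_[np.ones(6), np.zeros(6)]
        op = optimal_operating_point(roc_curve(s, y))
        assert op.sensitivity == 1.0 and op.specificity == 1.0
        assert op.accuracy == 1.0

    def test_tie_breaks_toward_specificity(self):
        # J values by hand: 0.2, 0.5, 0.5, 0.1 -> the J=0.5 point with the
        # higher specificity (threshold 3) must win
        curve = RocCurve(
            thresholds=np.array([4.0, 3.0, 2.0, 1.0]),
            sensitivity=np.array([0.4, 0.7, 0.9, 1.0]),
            specificity=np.array([0.8, 0.8, 0.6, 0.1]),
            auc=0.7,
        )
        op = optimal_operating_point(curve)
        assert op.threshold == 3.0
        assert op.specificity == 0.8 and op.sensitivity == 0.7

    def test_random_scores_give_small_j(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=1000)
        y = rng.integers(0, 2, 1000)
        op = optimal_operating_point(roc_curve(s, y))
        assert abs(op.sensitivity + op.specificity - 1.0) <= 0.15


class TestDetectionRates:
    def test_threshold_below_all_scores(self):
        t = detection_rate_table([1, 2, 3, 4], [5, 5, 1, 1], tau=0.0)
        assert (t["detection_rate"] == 100.0).all()

    def test_threshold_above_all_scores(self):
        t = detection_rate_table([1, 2, 3, 4], [5, 5, 1, 1], tau=10.0)
        assert (t["detection_rate"] == 0.0).all()

    def test_direct_count(self):
        t = detection_rate_table([1, 2, 3, 4], [5, 5, 5, 5], tau=2.5)
        assert t["detection_rate"].tolist() == [50.0]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=500)
        c = rng.choice([5.0, 0.5, 0.1], 500)
        tau = 0.3
        a = detection_rate_table(s, c, tau)
        b = detection_rate_table(np.exp(s), c, np.exp(tau))
        np.testing.assert_allclose(a["detection_rate"], b["detection_rate"])


class TestNegativeFrameSpecificity:
    @staticmethod
    def frame_with_black(h, w, n_black):
        f = np.full((h, w, 3), 30, dtype=np.uint8)
        f.reshape(-1, 3)[:n_black] = 0
        return f

    def test_empty_masks_give_perfect_specificity(self):
        frames = [self.frame_with_black(10, 10, 5)] * 3
        masks = [np.zeros((10, 10), bool)] * 3
        rep = negative_frame_specificity(masks, frames)
        assert (rep.specificity_all == 1.0).all() and rep.pooled == 1.0

    def test_pooled_equals_count_weighted_combination(self):
        rng = np.random.default_rng(3)
        frames, masks = [], []
        for k in range(4):
            frames.append(self.frame_with_black(20, 30, 10 * k))
            m = np.zeros((20, 30), bool)
            m.ravel()[rng.choice(600, 5 * (k + 1), replace=False)] = True
            masks.append(m)
        rep = negative_frame_specificity(masks, frames)
        expected = 1.0 - rep.fp_counts.sum() / rep.totals.sum()
        assert rep.pooled == pytest.approx(expected)
        # algebraic identity against per-frame values
        recombined = (rep.specificity_all * rep.totals).sum() / rep.totals.sum()
        assert rep.pooled == pytest.approx(recombined)

    def test_all_black_frame_rejected(self):
        frame = np.zeros((5, 5, 3), dtype=np.uint8)
        with pytest.raises(ZeroDivisionError):
            negative_frame_specificity([np.zeros((5, 5), bool)], [frame])

    def test_detection_mask_never_flags_black_pixels(self):
        frame = self.frame_with_black(8, 8, 12)
        scores = np.full((8, 8), 10.0)
        mask = detection_mask(scores, frame, tau=1.0)
        from fluopix.frame import black_mask

        assert not mask[black_mask(frame)].any()
        assert mask[~black_mask(frame)].all()


class TestAnnotationOverlap:
    def test_identical_masks(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        rep = annotation_overlap(m, m)
        assert rep.area_ratio == 1.0 and rep.coverage == 1.0

    def test_strict_superset_ratio(self):
        annot = np.zeros((10, 10), bool)
        annot.ravel()[:10] = True
        model = annot.copy()
        model.ravel()[10:24] = True  # 24 vs 10 true pixels
        rep = annotation_overlap(model, annot)
        assert rep.area_ratio == pytest.approx(2.4)
        assert rep.coverage == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert annotation_overlap(a, b).coverage == 0.0

    def test_empty_annotation_is_undefined(self):
        rep = annotation_overlap(np.ones((3, 3), bool), np.zeros((3, 3), bool))
        assert rep.area_ratio is None and rep.coverage is None


class TestEmbedding:
    @staticmethod
    def clusters(seed=0, n=250):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, (n, 10))
        b = rng.normal(10.0, 1.0, (n, 10))
        X = np.vstack([a, b])
        y = np.r_[np.zeros(n), np.ones(n)]
        return X, y

    def test_shape_and_determinism(self):
        X, _ = self.clusters()
        z1 = embed_qualitative(X, perplexity=40, seed=3)
        z2 = embed_qualitative(X, perplexity=40, seed=3)
        assert z1.shape == (len(X), 2)
        np.testing.assert_array_equal(z1, z2)

    def test_separated_clusters_stay_separable(self):
        X, y = self.clusters(seed=1)
        z = embed_qualitative(X, perplexity=40, seed=0)
        c0 = z[y == 0].mean(axis=0)
        c1 = z[y == 1].mean(axis=0)
        pred = np.linalg.norm(z - c1, axis=1) < np.linalg.norm(z - c0, axis=1)
        assert (pred == y.astype(bool)).mean() >= 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            embed_qualitative(np.zeros((100, 10)), perplexity=50)
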