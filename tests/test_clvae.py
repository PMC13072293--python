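import numpy as np
import pytest

from conftest import ladder_pools
from fluopix.clvae import (
    TrainedClvae,
    VaeConfig,
    beta_at,
    calibrate_threshold,
    kl_anomaly_score,
    lr_at,
    train_clvae,
)
from fluopix.evaluate import roc_curve
from fluopix.sampling import (
    NEGATIVE,
    POSITIVE,
    build_anomaly_training_set,
    extract_roi_pixels,
)
from fluopix.synth import SampleSceneSpec, render_sample_scene


class TestBetaSchedule:
    def test_cycle_start_is_zero(self):
        assert beta_at(VaeConfig(), 0) == 0.0

    def test_plateau_half_is_beta_max(self):
        cfg = VaeConfig(beta_max=2.0)  # defaults: cycle length 50
        for epoch in (25, 30, 49, 75, 999):
            assert beta_at(cfg, epoch) == 2.0

    def test_periodicity(self):
        cfg = VaeConfig()
        first = [beta_at(cfg, e) for e in range(50)]
        second = [beta_at(cfg, e) for e in range(50, 100)]
        assert first == second

    def test_bounds_and_ramp_endpoint(self):
        cfg = VaeConfig(beta_max=3.0)
        vals = np.array([beta_at(cfg, e) for e in range(cfg.epochs)])
        assert (0 <= vals).all() and (vals <= 3.0).all()
        assert beta_at(cfg, 24) == pytest.approx(3.0)  # ramp hits max exactly

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            beta_at(VaeConfig(), 1000)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            VaeConfig(epochs=999)  # not divisible by 20 cycles
        with pytest.raises(ValueError):
            VaeConfig(lr_start=1e-4, lr_end=1e-3)


class TestLrSchedule:
    def test_endpoints(self):
        cfg = VaeConfig()
        assert lr_at(cfg, 0) == pytest.approx(1e-3)
        assert lr_at(cfg, 999) == pytest.approx(1e-4)

    def test_midpoint_is_geometric_mean(self):
        cfg = VaeConfig(epochs=1000, cycles=20)
        # closed form: sqrt(1e-3 * 1e-4) at the midpoint of the exponent
        mid = np.sqrt(1e-3 * 1e-4)
        assert lr_at(cfg, 499) == pytest.approx(mid, rel=2e-3)

    def test_strictly_decreasing(self):
        cfg = VaeConfig(epochs=200, cycles=20)
        lrs = [lr_at(cfg, e) for e in range(200)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))


class TestKlScore:
    def test_prior_posterior_scores_zero(self):
        assert kl_anomaly_score([0, 0, 0], [0, 0, 0]) == 0.0

    def test_unit_mean_shift(self):
        assert kl_anomaly_score([1, 0, 0], [0, 0, 0]) == pytest.approx(0.5)

    def test_inflated_variance(self):
        # sigma^2 = e in one coordinate: 0.5 * (e - 2)
        assert kl_anomaly_score([0, 0, 0], [1, 0, 0]) == pytest.approx(
            0.5 * (np.e - 2)
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            kl_anomaly_score([np.inf, 0, 0], [0, 0, 0])

    def test_nonnegative_on_random_posteriors(self):
        rng = np.random.default_rng(0)
        s = kl_anomaly_score(rng.normal(0, 2, (200, 3)),
                             rng.normal(0, 1, (200, 3)))
        assert (s >= 0).all()


class TestTraining:
    def test_loss_trace_finite_and_improving(self, tiny_clvae):
        trace = tiny_clvae.loss_trace
        assert trace.shape == (tiny_clvae.config.epochs,)
        assert np.isfinite(trace).all()
        k = min(20, len(trace) // 2)
        assert trace[-k:].mean() <= trace[:k].mean()

    def test_bit_identical_retrain(self, sample_scene):
        frame, gt = sample_scene
        pos, neg = ladder_pools(frame, gt)
        normal, pairs = build_anomaly_training_set(neg, pos, 2000, 300, seed=1)
        cfg = VaeConfig(epochs=40, cycles=10, seed=5)
        m1 = train_clvae(normal, pairs, cfg)
        m2 = train_clvae(normal, pairs, cfg)
        np.testing.assert_array_equal(m1.loss_trace, m2.loss_trace)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_empty_normal_set_rejected(self):
        with pytest.raises(ValueError):
            train_clvae(np.empty((0, 10)), None, VaeConfig(epochs=40, cycles=10))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_clvae(np.zeros((50, 3)), None, VaeConfig(epochs=40, cycles=10))

    def test_heldout_strong_fluorescence_auc(self):
        # trained on one scene's normals, the detector must separate
        # held-out c=5 pixels from held-out negatives almost perfectly
        for seed in (0, 1, 2):
            spec = SampleSceneSpec(well_radius=16)
            ftr, gtr = render_sample_scene(spec, 50 + seed)
            fte, gte = render_sample_scene(spec, 150 + seed)
            pos, neg = ladder_pools(ftr, gtr)
            normal, pairs = build_anomaly_training_set(neg, pos, 6000, 1000, seed)
            model = train_clvae(
                normal, pairs, VaeConfig(epochs=200, cycles=20, seed=seed)
            )
            s_pos = model.score(
                extract_roi_pixels(fte, gte.roi_masks[5.0], POSITIVE).features()
            )
            _, neg_te = ladder_pools(fte, gte)
            s_neg = model.score(neg_te.features())
            auc = roc_curve(
                np.r_[s_pos, s_neg],
                np.r_[np.ones(len(s_pos)), np.zeros(len(s_neg))],
            ).auc
            assert auc >= 0.99

    def test_vague_fluorescence_scores_above_reference(self, tiny_clvae, sample_scene):
        frame, gt = sample_scene
        vague = tiny_clvae.score(
            extract_roi_pixels(frame, gt.roi_masks[0.5], POSITIVE).features()
        )
        ref = tiny_clvae.score(
            extract_roi_pixels(frame, gt.roi_masks[0.0], NEGATIVE).features()
        )
        assert vague.mean() > ref.mean()


class TestScoring:
    def test_constant_frame_constant_scores(self, tiny_clvae):
        frame = np.full((8, 11, 3), (30, 10, 60), dtype=np.uint8)
        plane = tiny_clvae.score_frame(frame)
        assert plane.shape == (8, 11)
        assert np.ptp(plane) == 0

    def test_scores_nonnegative_and_match_scalar_path(self, tiny_clvae):
        rng = np.random.default_rng(3)
        frame = rng.integers(0, 256, (24, 31, 3), dtype=np.uint8)
        plane = tiny_clvae.score_frame(frame)
        assert plane.min() >= 0
        from fluopix.features import extract_features

        for i, j in zip(rng.integers(0, 24, 30), rng.integers(0, 31, 30)):
            expect = tiny_clvae.score(extract_features(*frame[i, j])[None, :])[0]
            assert plane[i, j] == pytest.approx(expect, abs=1e-12)

    def test_checkpoint_roundtrip_is_exact(self, tiny_clvae, tmp_path):
        tiny_clvae.save(tmp_path / "ckpt")
        loaded = TrainedClvae.load(tmp_path / "ckpt")
        x = np.random.default_rng(4).uniform(0, 1, (50, 10))
        np.testing.assert_array_equal(tiny_clvae.score(x), loaded.score(x))


class TestCalibrateThreshold:
    def test_order_statistic_example(self):
        tau = calibrate_threshold(np.arange(1, 101), 0.99)
        assert tau == 99
        scores = np.arange(1, 101)
        assert (scores > tau).sum() == 1  # only the top score flagged

    def test_all_equal_scores_flag_nothing(self):
        tau = calibrate_threshold(np.full(40, 3.2), 0.99)
        assert tau == 3.2
        assert (np.full(40, 3.2) > tau).sum() == 0

    def test_target_one_returns_max(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=77)
        assert calibrate_threshold(s, 1.0) == s.max()

    def test_empty_and_invalid_target(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([]), 0.99)
        with pytest.raises(ValueError):
            calibrate_threshold(np.ones(5), 0.0)
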