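import numpy as np
import pytest

from fluopix.quantify import (
    REFERENCE_BIVARIATE,
    REFERENCE_QUADRATIC,
    QuantModel,
    fit_poly_2d,
    fit_quadratic_1d,
    predict_concentration,
    rank_feature_importance,
    reference_bivariate,
    reference_quadratic,
    render_concentration_map,
)
from fluopix.synth import SampleSceneSpec, render_sample_scene
from fluopix.features import extract_features_frame


class TestFeatureImportance:
    @staticmethod
    def make_data(seed, n=1200):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, 10))
        y = 5.0 * X[:, 0] + rng.normal(0, 0.2, n)
        return X, y

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_informative_feature_ranked_first(self, seed):
        X, y = self.make_data(seed)
        rep = rank_feature_importance(X, y, n_trees=50, seed=seed)
        assert rep.ranks[0] == 1
        # independent features score at least 10x below the top feature
        assert np.abs(rep.importances[1:]).max() <= rep.importances[0] / 10

    def test_deterministic(self):
        X, y = self.make_data(5)
        a = rank_feature_importance(X, y, n_trees=30, seed=9)
        b = rank_feature_importance(X, y, n_trees=30, seed=9)
        np.testing.assert_array_equal(a.importances, b.importances)
        assert a.oob_r2 == b.oob_r2

    def test_ranks_are_a_permutation(self):
        X, y = self.make_data(6, n=300)
        rep = rank_feature_importance(X, y, n_trees=20, seed=0)
        assert sorted(rep.ranks) == list(range(1, 11))

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            rank_feature_importance(np.zeros((10, 10)), np.zeros(10))


class TestPolynomialFits:
    def test_quadratic_recovers_reference_coefficients(self):
        p1, p2, p3 = REFERENCE_QUADRATIC
        x = np.linspace(0, 1, 200)
        model = fit_quadratic_1d(x, p1 + p2 * x + p3 * x**2)
        np.testing.assert_allclose(model.coeffs, REFERENCE_QUADRATIC, atol=1e-6)
        assert model.r_squared == pytest.approx(1.0)

    def test_bivariate_recovers_reference_coefficients(self):
        p00, p10, p01, p20, p11 = REFERENCE_BIVARIATE
        gx, gy = np.meshgrid(np.linspace(0, 1, 20), np.linspace(0, 1, 20))
        c = p00 + p10 * gx + p01 * gy + p20 * gx**2 + p11 * gx * gy
        model = fit_poly_2d(gx.ravel(), gy.ravel(), c.ravel())
        np.testing.assert_allclose(model.coeffs, REFERENCE_BIVARIATE, atol=1e-6)

    def test_constant_response_convention(self):
        model = fit_quadratic_1d(np.linspace(0, 1, 30), np.full(30, 2.5))
        assert model.coeffs == (2.5, 0.0, 0.0)
        assert model.r_squared == 0.0

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_1d([1, 1, 2, 2], [0, 0, 1, 1])

    def test_bivariate_drops_unused_predictor(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 600)
        y = rng.uniform(0, 1, 600)
        c = 1.0 + 3.0 * x + 2.0 * x**2 + rng.normal(0, 0.01, 600)
        model = fit_poly_2d(x, y, c)
        assert abs(model.coeffs[2]) < 0.05 and abs(model.coeffs[4]) < 0.05

    def test_perfect_fit_r_squared_one(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        c = 0.3 - x + 0.5 * y + 2 * x**2 - 3 * x * y
        assert fit_poly_2d(x, y, c).r_squared == pytest.approx(1.0)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0, 1, 400), rng.uniform(0, 1, 400)
        c = 1 + x - y + rng.normal(0, 0.5, 400)
        model = fit_poly_2d(x, y, c)
        design = np.column_stack([np.ones_like(x), x, y, x**2, x * y])
        resid = c - design @ np.array(model.coeffs)
        assert np.abs(design.T @ resid).max() < 1e-8


class TestPrediction:
    def test_reference_models_at_origin(self):
        assert predict_concentration(reference_bivariate(), 0.0, 0.0) == \
            pytest.approx(0.0327)
        assert predict_concentration(reference_quadratic(), 0.0) == \
            pytest.approx(2.166)

    def test_negative_polynomial_values_clamp_to_zero(self):
        model = QuantModel("quadratic1d", (-5.0, 0.0, 0.0))
        assert predict_concentration(model, 0.7) == 0.0

    def test_clamped_to_cmax(self):
        model = QuantModel("quadratic1d", (0.0, 100.0, 0.0))
        assert predict_concentration(model, 1.0) == 5.0

    def test_bivariate_requires_both_predictors(self):
        with pytest.raises(ValueError):
            predict_concentration(reference_bivariate(), 0.5)

    def test_serialization_roundtrip_bit_exact(self, tmp_path):
        model = reference_bivariate()
        model.save(tmp_path / "quant.json")
        loaded = QuantModel.load(tmp_path / "quant.json")
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)
        np.testing.assert_array_equal(
            predict_concentration(model, x, y),
            predict_concentration(loaded, x, y),
        )


class TestConcentrationMap:
    def test_all_false_mask_gives_zero_map(self, sample_scene):
        frame, _ = sample_scene
        conc, overlay = render_concentration_map(
            frame, reference_bivariate(), np.zeros(frame.shape[:2], bool)
        )
        assert not conc.any()
        np.testing.assert_array_equal(overlay, frame)

    def test_map_respects_clamp_range(self, sample_scene):
        frame, gt = sample_scene
        conc, _ = render_concentration_map(
            frame, reference_bivariate(), gt.fluorescence_mask
        )
        assert conc.min() >= 0 and conc.max() <= 5.0

    def test_per_well_median_monotone_with_scene_fit(self):
        frame, gt = render_sample_scene(SampleSceneSpec(well_radius=16), 21)
        feats = extract_features_frame(frame, names=("R", "pG"))
        wells = gt.fluorescence_mask
        model = fit_poly_2d(
            feats[..., 0][wells], feats[..., 1][wells],
            gt.concentration_map[wells],
        )
        conc, _ = render_concentration_map(frame, model, wells)
        medians = [
            np.median(conc[gt.roi_masks[c]])
            for c in (5.0, 2.0, 1.0, 0.5, 0.2)
        ]
        assert all(a >= b for a, b in zip(medians, medians[1:]))

    def test_mask_shape_mismatch(self, sample_scene):
        with pytest.raises(ValueError):
            render_concentration_map(
                sample_scene[0], reference_quadratic(), np.zeros((3, 3), bool)
            )
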