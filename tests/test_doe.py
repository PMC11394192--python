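"""Box–Behnken design structure, factor coding, and quadratic fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmofreeze import (
    Factor,
    FactorSpace,
    anova_table,
    fit_quadratic,
    generate_bbd,
    predict,
)
from osmofreeze.doe import QuadraticModel, SingularDesignError


class TestDesignStructure:
    def test_default_design_is_15_runs(self, bbd_runs):
        assert len(bbd_runs) == 15
        centers = [r for r in bbd_runs if r.coded == (0.0, 0.0, 0.0)]
        assert len(centers) == 3

    @pytest.mark.parametrize("n_center", [1, 3, 5])
    def test_design_counts_and_balance(self, factor_space, n_center):
        runs = generate_bbd(factor_space, n_center=n_center)
        assert len(runs) == 12 + n_center
        coded = np.array([r.coded for r in runs])
        assert np.allclose(coded.sum(axis=0), 0.0)
        assert np.allclose((coded**2).sum(axis=0), 8.0)

    def test_edge_runs_have_exactly_one_zero(self, bbd_runs):
        for r in bbd_runs[:12]:
            assert sum(1 for x in r.coded if x == 0.0) == 1
            assert all(x in (-1.0, 0.0, 1.0) for x in r.coded)

    def test_coded_columns_pairwise_orthogonal(self, bbd_runs):
        coded = np.array([r.coded for r in bbd_runs])
        gram = coded.T @ coded
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0)

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(ValueError):
            FactorSpace((Factor("a", 0, 1, 2), Factor("b", 0, 1, 2)))


class TestCoding:
    def test_named_points(self, factor_space):
        temp = factor_space.factors[0]
        assert temp.code(35.0) == 0.0
        assert temp.code(45.0) == 1.0
        assert temp.code(25.0) == -1.0
        assert factor_space.code((36.0, 72.0, 61.5)) == pytest.approx((0.1, 0.4, 0.15))

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(-2, 2, allow_nan=False))
    def test_decode_inverts_code(self, x):
        f = Factor("temperature", 25.0, 35.0, 45.0, "°C")
        assert f.code(f.decode(x)) == pytest.approx(x, abs=1e-12)


class TestQuadraticFit:
    def test_noiseless_recovery_is_exact(self, factor_space, bbd_runs):
        rng = np.random.default_rng(7)
        for _ in range(5):
            truth = rng.normal(size=10)
            model = QuadraticModel.from_coded("y", truth, factor_space)
            y = np.array([model.predict_coded(*r.coded) for r in bbd_runs])
            fit = fit_quadratic(bbd_runs, y)
            assert np.allclose(fit.coded_coeffs, truth, atol=1e-10)
            assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self, bbd_runs):
        fit = fit_quadratic(bbd_runs, np.full(15, 3.25))
        assert fit.coded_coeffs[0] == pytest.approx(3.25)
        assert np.allclose(fit.coded_coeffs[1:], 0.0, atol=1e-12)

    def test_fit_on_noisy_surface_matches_published_diagnostic_pattern(
        self, factor_space, bbd_runs, surface_models
    ):
        # water-loss surface plus realistic replicate noise: the model is
        # significant, lack of fit is not, and R2 is high.
        rng = np.random.default_rng(42)
        truth = surface_models["water_loss"]
        y = np.array([truth.predict(*r.actual) for r in bbd_runs])
        y += rng.normal(0, 0.2, size=15)
        fit = fit_quadratic(bbd_runs, y, "water_loss")
        assert fit.r2 > 0.8
        assert fit.p_model < 0.05
        assert fit.p_lack_of_fit > 0.05

    def test_pure_noise_type_I_error_rate(self, bbd_runs):
        # under a null (pure-noise) response the overall model F-test should
        # reject at roughly its nominal 5% level
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            y = rng.normal(size=15)
            if fit_quadratic(bbd_runs, y).p_model < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 < rate < 0.09

    def test_lack_of_fit_requires_replicates(self, factor_space):
        runs = generate_bbd(factor_space, n_center=1)
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            fit = fit_quadratic(runs, rng.normal(size=13))
        assert fit.p_lack_of_fit is None

    def test_singular_design_rejected(self, bbd_runs):
        runs = [r for r in bbd_runs if r.coded[0] != 1.0]
        with pytest.raises((SingularDesignError, ValueError)):
            fit_quadratic(runs, np.zeros(len(runs)))


class TestPrediction:
    def test_coded_and_uncoded_paths_agree(self, factor_space, surface_models):
        rng = np.random.default_rng(11)
        pts = rng.uniform([25, 30, 50], [45, 90, 70], size=(1000, 3))
        for model in surface_models.values():
            for T, t, C in pts[:50]:
                coded = factor_space.code((T, t, C))
                a = model.predict(T, t, C)
                b = model.predict_coded(*coded)
                assert a == pytest.approx(b, rel=1e-8)
            # vectorised check across all 1000 points
            ya = model.predict(pts[:, 0], pts[:, 1], pts[:, 2])
            xc = np.array([factor_space.code(p) for p in pts])
            yb = model.predict_coded(xc[:, 0], xc[:, 1], xc[:, 2])
            assert np.allclose(ya, yb, rtol=1e-8)

    def test_center_prediction_equals_coded_constant(self, surface_models):
        for model in surface_models.values():
            assert model.predict(35, 60, 60) == pytest.approx(
                model.coded_coeffs[0], rel=1e-12
            )

    def test_published_equations_reproduce_validation_predictions(self, surface_models):
        # predicted water activity at the reported optimum
        assert predict(surface_models["water_activity"], 36, 72, 61.5) == pytest.approx(
            0.9117, abs=0.001
        )
        # coded constants at the design centre
        assert surface_models["water_loss"].predict(35, 60, 60) == pytest.approx(4.889, abs=0.01)
        assert surface_models["delta_e"].predict(35, 60, 60) == pytest.approx(7.498, abs=0.01)


class TestAnova:
    def test_noiseless_surface_stars_true_nonzero_terms(self, factor_space, bbd_runs):
        truth = np.array([2.0, 1.5, 0.0, 0.0, -1.0, 0.0, 0.0, 0.8, 0.0, 0.0])
        model = QuadraticModel.from_coded("y", truth, factor_space)
        rng = np.random.default_rng(5)
        y = np.array([model.predict_coded(*r.coded) for r in bbd_runs])
        y += rng.normal(0, 1e-6, size=15)  # tiny noise so t-tests are defined
        tab = anova_table(fit_quadratic(bbd_runs, y), bbd_runs, y)
        starred = dict(zip(tab["term"], tab["starred"]))
        for term, coef in zip(tab["term"], truth):
            assert starred[term] == (coef != 0.0)

    def test_quadratic_terms_starred_on_water_activity_like_surface(
        self, bbd_runs, surface_models
    ):
        # replicates the published star pattern for water activity: strong
        # curvature, weak linear effects at this noise level
        rng = np.random.default_rng(0)
        truth = surface_models["water_activity"]
        y = np.array([truth.predict(*r.actual) for r in bbd_runs])
        y += rng.normal(0, 0.006, size=15)
        tab = anova_table(fit_quadratic(bbd_runs, y), bbd_runs, y)
        starred = dict(zip(tab["term"], tab["starred"]))
        assert starred["a11"] and starred["a22"] and starred["a33"]
        assert not (starred["a1"] or starred["a2"] or starred["a3"])
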