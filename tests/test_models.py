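"""Unit and property tests for the four candidate-form fitters."""

import math

import numpy as np
import pytest

import pondbounds as pb
from pondbounds import models

from conftest import brute_force_segmented_rss, make_gradient


class TestNull:
    def test_mean_is_exact(self):
        fit = pb.fit_null(pb.GradientDataset([0, 1, 2], [3, 5, 7]))
        assert fit.params["a"] == 5.0
        assert fit.k == 2

    def test_constant_data_has_zero_rmse(self):
        fit = pb.fit_null(pb.GradientDataset([0, 1, 2], [4.2, 4.2, 4.2]))
        assert fit.params["a"] == pytest.approx(4.2)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        y = rng.standard_normal(1000)
        fit = pb.fit_null(pb.GradientDataset(np.arange(1000.0), y))
        assert fit.params["a"] == pytest.approx(math.fsum(y) / 1000, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(pb.models.InsufficientDataError):
            pb.GradientDataset([1.0], [1.0])


class TestLinear:
    def test_exact_line(self):
        fit = pb.fit_linear(pb.GradientDataset([0, 1, 2], [1, 3, 5]))
        assert fit.params["b"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["c"] == pytest.approx(1.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.k == 3

    def test_constant_y_gives_zero_slope(self):
        fit = pb.fit_linear(pb.GradientDataset([0, 1, 2, 3], [4.0, 4.0, 4.0, 4.0]))
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["c"] == pytest.approx(4.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(-3, 3, 200)
        y = 0.7 * x + 1.1 + rng.normal(0, 0.4, 200)
        fit = pb.fit_linear(pb.GradientDataset(x, y))
        design = np.column_stack([x, np.ones_like(x)])
        b, c = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.params["b"] == pytest.approx(b, abs=1e-10)
        assert fit.params["c"] == pytest.approx(c, abs=1e-10)

    def test_degenerate_x_raises(self):
        with pytest.raises(pb.models.DegenerateGradientError):
            pb.fit_linear(pb.GradientDataset([2.0, 2.0, 2.0], [1, 2, 3]))


class TestSegmented:
    def test_noiseless_recovery(self):
        data = make_gradient("segmented", {"d1": 2.0, "d2": 0.0, "e1": 0.0, "bp": 1.0},
                             n=100, noise_sd=0.0, seed=11)
        fit = pb.fit_segmented(data)
        assert fit.params["bp"] == pytest.approx(1.0, abs=0.05)
        assert fit.params["d1"] == pytest.approx(2.0, abs=1e-6)
        assert fit.params["d2"] == pytest.approx(0.0, abs=1e-6)
        # continuity: right intercept is derived from the left one
        assert fit.params["e2"] == pytest.approx(
            fit.params["e1"] + (fit.params["d1"] - fit.params["d2"]) * fit.params["bp"])

    def test_flat_second_segment_holds_level(self):
        # zero-noise generator check: with d2 = 0 the curve stays at the bp level
        data = make_gradient("segmented", {"d1": 1.0, "d2": 0.0, "e1": 0.0, "bp": 1.0},
                             n=50, noise_sd=0.0, seed=1)
        right = data.x > 1.0
        assert np.allclose(data.y[right], 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_profile_beats_brute_force_grid(self, seed):
        x = np.sort(np.random.default_rng(seed).uniform(-2, 2, 30))
        y = np.where(x <= 0.3, 1.2 * x, 0.3 * 1.2 + 0.1 * (x - 0.3)) \
            + np.random.default_rng(seed + 100).normal(0, 0.3, 30)
        data = pb.GradientDataset(x, y)
        fit = pb.fit_segmented(data)
        rss = float(np.sum((y - fit.predict(x)) ** 2))
        assert rss <= brute_force_segmented_rss(x, y) + 1e-8

    def test_discontinuous_variant_has_free_intercepts(self):
        data = make_gradient("segmented", {"d1": 1.0, "d2": -0.5, "e1": 0.0, "bp": 0.0},
                             n=80, noise_sd=0.2, seed=7)
        cont = pb.fit_segmented(data, continuous=True)
        disc = pb.fit_segmented(data, continuous=False)
        assert cont.k == 5 and disc.k == 6
        assert disc.loglik >= cont.loglik - 1e-8  # extra parameter can only help

    def test_too_few_points_per_side(self):
        with pytest.raises(pb.models.InsufficientDataError):
            pb.fit_segmented(pb.GradientDataset(np.arange(6.0), np.arange(6.0)))

    def test_bootstrap_se_close_to_delta(self):
        data = make_gradient("segmented", {"d1": 1.0, "d2": 0.0, "e1": 0.0, "bp": 0.5},
                             n=150, noise_sd=0.3, seed=5)
        delta = pb.fit_segmented(data, se_method="delta")
        boot = pb.fit_segmented(data, se_method="bootstrap", n_boot=200, seed=9)
        assert delta.bp_se is not None and boot.bp_se is not None
        assert boot.bp_se == pytest.approx(delta.bp_se, rel=1.0)  # same order of magnitude


class TestLogistic:
    def test_noiseless_recovery(self):
        data = make_gradient("logistic", {"f": 0.0, "g": 10.0, "bp": 0.5, "h": 0.2},
                             n=100, noise_sd=0.0, seed=3)
        fit = pb.fit_logistic(data)
        assert fit.converged
        for name, true in (("f", 0.0), ("g", 10.0), ("bp", 0.5), ("h", 0.2)):
            assert fit.params[name] == pytest.approx(true, rel=1e-4, abs=1e-4)

    def test_midpoint_identity(self):
        # at x = bp the sigmoid equals (f + g) / 2, for the generator and the fit
        data = make_gradient("logistic", {"f": 1.0, "g": 5.0, "bp": 0.0, "h": 0.4},
                             n=120, noise_sd=0.05, seed=8)
        fit = pb.fit_logistic(data)
        bp = fit.params["bp"]
        mid = fit.predict(np.array([bp]))[0]
        assert mid == pytest.approx((fit.params["f"] + fit.params["g"]) / 2, abs=1e-9)

    def test_mirror_symmetry(self):
        # reflecting y about (f+g)/2 swaps the plateaus and flips h; RSS unchanged
        data = make_gradient("logistic", {"f": 0.0, "g": 4.0, "bp": 0.2, "h": 0.3},
                             n=150, noise_sd=0.2, seed=13)
        fit = pb.fit_logistic(data)
        mirrored = pb.GradientDataset(data.x, (fit.params["f"] + fit.params["g"]) - data.y)
        mfit = pb.fit_logistic(mirrored)
        assert mfit.rmse == pytest.approx(fit.rmse, abs=1e-6)
        assert mfit.params["f"] == pytest.approx(fit.params["g"], abs=1e-3)
        assert mfit.params["g"] == pytest.approx(fit.params["f"], abs=1e-3)
        assert mfit.params["bp"] == pytest.approx(fit.params["bp"], abs=1e-3)


class TestInformationCriteria:
    def test_aicc_arithmetic(self):
        assert pb.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_correction_vanishes_for_large_n(self):
        aic = -2 * (-5.0) + 2 * 2
        assert pb.aicc(-5.0, 2, 10**7) == pytest.approx(aic, abs=1e-5)

    def test_small_n_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert pb.aicc(0.0, 3, 4) == math.inf

    def test_zero_residual_rmse(self):
        assert pb.rmse(np.zeros(5)) == 0.0

    def test_gaussian_loglik_matches_scipy(self, rng):
        from scipy import stats
        r = rng.normal(0, 0.7, 50)
        assert pb.gaussian_loglik(r, 0.7) == pytest.approx(
            stats.norm.logpdf(r, scale=0.7).sum(), abs=1e-9)


class TestNesting:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_monotone_in_complexity(self, seed):
        data = make_gradient("segmented", {"d1": 1.0, "d2": 0.2, "e1": 0.0, "bp": 0.0},
                             n=80, noise_sd=0.4, seed=seed)
        null, lin, seg = pb.fit_null(data), pb.fit_linear(data), pb.fit_segmented(data)
        assert lin.loglik >= null.loglik - 1e-8
        assert seg.loglik >= lin.loglik - 1e-8

    def test_fits_are_deterministic(self):
        data = make_gradient("logistic", {"f": 0.0, "g": 3.0, "bp": 0.0, "h": 0.3},
                             n=100, noise_sd=0.3, seed=21)
        first, second = pb.fit_logistic(data), pb.fit_logistic(data)
        assert first.params == second.params
        assert first.aicc == second.aicc


class TestTransforms:
    def test_nonpositive_values_dropped_and_counted(self):
        data = pb.GradientDataset.from_raw(
            [0.1, 1.0, 10.0, -2.0], [5.0, 5.0, 0.0, 5.0],
            x_transform="log10", y_transform="log10")
        assert data.n == 2
        assert data.n_dropped == 2
        assert np.allclose(data.x, [-1.0, 0.0])
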