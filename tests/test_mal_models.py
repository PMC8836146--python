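"""MAL formulas, weighted fitting, and model comparison."""

import math

import numpy as np
import pytest

from menzerath.mal_models import (
    MODELS,
    DegreesOfFreedomError,
    FitResult,
    InvalidComparisonError,
    check_formula5_consistency,
    compare_models,
    eval_model,
    fit_nwls,
    residual_standard_error,
)
from menzerath.mal_models import test_b_equals_minus1 as wald_b_minus1
from menzerath.synthetic_data import simulate_bins


class TestEvalModel:
    def test_constant_power_law(self):
        assert eval_model(2, {"a": 1.0, "b": 0.0}, 17) == pytest.approx(1.0)

    def test_model2_with_b_minus1_equals_model3(self):
        x = np.arange(1.0, 143.0)
        y2 = eval_model(2, {"a": 9.3, "b": -1.0}, x)
        y3 = eval_model(3, {"a": 9.3}, x)
        np.testing.assert_allclose(y2, y3, rtol=1e-12)

    def test_minimal_length_form_worked_values(self):
        assert eval_model(4, {"a": 11.008, "d": 6.99}, 1) == pytest.approx(17.998)
        assert eval_model(4, {"a": 11.008, "d": 6.99}, 10_000) == pytest.approx(6.99, abs=0.01)

    def test_empirical_form_passes_consistency_gate(self):
        check_formula5_consistency()

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
    def test_jacobian_matches_central_differences(self, model_id):
        rng = np.random.default_rng(42)
        x = np.array([1.0, 2.0, 5.0, 17.0, 60.0, 142.0])
        spec = MODELS[model_id]
        for _ in range(5):
            theta = {
                "a": rng.uniform(5.0, 250.0),
                "b": rng.uniform(-1.2, 0.2),
                "c": rng.uniform(-0.01, 0.01),
                "d": rng.uniform(3.0, 50.0),
            }
            t = np.array([theta[n] for n in spec.param_names])
            J = spec.jacobian(t, x)
            for j in range(spec.n_params):
                h = 1e-6 * max(abs(t[j]), 1.0)
                tp, tm = t.copy(), t.copy()
                tp[j] += h
                tm[j] -= h
                fd = (spec.predict(tp, x) - spec.predict(tm, x)) / (2 * h)
                np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)


class TestFitNWLS:
    def test_noiseless_self_consistency(self):
        bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=30, sigma=1e-300, seed=0)
        fit = fit_nwls(4, bins, seed=0)
        assert fit.converged
        assert fit.estimates["a"] == pytest.approx(11.0, abs=1e-6)
        assert fit.estimates["d"] == pytest.approx(7.0, abs=1e-6)
        assert fit.s == pytest.approx(0.0, abs=1e-6)

    def test_model3_matches_closed_form(self):
        bins = simulate_bins(4, {"a": 9.0, "d": 5.0}, n_bins=40, sigma=1.0, seed=3)
        for weighted in (True, False):
            fit = fit_nwls(3, bins, weighted=weighted, seed=0)
            x = np.array([b.x for b in bins], dtype=float)
            y = np.array([b.y_bar for b in bins])
            w = np.array([b.weight for b in bins]) if weighted else np.ones_like(x)
            a_star = np.sum(w * y / x) / np.sum(w / x**2)
            assert fit.estimates["a"] == pytest.approx(a_star, abs=1e-8)

    def test_model2_matches_grid_search(self):
        bins = simulate_bins(2, {"a": 10.7, "b": -0.11}, n_bins=20, sigma=0.5, seed=4)
        fit = fit_nwls(2, bins, seed=0)
        x = np.array([b.x for b in bins], dtype=float)
        y = np.array([b.y_bar for b in bins])
        w = np.array([b.weight for b in bins])

        def sse(a, b):
            return float(np.sum(w * (y - a * x**b) ** 2))

        a_lo, a_hi, b_lo, b_hi = 5.0, 20.0, -0.6, 0.2
        best = None
        for _ in range(4):
            a_grid = np.linspace(a_lo, a_hi, 61)
            b_grid = np.linspace(b_lo, b_hi, 61)
            vals = [(sse(a, b), a, b) for a in a_grid for b in b_grid]
            _, a_best, b_best = min(vals)
            da, db = (a_hi - a_lo) / 60, (b_hi - b_lo) / 60
            a_lo, a_hi = a_best - 2 * da, a_best + 2 * da
            b_lo, b_hi = b_best - 2 * db, b_best + 2 * db
            best = (a_best, b_best)
        assert fit.estimates["a"] == pytest.approx(best[0], abs=1e-3)
        assert fit.estimates["b"] == pytest.approx(best[1], abs=1e-3)

    def test_nested_models_never_fit_worse(self):
        bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=50, sigma=2.0, seed=6)
        sse3 = fit_nwls(3, bins, seed=0).sse_weighted
        assert fit_nwls(2, bins, seed=0).sse_weighted <= sse3 + 1e-9
        assert fit_nwls(4, bins, seed=0).sse_weighted <= sse3 + 1e-9

    def test_weighting_irrelevant_when_weights_equal(self):
        # n chosen so every bin has the same n·x.
        bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=8, sigma=0.5, seed=7,
                             n_per_bin=[24 // x for x in range(1, 9)])
        weights = {b.weight for b in bins if 24 % b.x == 0}
        fw = fit_nwls(4, [b for b in bins if 24 % b.x == 0], weighted=True, seed=0)
        fu = fit_nwls(4, [b for b in bins if 24 % b.x == 0], weighted=False, seed=0)
        assert len(weights) == 1
        assert fw.estimates["a"] == pytest.approx(fu.estimates["a"], abs=1e-6)
        assert fw.estimates["d"] == pytest.approx(fu.estimates["d"], abs=1e-6)

    def test_standard_errors_shrink_with_replication(self):
        bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=40, sigma=2.0, seed=8)
        fit1 = fit_nwls(4, bins, seed=0)
        fit4 = fit_nwls(4, list(bins) * 4, seed=0)
        for name in ("a", "d"):
            ratio = fit4.std_errors[name] / fit1.std_errors[name]
            assert ratio == pytest.approx(0.5, rel=0.2)

    def test_too_few_bins_is_an_error(self):
        bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=2, sigma=0.1, seed=0)
        with pytest.raises(DegreesOfFreedomError):
            fit_nwls(4, bins, seed=0)


def _manual_fit(model_id, x, y, w, estimates, p):
    """Assemble a FitResult around given arrays without running the optimizer."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    theta = np.array([estimates[n] for n in MODELS[model_id].param_names])
    yhat = MODELS[model_id].predict(theta, x)
    resid = np.sqrt(w) * (y - yhat)
    sse = float(np.sum(resid**2))
    k = len(x)
    s = math.sqrt(sse / (k - p))
    return FitResult(
        model_id=model_id,
        estimates=dict(estimates),
        std_errors={n: 1.0 for n in estimates},
        covariance=np.eye(p),
        k=k,
        p=p,
        s=s,
        aic=0.0,
        log_likelihood=0.0,
        weighted=True,
        converged=True,
        n_iterations=1,
        sse_weighted=sse,
        x=x,
        y=y,
        w=w,
        predicted=yhat,
        residuals=resid,
    )


class TestResidualStandardError:
    def test_hand_case_two_bins_unit_weights(self):
        # model 3 with a = 2: predictions (2, 1); observations chosen for residuals (1, -1)
        fit = _manual_fit(3, [1, 2], [3.0, 0.0], [1.0, 1.0], {"a": 2.0}, p=1)
        assert residual_standard_error(fit) == pytest.approx(math.sqrt(2.0))

    def test_halving_weights_scales_s(self):
        fit_full = _manual_fit(3, [1, 2, 4], [3.0, 0.5, 1.0], [4.0, 2.0, 8.0], {"a": 2.0}, p=1)
        fit_half = _manual_fit(3, [1, 2, 4], [3.0, 0.5, 1.0], [2.0, 1.0, 4.0], {"a": 2.0}, p=1)
        assert fit_half.s == pytest.approx(fit_full.s / math.sqrt(2.0))

    def test_perfect_fit_gives_zero(self):
        fit = _manual_fit(3, [1, 2, 4], [2.0, 1.0, 0.5], [1.0, 1.0, 1.0], {"a": 2.0}, p=1)
        assert residual_standard_error(fit) == 0.0

    def test_insufficient_dof(self):
        fit = _manual_fit(3, [1, 2], [3.0, 0.0], [1.0, 1.0], {"a": 2.0}, p=1)
        fit.p = 2
        with pytest.raises(DegreesOfFreedomError):
            residual_standard_error(fit)


class TestAIC:
    def test_useless_parameter_costs_about_two(self):
        bins = simulate_bins(3, {"a": 75.238}, n_bins=60, sigma=0.05, seed=9)
        aic3 = fit_nwls(3, bins, seed=0).aic
        aic4 = fit_nwls(4, bins, seed=0).aic
        assert 0.0 < aic4 - aic3 <= 2.5

    def test_generating_model_preferred_over_nested_rival(self):
        wins = 0
        for rep in range(50):
            bins = simulate_bins(4, {"a": 11.0, "d": 7.0}, n_bins=60, sigma=2.0, seed=100 + rep)
            if fit_nwls(4, bins, seed=0, n_restarts=2).aic < fit_nwls(3, bins, seed=0, n_restarts=2).aic:
                wins += 1
        assert wins >= 48


class TestWaldB:
    def test_exact_minus_one_gives_zero(self):
        fit = _manual_fit(2, [1, 2, 3], [2.0, 1.0, 2 / 3], [1.0] * 3, {"a": 2.0, "b": -1.0}, p=2)
        fit.std_errors["b"] = 0.05
        res = wald_b_minus1(fit)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_published_style_estimate_rejects(self):
        fit = _manual_fit(2, [1, 2, 3], [2.0, 1.0, 2 / 3], [1.0] * 3, {"a": 2.0, "b": -0.108}, p=2)
        fit.std_errors["b"] = 0.007
        res = wald_b_minus1(fit)
        assert abs(res.z) == pytest.approx(127.43, rel=1e-3)
        assert res.p_value < 1e-300

    def test_type_one_error_rate_near_nominal(self):
        rejections = 0
        n_reps = 100
        for rep in range(n_reps):
            bins = simulate_bins(3, {"a": 75.238}, n_bins=100, sigma=1.0, seed=500 + rep)
            fit = fit_nwls(2, bins, seed=0, n_restarts=2)
            if wald_b_minus1(fit).p_value < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.12

    def test_missing_standard_error(self):
        fit = _manual_fit(3, [1, 2, 3], [2.0, 1.0, 2 / 3], [1.0] * 3, {"a": 2.0}, p=1)
        with pytest.raises(ValueError):
            wald_b_minus1(fit)


class TestCompareModels:
    def _fits_with_s(self, s_by_model, weighted=True):
        fits = []
        for model_id, s in s_by_model.items():
            spec = MODELS[model_id]
            est = {n: 1.0 for n in spec.param_names}
            f = _manual_fit(model_id, [1, 2, 3, 4, 5], [2.0, 1.0, 0.7, 0.5, 0.4],
                            [1.0] * 5, est, p=spec.n_params)
            f.s = s
            f.aic = s  # mirror ordering
            f.weighted = weighted
            fits.append(f)
        return fits

    def test_published_s_ordering_worst_to_best(self):
        fits = self._fits_with_s({1: 10.072, 2: 11.679, 3: 162.313, 4: 8.763, 5: 8.135})
        ranking = compare_models(fits)
        assert ranking.by_s == (3, 2, 1, 4, 5)
        assert ranking.by_aic == (3, 2, 1, 4, 5)

    def test_ties_preserved_in_model_order(self):
        fits = self._fits_with_s({2: 5.0, 4: 5.0})
        assert compare_models(fits).by_s == (2, 4)

    def test_mixed_weighting_rejected(self):
        fits = self._fits_with_s({2: 5.0})
        fits += self._fits_with_s({4: 4.0}, weighted=False)
        with pytest.raises(InvalidComparisonError):
            compare_models(fits)
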