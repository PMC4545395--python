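"""Latent-truth model: likelihood oracle, figure of merit, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cardiofuse.erwt import (
    ErwtModel,
    figure_of_merit,
    fit_erwt,
    marginal_loglik,
    rescale_to_unit,
    tune_beta_shape,
    unrescale_from_unit,
    _moment_start,
)
from cardiofuse.synthetic import simulate_estimates, simulate_true_values
from cardiofuse.types import BetaShape, MethodProfile


def loglik_dense_grid_oracle(theta, a, b, sigma, mu, nu, n_grid=100_000):
    """Brute-force trapezoid integration of the marginal likelihood."""
    t = np.linspace(0.0, 1.0, n_grid)
    prior = stats.beta.pdf(t, mu, nu)
    total = 0.0
    for p in range(theta.shape[0]):
        like = prior.copy()
        for k in range(theta.shape[1]):
            like = like * stats.norm.pdf(theta[p, k], a[k] * t + b[k], sigma[k])
        total += np.log(np.trapezoid(like, t))
    return total


class TestRescale:
    def test_identity_for_unit_range(self):
        v = np.array([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(rescale_to_unit(v, (0, 1)), v)

    def test_endpoints_and_roundtrip(self):
        assert rescale_to_unit(np.array([30.0]), (30, 300))[0] == 0.0
        assert rescale_to_unit(np.array([300.0]), (30, 300))[0] == 1.0
        v = np.array([42.0, 130.5, 299.9])
        back = unrescale_from_unit(rescale_to_unit(v, (30, 300)), (30, 300))
        np.testing.assert_allclose(back, v, atol=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_unit(np.array([1.0]), (5, 5))


class TestMarginalLoglik:
    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(0)
        theta = np.clip(rng.normal(0.5, 0.15, size=(4, 2)), 0.05, 0.95)
        a = np.array([1.0, 0.9])
        b = np.array([0.0, 0.05])
        sigma = np.array([0.05, 0.08])
        ours = marginal_loglik(theta, a, b, sigma, BetaShape(2.85, 3.40))
        oracle = loglik_dense_grid_oracle(theta, a, b, sigma, 2.85, 3.40)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            marginal_loglik(np.array([[0.5]]), [1.0], [0.0], [0.0], BetaShape(2, 3))

    def test_value_at_model_mean_beats_outlier(self):
        shape = BetaShape(2.85, 3.40)
        mean = shape.mean
        near = marginal_loglik(np.array([[mean]]), [1.0], [0.0], [0.03], shape)
        far = marginal_loglik(np.array([[mean + 3 * 0.03]]), [1.0], [0.0], [0.03], shape)
        assert near > far

    def test_large_sigma_flattens_likelihood(self):
        shape = BetaShape(4, 5)
        theta = np.array([[0.2], [0.5], [0.8]])
        lls = [marginal_loglik(theta, [1.0], [0.0], [s], shape) for s in (0.1, 0.3, 0.5)]
        spread = [marginal_loglik(theta[:1], [1.0], [0.0], [s], shape)
                  - marginal_loglik(theta[1:2], [1.0], [0.0], [s], shape)
                  for s in (0.1, 0.3, 0.5)]
        # the per-subject contrast between a central and an off-center value
        # shrinks monotonically as sigma grows
        assert abs(spread[0]) > abs(spread[1]) > abs(spread[2])

    def test_missing_cells_rejected(self):
        theta = np.array([[0.5, np.nan]])
        with pytest.raises(ValueError):
            marginal_loglik(theta, [1, 1], [0, 0], [0.1, 0.1], BetaShape(2, 3))


class TestFigureOfMerit:
    def test_perfect_method_scores_zero(self):
        assert figure_of_merit(1.0, 0.0, 0.0, BetaShape(4, 5)) == 0.0

    def test_pure_noise_reduces_to_sigma_squared(self):
        assert figure_of_merit(1.0, 0.0, 0.1, BetaShape(4, 5)) == pytest.approx(0.01)

    def test_matches_monte_carlo_expected_square_error(self):
        shape = BetaShape(2.85, 3.40)
        a, b, s = 0.9, 0.05, 0.0
        rng = np.random.default_rng(42)
        th = rng.beta(shape.mu, shape.nu, size=1_000_000)
        err2 = (th - a * th - b) ** 2
        mc, se = err2.mean(), err2.std(ddof=1) / np.sqrt(err2.size)
        assert figure_of_merit(a, b, s, shape) == pytest.approx(mc, abs=3 * se)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.3, 1.8),
        b=st.floats(-0.3, 0.3),
        s=st.floats(0.0, 0.3),
        mu=st.floats(0.5, 8.0),
        nu=st.floats(0.5, 8.0),
    )
    def test_nonnegative_and_data_independent(self, a, b, s, mu, nu):
        shape = BetaShape(mu, nu)
        f1 = figure_of_merit(a, b, s, shape)
        f2 = figure_of_merit(a, b, s, shape)
        assert f1 >= -1e-15
        assert f1 == f2  # pure function of (a, b, sigma, mu, nu)


class TestFit:
    def test_near_noiseless_identity_recovery(self):
        t = simulate_true_values(200, BetaShape(2.85, 3.40), seed=1)
        m = simulate_estimates(
            t, [MethodProfile(1, 0, 0.005, f"M{k}") for k in range(3)], seed=2)
        fit = fit_erwt(m, multistart=2)
        assert np.all((fit.a >= 0.95) & (fit.a <= 1.05))
        assert np.all(np.abs(fit.b) <= 0.02)

    def test_column_permutation_permutes_parameters(self):
        t = simulate_true_values(120, BetaShape(2.85, 3.40), seed=3)
        m = simulate_estimates(
            t, [MethodProfile(0.9, 0.05, 0.03, "A"), MethodProfile(1.1, -0.02, 0.05, "B")],
            seed=4)
        f1 = fit_erwt(m, multistart=2)
        f2 = fit_erwt(m[["B", "A"]], multistart=2)
        np.testing.assert_allclose(f1.a, f2.a[::-1], atol=1e-4)
        np.testing.assert_allclose(f1.sigma, f2.sigma[::-1], atol=1e-4)

    def test_fitted_loglik_beats_moment_start(self):
        t = simulate_true_values(100, BetaShape(2.85, 3.40), seed=5)
        m = simulate_estimates(
            t, [MethodProfile(0.95, 0.02, 0.04, "A"), MethodProfile(1.0, 0.0, 0.06, "B")],
            seed=6)
        fit = fit_erwt(m, multistart=2)
        x0 = _moment_start(m.to_numpy())
        K = 2
        ll0 = marginal_loglik(m, x0[:K], x0[K:2 * K], np.exp(x0[2 * K:]),
                              BetaShape(2.85, 3.40))
        assert fit.loglik >= ll0 - 1e-8

    def test_estimator_interface(self):
        t = simulate_true_values(80, BetaShape(2.85, 3.40), seed=7)
        m = simulate_estimates(
            t, [MethodProfile(1, 0, 0.03, "A"), MethodProfile(1, 0, 0.08, "B")], seed=8)
        model = ErwtModel(multistart=2, seed=0).fit(m)
        assert model.methods_ == ["A", "B"]
        assert model.noise_sd_[0] < model.noise_sd_[1]
        assert model.fom_[0] < model.fom_[1]
        assert np.isfinite(model.score(m))
        clone = ErwtModel(**model.get_params())
        assert clone.get_params() == model.get_params()
        with pytest.raises(ValueError):
            model.set_params(nonsense=1)

    def test_incomplete_matrix_rejected(self):
        m = pd.DataFrame({"A": [0.5, np.nan], "B": [0.4, 0.6]})
        with pytest.raises(ValueError):
            fit_erwt(m)


class TestShapeTuning:
    @pytest.mark.parametrize("shape", [BetaShape(4, 5), BetaShape(2.85, 3.40)])
    def test_identity_raters_objective_reduces_to_noise(self, shape):
        # identity raters observed under the fitted latent shape: the fit
        # returns a ~ 1, b ~ 0, so the summed FoM collapses to sum sigma_k^2
        # (a misspecified latent shape instead bleeds into the slope)
        t = simulate_true_values(500, shape, seed=9)
        m = simulate_estimates(
            t, [MethodProfile(1, 0, 0.02, "A"), MethodProfile(1, 0, 0.02, "B"),
                MethodProfile(1, 0, 0.02, "C")], seed=10)
        fit = fit_erwt(m, shape=shape, multistart=1)
        assert fit.fom.sum() == pytest.approx(3 * 0.02**2, rel=0.15)

    def test_tuning_improves_on_initial_shape(self):
        t = simulate_true_values(150, BetaShape(3.0, 3.5), seed=11)
        m = simulate_estimates(
            t, [MethodProfile(0.95, 0.03, 0.03, "A"), MethodProfile(1.05, -0.02, 0.05, "B"),
                MethodProfile(1.0, 0.0, 0.04, "C")], seed=12)
        tuned, diag = tune_beta_shape(m, BetaShape(4, 5), multistart=1)
        start_fit = fit_erwt(m, shape=BetaShape(4, 5), multistart=1)
        assert diag["sum_fom"] <= start_fit.fom.sum() + 1e-9

    def test_tuning_deterministic_under_seed(self):
        t = simulate_true_values(80, BetaShape(3.0, 3.5), seed=13)
        m = simulate_estimates(
            t, [MethodProfile(1, 0, 0.04, "A"), MethodProfile(1, 0, 0.06, "B")], seed=14)
        t1, d1 = tune_beta_shape(m, BetaShape(4, 5), multistart=1, seed=3)
        t2, d2 = tune_beta_shape(m, BetaShape(4, 5), multistart=1, seed=3)
        assert (t1.mu, t1.nu) == (t2.mu, t2.nu)
        assert d1["sum_fom"] == d2["sum_fom"]
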