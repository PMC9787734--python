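"""Adapter contracts and diagnostics for the four model families."""

import numpy as np
import pytest

from qsarval import (
    SingularDesignError,
    UnderdeterminedError,
    ann_hidden_for_budget,
    ann_spec,
    default_grid,
    fit_ann,
    fit_mlr,
    fit_pls2,
    fit_svr,
    goodness_of_fit,
    pls2_spec,
    svr_spec,
)
from qsarval.models import ann_n_params


def normal_equations_predictions(X, y, Xnew):
    """Independent OLS oracle via the normal equations."""
    D = np.column_stack([np.ones(len(X)), X])
    coef = np.linalg.solve(D.T @ D, D.T @ y)
    return np.column_stack([np.ones(len(Xnew)), Xnew]) @ coef


class TestMLR:
    def test_recovers_exact_linear_data(self, rng):
        X = rng.standard_normal((30, 2))
        y = 2 * X[:, 0] - X[:, 1] + 3
        fm = fit_mlr(X, y)
        np.testing.assert_allclose(fm.diagnostics["coef"], [2, -1], atol=1e-10)
        assert fm.diagnostics["intercept"] == pytest.approx(3, abs=1e-10)
        assert goodness_of_fit(y, fm.predict(X)).r2 == pytest.approx(1.0)
        assert fm.p_params == 2

    def test_no_predictors_rejected(self):
        with pytest.raises(ValueError):
            fit_mlr(np.empty((10, 0)), np.arange(10.0))

    def test_rank_deficiency_and_underdetermination(self, rng):
        X = rng.standard_normal((20, 2))
        Xdup = np.column_stack([X, X[:, 0]])
        with pytest.raises(SingularDesignError):
            fit_mlr(Xdup, rng.standard_normal(20))
        with pytest.raises(UnderdeterminedError):
            fit_mlr(rng.standard_normal((4, 3)), rng.standard_normal(4))

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((30, 4))
        y = X @ rng.normal(size=4) + rng.standard_normal(30)
        Xnew = rng.standard_normal((10, 4))
        fm = fit_mlr(X, y)
        np.testing.assert_allclose(
            fm.predict(Xnew), normal_equations_predictions(X, y, Xnew), atol=1e-8
        )

    def test_training_r2_never_decreases_with_added_predictor(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, 0.5, -1.0] + rng.standard_normal(40)
        r2_small = goodness_of_fit(y, fit_mlr(X[:, :2], y).predict(X[:, :2])).r2
        r2_full = goodness_of_fit(y, fit_mlr(X, y).predict(X)).r2
        assert r2_full >= r2_small - 1e-12


def brute_force_one_component_pls(X, y, Xnew):
    """One latent pair by direct covariance maximization: w ∝ X'y."""
    Xc, yc = X - X.mean(0), y - y.mean()
    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    t = Xc @ w
    b = (t @ yc) / (t @ t)
    return y.mean() + ((Xnew - X.mean(0)) @ w) * b


class TestPLS2:
    def test_full_rank_limit_equals_ols(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ rng.normal(size=4) + rng.standard_normal(50)
        fp = fit_pls2(X, y, pls2_spec(n_latent=4))
        np.testing.assert_allclose(
            fp.predict(X), normal_equations_predictions(X, y, X), atol=1e-6
        )
        assert fp.diagnostics["n_latent"] == 4

    def test_one_component_sufficiency(self, rng):
        # y proportional to one predictor; the rest is independent noise
        n = 200
        x1 = rng.standard_normal(n)
        X = np.column_stack([x1, rng.standard_normal((n, 3))])
        y = 2.0 * x1
        fp = fit_pls2(X, y, pls2_spec(n_latent=1, standardize=True))
        r2 = goodness_of_fit(y, fp.predict(X)).r2
        assert r2 > 0.99
        # cross-check against the brute-force covariance maximizer
        oracle = brute_force_one_component_pls(X, y, X)
        fp_raw = fit_pls2(X, y, pls2_spec(n_latent=1, standardize=False))
        np.testing.assert_allclose(fp_raw.predict(X), oracle, atol=1e-8)

    def test_standardization_matters_only_for_unequal_scales(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ [1.0, -1.0, 0.5] + rng.standard_normal(60)
        on = fit_pls2(X, y, pls2_spec(2, standardize=True)).predict(X)
        off = fit_pls2(X, y, pls2_spec(2, standardize=False)).predict(X)
        Xs = (X - X.mean(0)) / X.std(0)
        on_s = fit_pls2(Xs, y, pls2_spec(2, standardize=True)).predict(Xs)
        off_s = fit_pls2(Xs, y, pls2_spec(2, standardize=False)).predict(Xs)
        Xu = X * np.array([1.0, 100.0, 0.01])
        on_u = fit_pls2(Xu, y, pls2_spec(2, standardize=True)).predict(Xu)
        off_u = fit_pls2(Xu, y, pls2_spec(2, standardize=False)).predict(Xu)
        np.testing.assert_allclose(on_s, off_s, atol=1e-8)  # pre-standardized
        assert np.abs(on_u - off_u).max() > 1e-3  # unequal scales differ
        del on, off

    def test_training_rss_non_increasing_in_n_latent(self, rng):
        X = rng.standard_normal((60, 5))
        Y = np.column_stack([
            X @ rng.normal(size=5) + rng.standard_normal(60) for _ in range(2)
        ])
        rss = []
        for k in range(1, 6):
            fp = fit_pls2(X, Y, pls2_spec(k))
            rss.append(np.sum((Y - fp.predict(X)) ** 2))
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_excessive_n_latent_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            fit_pls2(X, rng.standard_normal(20), pls2_spec(n_latent=4))


class TestANN:
    def test_hidden_size_budget_rule(self):
        # p=5, n=30: H=4 gives (5+1)*4 + 5 = 29 weights <= 30 cases
        assert ann_hidden_for_budget(5, 30) == 4
        assert ann_n_params(5, 4) == 29

    def test_deterministic_given_rng(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.sin(X[:, 0]) + rng.standard_normal(50) * 0.1
        spec = ann_spec(n_hidden=3, max_iter=200)
        p1 = fit_ann(X, y, spec, np.random.default_rng(7)).predict(X)
        p2 = fit_ann(X, y, spec, np.random.default_rng(7)).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_learns_smooth_nonlinear_target(self, rng):
        n = 400
        X = rng.standard_normal((n, 5))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        best = -np.inf
        for spec in default_grid("ann", p=5, n_min=n):
            fm = fit_ann(X, y, spec, np.random.default_rng(0))
            best = max(best, goodness_of_fit(y, fm.predict(X)).r2)
            if best > 0.95:
                break
        assert best > 0.95

    def test_nan_inputs_rejected(self):
        X = np.ones((20, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_ann(X, np.ones(20), ann_spec(2), np.random.default_rng(0))


class TestSVR:
    def test_wide_tube_swallows_all_data(self, rng):
        X = rng.standard_normal((40, 3))
        y = X[:, 0] + rng.standard_normal(40) * 0.1
        # epsilon far beyond the (standardized) response range
        fm = fit_svr(X, y, svr_spec(epsilon=50.0))
        assert fm.diagnostics["n_support_vectors"] <= 1
        assert np.ptp(fm.predict(X)) == pytest.approx(0.0, abs=1e-8)

    def test_small_epsilon_makes_every_case_a_support_vector(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        fm = fit_svr(X, y, svr_spec(epsilon=1e-6))
        assert fm.diagnostics["n_support_vectors"] >= 38

    def test_sv_fraction_non_increasing_in_epsilon(self, rng):
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.standard_normal(60)
        fractions = [
            fit_svr(X, y, svr_spec(epsilon=e)).diagnostics["sv_fraction"]
            for e in (0.01, 0.1, 0.5, 1.0, 2.0)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_deterministic(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        a = fit_svr(X, y, svr_spec())
        b = fit_svr(X, y, svr_spec())
        assert a.diagnostics["n_support_vectors"] == b.diagnostics["n_support_vectors"]
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            svr_spec(C=-1.0)
        with pytest.raises(ValueError):
            svr_spec(gamma=0.0)


def test_grids_stay_reduced():
    for family in ("mlr", "pls2", "ann", "svr"):
        assert 1 <= len(default_grid(family)) <= 25
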