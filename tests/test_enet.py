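"""Elastic net: coordinate descent vs closed forms, KKT certificates,
independent solvers, and the random grid search."""

import dataclasses

import numpy as np
import pytest

from milkpred.enet import (
    ElasticNet,
    EnetError,
    fit_coordinate_descent,
    glmnet_to_printed,
    kkt_check,
    tune_random_grid,
    _objective,
)


def _data(n=50, p=20, k=5, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k] = rng.normal(size=k) * 2
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def _standardized(X, y):
    return (X - X.mean(0)) / X.std(0), y - y.mean()


def fista_oracle(Xs, yc, alpha, lam, iters=100_000, tol=1e-14):
    """Independent first-order minimiser of the same objective."""
    n, p = Xs.shape
    L = 2 * np.linalg.norm(Xs, 2) ** 2 + 2 * lam * (1 - alpha)
    b = np.zeros(p)
    z, t = b.copy(), 1.0
    prev = np.inf
    for k in range(iters):
        g = -2 * Xs.T @ (yc - Xs @ z) + 2 * lam * (1 - alpha) * z
        w = z - g / L
        b_new = np.sign(w) * np.maximum(np.abs(w) - lam * alpha / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = b_new + ((t - 1) / t_new) * (b_new - b)
        b, t = b_new, t_new
        if k % 200 == 0:
            obj = _objective(Xs, yc, b, alpha, lam)
            if abs(prev - obj) < tol * max(obj, 1.0):
                break
            prev = obj
    return b


class TestLimits:
    def test_lambda_zero_matches_ols(self):
        X, y = _data()
        res = fit_coordinate_descent(X, y, alpha=0.7, lam=0.0, tol=1e-12)
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)[0]
        assert np.abs(res.params - ols[1:]).max() < 1e-8
        assert abs(res.intercept - ols[0]) < 1e-8

    def test_alpha_zero_matches_closed_form_ridge(self):
        X, y = _data(seed=1)
        lam = 3.7
        res = fit_coordinate_descent(X, y, alpha=0.0, lam=lam, tol=1e-12)
        Xs, yc = _standardized(X, y)
        ridge = np.linalg.solve(Xs.T @ Xs + lam * np.eye(X.shape[1]), Xs.T @ yc)
        assert np.abs(res.beta_std - ridge).max() < 1e-8

    def test_lasso_null_threshold(self):
        X, y = _data(seed=2)
        Xs, yc = _standardized(X, y)
        lam = 2 * np.abs(Xs.T @ yc).max() * (1 + 1e-10)
        res = fit_coordinate_descent(X, y, alpha=1.0, lam=lam)
        assert np.abs(res.beta_std).max() == 0.0


class TestKkt:
    def test_converged_fit_certified(self):
        X, y = _data(seed=3)
        res = fit_coordinate_descent(X, y, alpha=0.6, lam=5.0, tol=1e-12)
        assert res.kkt_violation() < 1e-6

    def test_perturbed_solution_detected(self):
        X, y = _data(seed=4)
        res = fit_coordinate_descent(X, y, alpha=0.6, lam=5.0, tol=1e-12)
        bad = dataclasses.replace(res, beta_std=res.beta_std + 0.05)
        assert kkt_check(bad, X, y) > 1e-2

    def test_lambda_zero_reduces_to_normal_equations(self):
        X, y = _data(seed=5)
        res = fit_coordinate_descent(X, y, alpha=1.0, lam=0.0, tol=1e-12)
        Xs, yc = _standardized(X, y)
        grad = -2 * Xs.T @ (yc - Xs @ res.beta_std)
        assert np.abs(grad).max() == pytest.approx(res.kkt_violation(), abs=1e-12)


class TestAgainstIndependentSolvers:
    @pytest.mark.parametrize("seed,alpha,lam", [(0, 1.0, 20.0), (1, 0.4, 8.0),
                                                (2, 0.0, 3.0), (3, 0.8, 60.0)])
    def test_objective_matches_fista(self, seed, alpha, lam):
        X, y = _data(seed=seed)
        res = fit_coordinate_descent(X, y, alpha=alpha, lam=lam, tol=1e-12)
        Xs, yc = _standardized(X, y)
        b_oracle = fista_oracle(Xs, yc, alpha, lam)
        o_cd = _objective(Xs, yc, res.beta_std, alpha, lam)
        o_or = _objective(Xs, yc, b_oracle, alpha, lam)
        assert abs(o_cd - o_or) / max(abs(o_or), 1.0) < 1e-6

    def test_matches_sklearn_elasticnet(self):
        # sklearn minimises RSS/(2n) + a*l1*|b|_1 + a*(1-l1)/2*|b|_2^2;
        # times 2n that is the unscaled objective with lam*alpha = 2n*a*l1
        # and lam*(1-alpha) = n*a*(1-l1)
        from sklearn.linear_model import ElasticNet as SkEnet

        X, y = _data(seed=6)
        n, p = X.shape
        Xs, yc = _standardized(X, y)
        a_sk, l1 = 0.3, 0.6
        lam_l1 = 2 * n * a_sk * l1
        lam_l2 = n * a_sk * (1 - l1)
        lam = lam_l1 + lam_l2
        alpha = lam_l1 / lam
        res = fit_coordinate_descent(Xs, yc, alpha=alpha, lam=lam, tol=1e-12)
        sk = SkEnet(alpha=a_sk, l1_ratio=l1, fit_intercept=False, tol=1e-12,
                    max_iter=100_000).fit(Xs, yc)
        # our fit re-standardises internally; compare on the original scale
        assert np.abs(res.params - sk.coef_).max() < 1e-6

    def test_glmnet_conversion_roundtrip_shapes(self):
        a, l = glmnet_to_printed(0.5, 0.2, 100)
        assert l == pytest.approx(100 * 0.2 * 1.5)
        assert a == pytest.approx(2 * 0.5 / 1.5)
        assert glmnet_to_printed(0.0, 0.0, 50) == (0.0, 0.0)


class TestProperties:
    def test_monotone_l1_shrinkage_in_lambda(self):
        X, y = _data(seed=7)
        norms = []
        for lam in [0.0, 5.0, 20.0, 60.0, 200.0]:
            res = fit_coordinate_descent(X, y, alpha=1.0, lam=lam, tol=1e-10)
            norms.append(np.abs(res.beta_std).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_warm_start_independence(self):
        X, y = _data(seed=8)
        cold = fit_coordinate_descent(X, y, alpha=0.5, lam=10.0, tol=1e-12)
        other = fit_coordinate_descent(X, y, alpha=1.0, lam=50.0, tol=1e-12)
        warm = fit_coordinate_descent(X, y, alpha=0.5, lam=10.0, tol=1e-12,
                                      start=other.beta_std)
        assert abs(cold.objective - warm.objective) < 1e-9

    def test_zero_variance_column_dropped(self):
        X, y = _data(seed=9)
        X[:, 3] = 2.5
        with pytest.warns(UserWarning):
            res = fit_coordinate_descent(X, y, alpha=0.5, lam=1.0)
        assert res.params[3] == 0.0

    def test_nonfinite_rejected(self):
        X, y = _data(seed=10)
        X[0, 0] = np.nan
        with pytest.raises(EnetError):
            ElasticNet(y, X)


class TestPredict:
    def test_training_predictions_match_ols(self):
        X, y = _data(seed=11)
        res = fit_coordinate_descent(X, y, alpha=0.3, lam=0.0, tol=1e-12)
        Xc = np.column_stack([np.ones(len(y)), X])
        fitted = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(res.predict(X), fitted, atol=1e-7)

    def test_null_model_predicts_intercept(self):
        X, y = _data(seed=12)
        Xs, yc = _standardized(X, y)
        lam = 2 * np.abs(Xs.T @ yc).max() * 1.01
        res = fit_coordinate_descent(X, y, alpha=1.0, lam=lam)
        np.testing.assert_allclose(res.predict(X), np.full(len(y), y.mean()))

    def test_affine_rescaling_invariance(self):
        X, y = _data(seed=13)
        scale = np.linspace(0.5, 3.0, X.shape[1])
        shift = np.linspace(-2, 2, X.shape[1])
        res1 = fit_coordinate_descent(X, y, alpha=0.4, lam=2.0, tol=1e-12)
        res2 = fit_coordinate_descent(X * scale + shift, y, alpha=0.4, lam=2.0,
                                      tol=1e-12)
        Xnew = np.random.default_rng(14).normal(size=(7, X.shape[1]))
        np.testing.assert_allclose(
            res1.predict(Xnew), res2.predict(Xnew * scale + shift), atol=1e-6
        )

    def test_column_mismatch_raises(self):
        X, y = _data(seed=15)
        res = fit_coordinate_descent(X, y, alpha=0.5, lam=1.0)
        with pytest.raises(EnetError):
            res.predict(X[:, :-1])


class TestTuning:
    def test_singleton_candidate_chosen(self):
        X, y = _data(seed=16)
        t = tune_random_grid(X, y, n_candidates=1, seed=0)
        assert (t.alpha, t.lam) == (t.grid["alpha"].iloc[0], t.grid["lambda"].iloc[0])
        assert len(t.grid) == 1

    def test_split_is_80_20_and_seeded(self):
        X, y = _data(n=100, seed=17)
        t1 = tune_random_grid(X, y, n_candidates=3, seed=5)
        t2 = tune_random_grid(X, y, n_candidates=3, seed=5)
        assert len(t1.train_idx) == 80 and len(t1.tune_idx) == 20
        np.testing.assert_array_equal(t1.train_idx, t2.train_idx)
        assert (t1.alpha, t1.lam) == (t2.alpha, t2.lam)

    def test_pure_noise_tuning_correlation_not_positive(self):
        # winner's tuning-split correlation over 20 seeds: mean not
        # significantly above zero
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 10))
            y = rng.normal(size=40)
            t = tune_random_grid(X, y, n_candidates=10, seed=seed)
            row = t.grid[(t.grid["alpha"] == t.alpha) & (t.grid["lambda"] == t.lam)]
            r = float(row["r"].iloc[0])
            if np.isfinite(r):
                rs.append(r)
        tstat = np.mean(rs) / (np.std(rs, ddof=1) / np.sqrt(len(rs)))
        assert tstat < 2.0

    def test_signal_gives_sparser_model_without_worse_tuning_mse(self):
        rng = np.random.default_rng(18)
        n, p = 60, 50
        X = rng.normal(size=(n, p))
        y = X[:, :5] @ np.array([3.0, -2.0, 2.5, -3.0, 2.0]) + 0.5 * rng.normal(size=n)
        t = tune_random_grid(X, y, seed=1, parameterization="glmnet")
        lam0 = t.grid[t.grid["lambda"] == 0.0]["mse"].min()
        assert t.lam * t.alpha > 0  # some L1 was preferred
        assert np.count_nonzero(t.results.params) < p
        best = t.grid[(t.grid["alpha"] == t.alpha) & (t.grid["lambda"] == t.lam)]
        assert float(best["mse"].iloc[0]) <= lam0 + 1e-12

    def test_too_few_rows(self):
        X, y = _data(n=5, p=2, k=2)
        with pytest.raises(EnetError):
            tune_random_grid(X, y)
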