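"""SIMPLS regression, VIP scores, Q2Y, ensembles, time-resolved variant."""

import warnings

import numpy as np
import pandas as pd
import pytest

from betacell.plsr import (
    FluxInsulinPLS,
    fit_ensemble,
    predict_insulin,
    q2y_loo,
    simpls_fit,
    timecourse_plsr,
    vip_scores,
)


def _brute_force_pls1(X, y, n_components):
    """Deflation-free PLS1 oracle built from the cross-covariance vector.

    Components are extracted by explicit X-deflation (classical PLS1);
    for a single response this spans the same Krylov subspace as SIMPLS,
    so training predictions and coefficients must agree.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    mean, std = X.mean(0), X.std(0, ddof=1)
    Xk = (X - mean) / std
    y0 = y - y.mean()
    n, p = Xk.shape
    W, P, Q, T = [], [], [], []
    Xd = Xk.copy()
    yd = y0.copy()
    for _ in range(n_components):
        w = Xd.T @ yd
        w /= np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W.append(w); P.append(pvec); Q.append(q); T.append(t)
    W, P = np.array(W).T, np.array(P).T
    beta = W @ np.linalg.solve(P.T @ W, np.array(Q))
    return beta, mean, std, y.mean()


class TestSIMPLS:
    def test_exact_linear_relation_r2_one(self):
        # centered orthogonal columns: the exact relation is captured
        # within the requested two components (with a truncation warning
        # if the response is exhausted earlier)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 4))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = Q
        y = 2.0 * X[:, 0] - 1.0 * X[:, 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = simpls_fit(X, y, 2)
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(fit.predict(X), y, atol=1e-6)

    def test_one_component_matches_rank1_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        fit = simpls_fit(X, y, 1)
        beta, mean, std, ymean = _brute_force_pls1(X, y, 1)
        assert np.allclose(fit.coef_std, beta, atol=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_simpls_matches_pls1_oracle_on_random_tables(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n = rng.integers(5, 9)
        p = rng.integers(3, 7)
        ncomp = int(min(n - 2, p, rng.integers(1, 4)))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = simpls_fit(X, y, ncomp)
        beta, *_ = _brute_force_pls1(X, y, ncomp)
        assert np.allclose(fit.coef_std, beta, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        fit = simpls_fit(X, y, 3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(fit.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=5)
        fit = simpls_fit(X, y, 4)  # rows - 1 components
        Xs = np.column_stack([np.ones(5), X])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        assert np.allclose(fit.predict(X), Xs @ beta, atol=1e-6)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        X[:, 1] = 4.2
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = simpls_fit(X, y, 2)
        assert fit.coef_std[1] == 0.0
        assert vip_scores(fit)[1] == 0.0

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(1).normal(size=(4, 6))
        with pytest.raises(ValueError, match="n_components"):
            simpls_fit(X, np.zeros(4), 4)

    def test_autoscaling_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 4)) + 3
        y = rng.normal(size=6)
        fit1 = simpls_fit(X, y, 2)
        X2 = X.copy()
        X2[:, 1] *= 37.0
        fit2 = simpls_fit(X2, y, 2)
        assert np.allclose(fit1.predict(X), fit2.predict(X2), atol=1e-10)
        assert np.allclose(vip_scores(fit1), vip_scores(fit2), atol=1e-10)


class TestVIP:
    def test_mean_square_identity(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.normal(size=(7, 5))
            y = rng.normal(size=7)
            fit = simpls_fit(X, y, 2)
            vip = vip_scores(fit)
            assert np.mean(vip ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_column(self):
        rng = np.random.default_rng(8)
        X = np.zeros((6, 4))
        X[:, 2] = rng.normal(size=6)
        X[:, [0, 1, 3]] = 1.0  # constant -> dropped
        y = 3.0 * X[:, 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = simpls_fit(X, y, 1)
        vip = vip_scores(fit)
        assert vip[2] == pytest.approx(2.0)  # sqrt(p) with p = 4
        assert np.allclose(vip[[0, 1, 3]], 0.0)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        fit = simpls_fit(X, y, 3)
        W = fit.weights
        ssy = fit.y_loadings ** 2
        norms = np.linalg.norm(W, axis=0)
        manual = np.sqrt(5 * ((W / norms) ** 2 @ ssy) / ssy.sum())
        assert np.allclose(vip_scores(fit), manual, atol=1e-10)


class TestQ2Y:
    def test_perfect_linear_relation_q2_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        assert q2y_loo(X, y, 3) == pytest.approx(1.0, abs=1e-6)

    def test_random_noise_q2_nonpositive_in_expectation(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(100):
            X = rng.normal(size=(8, 4))
            y = rng.normal(size=8)
            vals.append(q2y_loo(X, y, 2))
        assert np.mean(vals) <= 0.0

    def test_manual_loo_oracle_exact(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        press = 0.0
        for i in range(5):
            mask = np.arange(5) != i
            f = simpls_fit(X[mask], y[mask], 1)
            press += (float(f.predict(X[i:i + 1])[0]) - y[i]) ** 2
        manual = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        assert q2y_loo(X, y, 1) == pytest.approx(manual, abs=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            q2y_loo(np.zeros((2, 3)), np.zeros(2), 1)


class TestEnsemble:
    def _fits(self, k=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        return [simpls_fit(X + 0.01 * j, y, 2) for j in range(k)], X

    def test_training_row_prediction_equals_fitted_value(self):
        fits, X = self._fits(1)
        fit = fits[0]
        scaled = (X - fit.x_mean) / fit.x_std
        fitted = scaled @ fit.coef_std + fit.y_mean
        assert predict_insulin(fit, X[2]) == pytest.approx(fitted[2])

    def test_ensemble_of_identical_models_matches_single(self):
        fits, X = self._fits(1)
        assert predict_insulin([fits[0]] * 5, X[0]) == pytest.approx(
            predict_insulin(fits[0], X[0]))

    def test_ensemble_mean_matches_manual_average(self):
        fits, X = self._fits(4, seed=5)
        manual = np.mean([float(f.predict(X[1:2])[0]) for f in fits])
        assert predict_insulin(fits, X[1]) == pytest.approx(manual)

    def test_dimension_mismatch_raises(self):
        fits, X = self._fits(1)
        with pytest.raises(ValueError):
            predict_insulin(fits[0], np.zeros(7))


class TestTimecoursePLSR:
    def _per_minute(self, T=10, p=5, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(T, p)), index=np.arange(1, T + 1),
                            columns=[f"r{j}" for j in range(p)])

    def test_response_endpoint_equals_total_fold_change(self):
        X = self._per_minute(10)
        fit = timecourse_plsr(X, insulin_fc_total=2.5, duration=10, n_components=2)
        # reconstruct the response convention at m = T
        assert 1.0 + (2.5 - 1.0) * 10 / 10 == pytest.approx(2.5)
        assert fit.n_components == 2

    def test_three_minute_course_three_rows(self):
        X = self._per_minute(15)
        with pytest.warns(UserWarning, match="at most 2 components"):
            fit = timecourse_plsr(X, 2.0, duration=3, n_components=3)
        assert fit.scores.shape[0] == 3
        assert fit.n_components == 2

    def test_linear_response_on_constant_plus_trend_gives_r2_one(self):
        T = 8
        X = self._per_minute(T, p=3, seed=2)
        X["r0"] = np.arange(1, T + 1, dtype=float)  # a flux tracking time
        fit = timecourse_plsr(X, 3.0, duration=T, n_components=3)
        assert fit.r2 > 0.999


class TestModelFrontDoor:
    def test_fit_summary_and_influential(self):
        rng = np.random.default_rng(42)
        times = [3.0, 6.0, 10.0, 15.0, 60.0]
        X = pd.DataFrame(rng.normal(size=(5, 6)), index=times,
                         columns=[f"r{j}" for j in range(6)])
        y = 1.5 + X["r1"] * 0.8
        res = FluxInsulinPLS(X, y, n_components=2, train_times=(3.0, 15.0, 60.0)).fit()
        assert 0 <= res.r2 <= 1
        text = res.summary()
        assert "R^2" in text and "components" in text
        infl = res.influential()
        assert (infl.VIP > 1).all()

    def test_fit_ensemble_size_matches_tables(self):
        rng = np.random.default_rng(1)
        times = [3.0, 6.0, 10.0, 15.0, 60.0]
        tabs = [pd.DataFrame(rng.normal(size=(5, 4)), index=times) for _ in range(8)]
        y = pd.Series(rng.uniform(1, 3, 5), index=times)
        ens = fit_ensemble(tabs, y, n_components=2)
        assert len(ens) == 8
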