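"""Elastic-net classifier: penalty factors, solver, CV, alpha search, predict."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hmcseal.classifier import (
    ElasticNetModel,
    cv_select_lambda,
    elastic_net_objective,
    fit_elastic_net,
    lambda_max,
    make_lambda_path,
    penalty_factors,
    predict,
    select_alpha,
    standardize,
)
from hmcseal.evaluation import roc_auc


def random_problem(seed, n=40, p=8, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    if signal:
        beta[: p // 2] = rng.normal(0, 1.5, size=p // 2)
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if y.sum() in (0, n):  # ensure both classes
        y[0] = 1 - y[0]
    nu = rng.uniform(0.5, 2.0, size=p)
    return X, y, nu / nu.mean()


def oracle_minimum(X, y, alpha, nu, lam):
    p = X.shape[1]

    def f(v):
        return elastic_net_objective(X, y, v[1:], v[0], alpha, nu, lam)

    r = minimize(f, np.zeros(p + 1), method="Nelder-Mead",
                 options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-13})
    r2 = minimize(f, r.x, method="Powell",
                  options={"maxiter": 40000, "xtol": 1e-12, "ftol": 1e-14})
    return min(r.fun, r2.fun)


class TestPenaltyFactors:
    def test_symmetry_and_rescaling(self):
        np.testing.assert_allclose(penalty_factors([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(penalty_factors([1.0, 2.0]), [4 / 3, 2 / 3])

    def test_zero_fold_change_capped_finite(self):
        nu = penalty_factors([0.0, 1.0], epsilon=0.01)
        assert np.isfinite(nu).all()
        assert nu.mean() == pytest.approx(1.0)
        assert nu[0] > nu[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            penalty_factors([])


class TestSolver:
    def test_all_zero_at_lambda_max(self):
        X, y, nu = random_problem(3)
        lmax = lambda_max(X, y, 0.5, nu)
        betas, b0s = fit_elastic_net(X, y, 0.5, nu, np.array([lmax * 1.01]))
        assert np.allclose(betas[0], 0.0)
        ybar = y.mean()
        assert b0s[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_near_ridge_tiny_lambda_matches_unpenalized_fit(self):
        import statsmodels.api as sm

        X, y, _ = random_problem(7, n=200, p=4)
        nu = np.ones(4)
        path = np.array([1e-2, 1e-4, 1e-7])
        betas, b0s = fit_elastic_net(X, y, 0.0, nu, path)
        fit = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert b0s[-1] == pytest.approx(fit.params[0], abs=1e-3)
        np.testing.assert_allclose(betas[-1], fit.params[1:], atol=1e-3)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_objective_matches_generic_optimizer(self, alpha):
        X, y, nu = random_problem(int(alpha * 100))
        path = make_lambda_path(X, y, alpha, nu, n_lambda=20)
        betas, b0s = fit_elastic_net(X, y, alpha, nu, path)
        li = 10
        ours = elastic_net_objective(X, y, betas[li], b0s[li], alpha, nu, path[li])
        assert ours <= oracle_minimum(X, y, alpha, nu, path[li]) + 1e-6

    def test_path_continuity_coefficients_shrink_toward_lambda_max(self):
        X, y, nu = random_problem(11)
        path = make_lambda_path(X, y, 0.5, nu, n_lambda=50)
        betas, _ = fit_elastic_net(X, y, 0.5, nu, path)
        norms = np.abs(betas).sum(axis=1)
        assert norms[0] == 0.0
        assert norms[-1] > norms[5]
        assert norms[1] < 0.2 * norms[-1]

    def test_kkt_conditions_at_solution(self):
        X, y, nu = random_problem(13)
        alpha = 0.5
        path = make_lambda_path(X, y, alpha, nu, n_lambda=20)
        betas, b0s = fit_elastic_net(X, y, alpha, nu, path)
        li, lam = 12, path[12]
        beta, b0 = betas[li], b0s[li]
        prob = 1 / (1 + np.exp(-(b0 + X @ beta)))
        grad = -X.T @ (y - prob) / len(y) + lam * (1 - alpha) * nu * beta
        for j in range(len(beta)):
            if beta[j] != 0:
                assert grad[j] + lam * alpha * nu[j] * np.sign(beta[j]) == pytest.approx(0, abs=1e-5)
            else:
                assert abs(grad[j]) <= lam * alpha * nu[j] + 1e-5

    def test_single_class_and_bad_path_rejected(self):
        X, _, nu = random_problem(1)
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(40), 0.5, nu, np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.r_[np.ones(20), np.zeros(20)], 0.5, nu,
                            np.array([0.5, 1.0]))


class TestCV:
    def test_seed_determinism(self):
        X, y, nu = random_problem(21, n=60)
        a = cv_select_lambda(X, y, 0.5, nu, n_folds=5, seed=4)
        b = cv_select_lambda(X, y, 0.5, nu, n_folds=5, seed=4)
        assert a.lambda_1se == b.lambda_1se
        np.testing.assert_allclose(a.mean_error, b.mean_error)

    def test_one_se_rule_picks_largest_lambda_within_band(self):
        X, y, nu = random_problem(22, n=60)
        cv = cv_select_lambda(X, y, 0.5, nu, n_folds=5, seed=1)
        imin = int(np.argmin(cv.mean_error))
        thresh = cv.mean_error[imin] + cv.se_error[imin]
        chosen = np.nonzero(cv.lambdas == cv.lambda_1se)[0][0]
        assert cv.mean_error[chosen] <= thresh
        assert (cv.mean_error[:chosen] > thresh).all()
        assert cv.lambda_1se >= cv.lambda_min

    def test_leave_one_out_matches_explicit_loop(self):
        X, y, nu = random_problem(23, n=10, p=3)
        path = make_lambda_path(X, y, 0.5, nu, n_lambda=10)
        cv = cv_select_lambda(X, y, 0.5, nu, n_folds=10, seed=0, lambda_path=path)
        from hmcseal.classifier import _binomial_deviance

        errs = np.empty((10, len(path)))
        for i in range(10):
            tr = np.delete(np.arange(10), i)
            betas, b0s = fit_elastic_net(X[tr], y[tr], 0.5, nu, path)
            eta = b0s + betas @ X[i]
            errs[i] = _binomial_deviance(y[i], eta)
        np.testing.assert_allclose(cv.mean_error, errs.mean(axis=0), atol=1e-8)

    def test_small_class_rejected(self):
        X, y, nu = random_problem(24)
        y = np.zeros(40)
        y[:3] = 1
        with pytest.raises(ValueError):
            cv_select_lambda(X, y, 0.5, nu, n_folds=10, seed=0)


class TestSelectAlpha:
    def make_frames(self, seed, n=40, p=10, separable=False):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        shift = 3.0 if separable else 0.8
        V = rng.normal(size=(p, n)) + shift * np.outer(rng.choice([1, -1], p), y)
        df = pd.DataFrame(V, index=[f"g{j}" for j in range(p)],
                          columns=[f"s{i}" for i in range(n)])
        return df, y

    def test_grid_of_one_returned(self):
        tr = self.make_frames(1)
        va = self.make_frames(2)
        nu = np.ones(10)
        alpha, model, table = select_alpha(tr, va, nu, alpha_grid=[0.3], n_folds=5, seed=0)
        assert alpha == 0.3 and len(table) == 1

    def test_separable_data_attains_auc_one_and_tie_prefers_smaller_alpha(self):
        tr = self.make_frames(13, separable=True)
        va = self.make_frames(14, separable=True)
        nu = np.ones(10)
        alpha, model, table = select_alpha(tr, va, nu, alpha_grid=[0.25, 0.75],
                                           n_folds=5, seed=13)
        assert table["validation_auc"].max() == 1.0
        ties = table[table.validation_auc == table.validation_auc.max()]
        assert alpha == ties["alpha"].min()

    def test_empty_grid_rejected(self):
        tr = self.make_frames(1)
        with pytest.raises(ValueError):
            select_alpha(tr, tr, np.ones(10), alpha_grid=[])


class TestPredict:
    def null_model(self, p=4):
        return ElasticNetModel(
            feature_ids=[f"g{j}" for j in range(p)],
            beta=np.zeros(p), intercept=0.0, alpha=0.5, lam=1.0,
            nu=np.ones(p), x_mean=np.zeros(p), x_sd=np.ones(p),
        )

    def test_null_model_gives_half_probability_not_called(self):
        model = self.null_model()
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)),
                              index=model.feature_ids, columns=list("abc"))
        out = predict(model, values)
        assert (out["probability"] == 0.5).all()
        assert (out["call"] == "not_cancer").all()  # strict > 0.5

    def test_duplicated_sample_scores_identically(self):
        rng = np.random.default_rng(1)
        model = self.null_model()
        model.beta = rng.normal(size=4)
        values = pd.DataFrame(rng.normal(size=(4, 2)), index=model.feature_ids,
                              columns=["a", "b"])
        values["b"] = values["a"]
        out = predict(model, values)
        assert out.loc["a", "probability"] == out.loc["b", "probability"]

    def test_missing_features_rejected(self):
        model = self.null_model()
        values = pd.DataFrame(np.zeros((2, 1)), index=["g0", "g1"], columns=["s"])
        with pytest.raises(ValueError, match="g2"):
            predict(model, values)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(5)
        model = self.null_model()
        model.beta = rng.normal(size=4)
        model.x_mean = rng.normal(size=4)
        model.x_sd = np.abs(rng.normal(size=4)) + 0.5
        values = pd.DataFrame(rng.normal(size=(4, 5)), index=model.feature_ids,
                              columns=[f"s{i}" for i in range(5)])
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ElasticNetModel.from_json(p)
        pd.testing.assert_series_equal(model.predict_proba(values),
                                       back.predict_proba(values))

    def test_training_auc_not_worse_than_null(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(6, 30)), index=[f"g{j}" for j in range(6)])
        y = np.r_[np.ones(15), np.zeros(15)]
        df.iloc[0] += 2.0 * y
        Z, mean, sd = standardize(df)
        from hmcseal.classifier import fit_at

        model, _ = fit_at(df, y, alpha=0.5, nu=np.ones(6), n_folds=5, seed=2)
        scores = model.predict_proba(df)
        assert (scores.to_numpy() >= 0).all() and (scores.to_numpy() <= 1).all()
        assert roc_auc(scores.to_numpy(), y.astype(int)).auc >= 0.5
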