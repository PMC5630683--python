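"""Penalty-weighted elastic-net logistic regression for cancer calling.

The classifier minimizes, over coefficients beta and intercept beta0,

    (1/N) sum_i [log(1 + exp(eta_i)) - y_i eta_i]
        + lambda sum_j nu_j [alpha |beta_j| + (1 - alpha) beta_j^2 / 2],

with eta_i = beta0 + x_i' beta, solved by cyclic coordinate descent on
an IRLS quadratic approximation with warm starts along a descending
lambda path (glmnet-style). Per-feature penalty factors
nu_j = 1 / max(|f_j|, eps), rescaled to mean one, down-weight the
penalty on loci with large training log2 fold changes f_j, which the
assay detects more reproducibly. lambda follows the 1-SE
cross-validation rule; alpha is chosen to maximize AUC on a held-out
validation batch over a grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .differential import NormalizationReference, rlog_apply
from .features import CountMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _cd_kernel(X, y, alpha, nu, lam, beta, b0, max_outer, max_inner, tol):
    n, p = X.shape
    beta_start = np.empty(p)
    for _outer in range(max_outer):
        for j in range(p):
            beta_start[j] = beta[j]
        b0_start = b0
        # quadratic approximation at current (beta, b0)
        eta = np.empty(n)
        for i in range(n):
            s = b0
            for j in range(p):
                s += X[i, j] * beta[j]
            eta[i] = s
        w = np.empty(n)
        z = np.empty(n)
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                pr = 1.0
            elif e < -30.0:
                pr = 0.0
            else:
                pr = 1.0 / (1.0 + math.exp(-e))
            wi = pr * (1.0 - pr)
            if wi < 1e-6:
                wi = 1e-6
            w[i] = wi
            z[i] = e + (y[i] - pr) / wi
        wx2 = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wx2[j] = s / n
        wsum = 0.0
        for i in range(n):
            wsum += w[i]
        r = np.empty(n)
        for i in range(n):
            r[i] = z[i] - eta[i]
        # inner coordinate descent on the weighted least squares problem
        for _inner in range(max_inner):
            dmax = 0.0
            for j in range(p):
                g = 0.0
                for i in range(n):
                    g += w[i] * X[i, j] * r[i]
                g = g / n + beta[j] * wx2[j]
                thr = lam * alpha * nu[j]
                if g > thr:
                    bj = (g - thr) / (wx2[j] + lam * (1.0 - alpha) * nu[j])
                elif g < -thr:
                    bj = (g + thr) / (wx2[j] + lam * (1.0 - alpha) * nu[j])
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    beta[j] = bj
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            # intercept (unpenalized)
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= wsum
            if d0 != 0.0:
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > dmax:
                    dmax = abs(d0)
            if dmax < tol:
                break
        outer_change = abs(b0 - b0_start)
        for j in range(p):
            c = abs(beta[j] - beta_start[j])
            if c > outer_change:
                outer_change = c
        if outer_change < tol * 10.0:
            break
    return b0


def penalty_factors(f: Sequence[float] | pd.Series, epsilon: float = 0.01) -> np.ndarray:
    """nu_j = 1 / max(|f_j|, epsilon), rescaled to mean one."""
    arr = np.asarray(f, dtype=float)
    if arr.size == 0:
        raise ValueError("empty fold-change vector")
    if not np.isfinite(arr).all():
        raise ValueError("fold changes must be finite")
    nu = 1.0 / np.maximum(np.abs(arr), epsilon)
    return nu / nu.mean()


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float, nu: np.ndarray) -> float:
    """Smallest lambda at which all penalized coefficients are zero."""
    n = len(y)
    ybar = y.mean()
    grad = np.abs(X.T @ (y - ybar)) / (n * max(alpha, 1e-3) * nu)
    return float(grad.max())


def make_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    nu: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    lmax = lambda_max(X, y, alpha, nu) * 1.000001
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambda))


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    nu: np.ndarray,
    lambda_path: np.ndarray,
    tol: float = 1e-9,
    max_outer: int = 100,
    max_inner: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent solution path over a descending lambda sequence.

    X must be standardized (the caller owns centering/scaling). Returns
    (betas: L x p, intercepts: L). Warm-starts each lambda at the
    previous solution.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y contains a single class")
    lambda_path = np.asarray(lambda_path, dtype=float)
    if (np.diff(lambda_path) >= 0).any():
        raise ValueError("lambda path must be strictly descending")
    X = np.ascontiguousarray(X, dtype=float)
    n, p = X.shape
    nu = np.asarray(nu, dtype=float)
    betas = np.zeros((len(lambda_path), p))
    b0s = np.zeros(len(lambda_path))
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = math.log(ybar / (1.0 - ybar)) if 0 < ybar < 1 else 0.0
    for li, lam in enumerate(lambda_path):
        b0 = _cd_kernel(X, y, float(alpha), nu, float(lam), beta, float(b0),
                        max_outer, max_inner, tol)
        betas[li] = beta
        b0s[li] = b0
    return betas, b0s


def elastic_net_objective(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    b0: float,
    alpha: float,
    nu: np.ndarray,
    lam: float,
) -> float:
    """Mean negative log-likelihood plus the weighted elastic-net penalty."""
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * np.sum(nu * (alpha * np.abs(beta) + 0.5 * (1.0 - alpha) * beta**2))
    return float(nll + pen)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray
    lambda_1se: float
    lambda_min: float
    index_1se: int


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    prob = np.clip(prob, 1e-10, 1 - 1e-10)
    return -2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    nu: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    lambda_path: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated lambda with the 1-SE rule.

    Stratified seeded folds; CV error is the mean held-out binomial
    deviance; lambda_1se is the largest lambda whose mean error is
    within one standard error of the minimum. With n_folds equal to the
    sample count, plain leave-one-out folds are used.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if lambda_path is None:
        lambda_path = make_lambda_path(X, y, alpha, nu)
    if n_folds == n:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        n_min = min((y == 1).sum(), (y == 0).sum())
        if n_min < n_folds:
            raise ValueError(
                f"smallest class ({n_min}) too small for {n_folds}-fold stratification"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    fold_err = np.empty((len(folds), len(lambda_path)))
    for fi, (tr, te) in enumerate(folds):
        betas, b0s = fit_elastic_net(X[tr], y[tr], alpha, nu, lambda_path)
        eta = b0s[:, None] + betas @ X[te].T  # L x n_te
        dev = _binomial_deviance(y[te][None, :], eta)
        fold_err[fi] = dev.mean(axis=1)
    mean_err = fold_err.mean(axis=0)
    se = fold_err.std(axis=0, ddof=1) / math.sqrt(len(folds))
    imin = int(np.argmin(mean_err))
    thresh = mean_err[imin] + se[imin]
    i1se = int(np.nonzero(mean_err <= thresh)[0][0])  # path is descending in lambda
    return CVResult(
        lambdas=lambda_path,
        mean_error=mean_err,
        se_error=se,
        lambda_1se=float(lambda_path[i1se]),
        lambda_min=float(lambda_path[imin]),
        index_1se=i1se,
    )


# ---------------------------------------------------------------------------
# Model container


@dataclass
class ElasticNetModel:
    """A fitted classifier: coefficients plus everything frozen at training.

    ``beta`` lives on the standardized-feature scale; ``x_mean`` /
    ``x_sd`` map new rlog values onto that scale. The embedded
    NormalizationReference lets ``predict`` start from raw counts.
    """

    feature_ids: list[str]
    beta: np.ndarray
    intercept: float
    alpha: float
    lam: float
    nu: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    reference: NormalizationReference | None = None
    x: pd.DataFrame | None = field(default=None, repr=False)  # training matrix

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def decision_function(self, values: pd.DataFrame) -> pd.Series:
        """Linear predictor from an rlog-scale features x samples frame."""
        missing = set(self.feature_ids) - set(values.index)
        if missing:
            raise ValueError(f"missing model features: {sorted(missing)[:10]}")
        V = values.loc[self.feature_ids].to_numpy(dtype=float)
        Z = (V - self.x_mean[:, None]) / self.x_sd[:, None]
        eta = self.intercept + self.beta @ Z
        return pd.Series(eta, index=values.columns, name="eta")

    def predict_proba(self, values: pd.DataFrame) -> pd.Series:
        eta = self.decision_function(values)
        return pd.Series(
            1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), index=eta.index, name="probability"
        )

    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_ids": self.feature_ids,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "nu": self.nu.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
        }
        if self.reference is not None:
            obj["normalization_reference"] = self.reference.to_dict()
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElasticNetModel":
        obj = json.loads(Path(path).read_text())
        ref = None
        if "normalization_reference" in obj:
            ref = NormalizationReference.from_dict(obj["normalization_reference"])
        return cls(
            feature_ids=obj["feature_ids"],
            beta=np.asarray(obj["beta"]),
            intercept=float(obj["intercept"]),
            alpha=float(obj["alpha"]),
            lam=float(obj["lambda"]),
            nu=np.asarray(obj["nu"]),
            x_mean=np.asarray(obj["x_mean"]),
            x_sd=np.asarray(obj["x_sd"]),
            reference=ref,
        )


# ---------------------------------------------------------------------------
# Alpha selection and the training entry point


def standardize(values: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-sample standardization stats from a features x samples frame."""
    V = values.to_numpy(dtype=float)
    mean = V.mean(axis=1)
    sd = V.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (V - mean[:, None]) / sd[:, None]
    return Z, mean, sd


def fit_at(
    values: pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    nu: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    reference: NormalizationReference | None = None,
) -> tuple[ElasticNetModel, CVResult]:
    """Fit at one alpha: CV-select lambda (1-SE) then refit on all samples."""
    Z, mean, sd = standardize(values)
    X = Z.T  # samples x features
    path = make_lambda_path(X, y, alpha, nu)
    cv = cv_select_lambda(X, y, alpha, nu, n_folds=n_folds, seed=seed, lambda_path=path)
    betas, b0s = fit_elastic_net(X, y, alpha, nu, path)
    model = ElasticNetModel(
        feature_ids=list(values.index),
        beta=betas[cv.index_1se].copy(),
        intercept=float(b0s[cv.index_1se]),
        alpha=alpha,
        lam=cv.lambda_1se,
        nu=np.asarray(nu, dtype=float),
        x_mean=mean,
        x_sd=sd,
        reference=reference,
        x=values,
    )
    return model, cv


def select_alpha(
    train: tuple[pd.DataFrame, np.ndarray],
    validation: tuple[pd.DataFrame, np.ndarray],
    nu: np.ndarray,
    alpha_grid: Sequence[float] = tuple(np.round(np.arange(0.05, 0.951, 0.1), 2)),
    n_folds: int = 10,
    seed: int = 0,
    reference: NormalizationReference | None = None,
) -> tuple[float, ElasticNetModel, pd.DataFrame]:
    """Search alpha to maximize validation AUC; ties go to the smaller alpha.

    Each candidate alpha is fitted on the training batch with its own
    1-SE lambda, scored on the disjoint validation batch, and the best
    model (refit on training at the chosen alpha/lambda) is returned
    with the per-alpha summary table.
    """
    from .evaluation import roc_auc

    if len(alpha_grid) == 0:
        raise ValueError("empty alpha grid")
    x_train, y_train = train
    x_val, y_val = validation
    rows = []
    best: tuple[float, float, ElasticNetModel] | None = None
    for a in sorted(alpha_grid):
        model, cv = fit_at(x_train, y_train, a, nu, n_folds=n_folds, seed=seed,
                           reference=reference)
        scores = model.predict_proba(x_val)
        auc = roc_auc(scores.to_numpy(), y_val).auc
        rows.append(
            {"alpha": a, "lambda_1se": cv.lambda_1se, "n_nonzero": model.n_nonzero,
             "validation_auc": auc}
        )
        if best is None or auc > best[0]:
            best = (auc, a, model)
    assert best is not None
    return best[1], best[2], pd.DataFrame(rows)


def predict(model: ElasticNetModel, counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Score samples: frozen rlog -> standardize -> sigmoid; call at p > 0.5.

    Accepts raw counts (transformed with the model's frozen reference)
    or an already rlog-transformed features x samples frame. No
    statistic is re-estimated from the test data.
    """
    if isinstance(counts, CountMatrix):
        if model.reference is None:
            raise ValueError("model has no normalization reference; pass rlog values")
        values = rlog_apply(counts, model.reference)
    else:
        values = counts
    prob = model.predict_proba(values)
    return pd.DataFrame(
        {"probability": prob, "call": (prob > 0.5).map({True: "cancer", False: "not_cancer"})}
    )
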