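"""Negative-binomial differential 5hmC analysis and frozen rlog normalization.

Per-feature counts are modeled as NB(mu, alpha) with a log link,
log mu_ij = offset_i + x_i' beta_j, where the offset is the log
median-of-ratios size factor and the design carries the covariates
(age group, technician, and patient-nested-under-technician for paired
tissue designs) with the disease-status contrast as the last column.
Dispersions are estimated per feature by Cox-Reid adjusted profile
likelihood, a parametric trend alpha(mu) = a0 + a1/mu is fitted across
features, and per-feature estimates are shrunk toward the trend under a
normal prior on the log dispersion. Differential features are called by
Wald test with Benjamini-Hochberg FDR control and a fold-change floor.

The regularized-log (rlog) transform shrinks per-sample log2 normalized
counts toward the feature's cross-sample mean, with stronger shrinkage
where the trend predicts higher dispersion. Fitting freezes everything
(reference geometric means, trend, per-feature targets) so validation
and test samples are transformed against the training reference without
re-estimating any statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import norm, t as student_t
from statsmodels.stats.multitest import multipletests

from .features import CountMatrix

LN2 = math.log(2.0)

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0
PRIOR_LOG_SD = 0.5
RLOG_PSEUDOCOUNT = 0.5
RLOG_SHRINK_SCALE = 5.0


@dataclass
class DesignSpec:
    """Model design: status contrast plus categorical covariates.

    ``pair_by_patient`` encodes the paired tumor/adjacent design with
    patient identity nested under technician identity (requires exactly
    two samples per patient, both handled by the same technician).
    """

    condition: str = "status"
    covariates: tuple[str, ...] = ("age_group", "technician")
    pair_by_patient: bool = False
    patient_column: str = "patient_id"
    technician_column: str = "technician"


# ---------------------------------------------------------------------------
# Size factors


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the per-feature geometric mean."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    ok = (arr > 0).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "consider a pseudocount before normalization"
        )
    loggeo = np.log(arr[ok]).mean(axis=1)
    ratios = np.log(arr[ok]) - loggeo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _size_factors_vs_reference(
    counts: pd.DataFrame, log_geo_mean: pd.Series
) -> pd.Series:
    """Size factors of new samples against frozen reference geometric means."""
    ref = log_geo_mean.reindex(counts.index)
    ok = np.isfinite(ref.to_numpy())
    arr = counts.to_numpy(dtype=float)[ok]
    with np.errstate(divide="ignore"):
        ratios = np.log(arr) - ref.to_numpy()[ok][:, None]
    sf = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Design matrices


def build_design_matrix(
    metadata: pd.DataFrame,
    design: DesignSpec,
    contrast: tuple[str, str, str],
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the fixed-effect design matrix; the contrast column is last.

    Returns (X, column names, indicator of the group of interest).
    Raises on a rank-deficient matrix, naming the collinear columns.
    """
    cond, interest, reference = contrast
    levels = set(metadata[cond])
    unknown = levels - {interest, reference}
    if unknown:
        raise ValueError(f"{cond} has levels outside the contrast: {sorted(unknown)}")
    y_ind = (metadata[cond] == interest).to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names = ["intercept"]
    for cov in design.covariates:
        lv = sorted(set(metadata[cov].astype(str)))
        for level in lv[1:]:
            cols.append((metadata[cov].astype(str) == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    if design.pair_by_patient:
        _validate_nesting(metadata, design)
        # patients renumbered within technician; drop the first per technician
        for tech, sub in metadata.groupby(design.technician_column, sort=True):
            patients = sorted(set(sub[design.patient_column]))
            for pat in patients[1:]:
                cols.append((metadata[design.patient_column] == pat).to_numpy(dtype=float))
                names.append(f"patient[{pat}]")
    cols.append(y_ind)
    names.append(f"{cond}[{interest}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _find_collinear(X, names)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    return X, names, y_ind


def _validate_nesting(metadata: pd.DataFrame, design: DesignSpec) -> None:
    g = metadata.groupby(design.patient_column)
    sizes = g.size()
    if (sizes != 2).any():
        bad = sizes[sizes != 2].index.tolist()
        raise ValueError(f"paired design requires exactly two samples per patient: {bad}")
    techs = g[design.technician_column].nunique()
    if (techs != 1).any():
        bad = techs[techs != 1].index.tolist()
        raise ValueError(f"patients split across technicians: {bad}")


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    out = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.abs(resid).max() < 1e-8:
            out.append(names[j])
    return out or names


# ---------------------------------------------------------------------------
# Batched NB GLM


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs with log link for all features at once.

    Y is features x samples, X samples x k, offset per sample, alpha per
    feature. Returns (beta (p x k), covariance diag (p x k), mu (p x n)).
    """
    p, n = Y.shape
    k = X.shape[1]
    beta = np.zeros((p, k))
    base = np.log(np.maximum(Y.mean(axis=1) / np.exp(offset).mean(), 1e-8))
    beta[:, 0] = base
    al = alpha[:, None]
    ridge = 1e-10 * np.eye(k)
    for _ in range(max_iter):
        eta = offset[None, :] + beta @ X.T
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + al * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("pn,ni,nj->pij", W, X, X) + ridge
        b = np.einsum("pn,pn,ni->pi", W, z, X)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            break
    eta = offset[None, :] + beta @ X.T
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + al * mu)
    A = np.einsum("pn,ni,nj->pij", W, X, X) + ridge
    cov = np.linalg.inv(A)
    return beta, np.diagonal(cov, axis1=1, axis2=2).copy(), mu


def _nb_profile_ll(
    Y: np.ndarray,
    mu: np.ndarray,
    alpha: np.ndarray,
    X: np.ndarray | None = None,
    cox_reid: bool = True,
) -> np.ndarray:
    """NB log-likelihood per feature at fixed mu, optionally Cox-Reid adjusted."""
    al = alpha[:, None]
    r = 1.0 / al
    ll = (
        gammaln(Y + r)
        - gammaln(r)
        + r * np.log(r / (r + mu))
        + Y * np.log(mu / (r + mu))
    ).sum(axis=1)
    if cox_reid and X is not None:
        W = mu / (1.0 + al * mu)
        A = np.einsum("pn,ni,nj->pij", W, X, X) + 1e-10 * np.eye(X.shape[1])
        _, logdet = np.linalg.slogdet(A)
        ll = ll - 0.5 * logdet
    return ll


def _mle_dispersion(
    Y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    grid_size: int = 40,
    refine: int = 25,
    cox_reid: bool = True,
    prior_mean_log: np.ndarray | None = None,
    prior_sd: float = PRIOR_LOG_SD,
) -> np.ndarray:
    """Per-feature dispersion by grid search + golden-section refinement.

    Maximizes the (Cox-Reid adjusted) profile likelihood; when
    ``prior_mean_log`` is given, maximizes the posterior under a normal
    prior on the log dispersion (MAP shrinkage toward the trend).
    """
    p = Y.shape[0]

    def objective(log_a: np.ndarray) -> np.ndarray:
        val = _nb_profile_ll(Y, mu, np.exp(log_a), X, cox_reid)
        if prior_mean_log is not None:
            val = val - (log_a - prior_mean_log) ** 2 / (2.0 * prior_sd**2)
        return val

    grid = np.linspace(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL), grid_size)
    ll = np.empty((p, grid_size))
    for g in range(grid_size):
        ll[:, g] = objective(np.full(p, grid[g]))
    best = np.argmax(ll, axis=1)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid_size - 1)]
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a_ = hi - gr * (hi - lo)
    b_ = lo + gr * (hi - lo)
    fa = objective(a_)
    fb = objective(b_)
    for _ in range(refine):
        take_a = fa > fb
        hi = np.where(take_a, b_, hi)
        lo = np.where(take_a, lo, a_)
        a_ = hi - gr * (hi - lo)
        b_ = lo + gr * (hi - lo)
        fa = objective(a_)
        fb = objective(b_)
    return np.exp((lo + hi) / 2.0)


@dataclass
class DispersionFit:
    """Per-feature dispersion estimates and the fitted mean trend."""

    dispersion: pd.Series  # final (shrunken) values
    mle: pd.Series
    trend: pd.Series
    trend_coef: tuple[float, float]  # alpha(mu) = a0 + a1 / mu
    base_mean: pd.Series


def _fit_trend(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu, iteratively excluding > 2-log-unit outliers."""
    use = (mean > 0) & (disp > DISPERSION_FLOOR * 10)
    if use.sum() < 10:
        med = float(np.median(disp[disp > 0])) if (disp > 0).any() else DISPERSION_FLOOR
        return max(med, DISPERSION_FLOOR), 0.0
    m, d = mean[use], disp[use]
    keep = np.ones(len(d), dtype=bool)
    a0, a1 = float(np.median(d)), 0.0
    for _ in range(10):
        A = np.column_stack([np.ones(keep.sum()), 1.0 / m[keep]])
        coef, *_ = np.linalg.lstsq(A, d[keep], rcond=None)
        a0, a1 = float(max(coef[0], DISPERSION_FLOOR)), float(max(coef[1], 0.0))
        pred = a0 + a1 / m
        new_keep = np.abs(np.log(d) - np.log(np.maximum(pred, DISPERSION_FLOOR))) < 2.0
        if new_keep.sum() < 10 or (new_keep == keep).all():
            break
        keep = new_keep
    return a0, a1


def estimate_dispersions(
    matrix: CountMatrix,
    design: DesignSpec | None = None,
    contrast: tuple[str, str, str] | None = None,
    cox_reid: bool = True,
) -> DispersionFit:
    """Estimate per-feature NB dispersions with trend shrinkage.

    Adjusted-profile-ML estimates are shrunk toward the parametric trend
    a0 + a1/mu under a normal prior (sd 0.5) on the log dispersion;
    estimates more than 2 log units above the trend are kept as-is
    (dispersion outliers), and features whose estimate sits at the floor
    (e.g. constant counts) stay at the floor.
    """
    counts = matrix.counts
    Y = counts.to_numpy(dtype=float)
    n = Y.shape[1]
    if design is None or contrast is None:
        X = np.ones((n, 1))
    else:
        X, _, _ = build_design_matrix(matrix.metadata, design, contrast)
    k = X.shape[1]
    if n - k < 2:
        raise ValueError(f"insufficient residual degrees of freedom ({n - k})")
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    nonzero = Y.sum(axis=1) > 0
    Yn = Y[nonzero]

    alpha0 = np.full(Yn.shape[0], 0.1)
    _, _, mu = _irls_nb(Yn, X, offset, alpha0)
    a_mle = _mle_dispersion(Yn, mu, X, cox_reid=cox_reid)
    _, _, mu = _irls_nb(Yn, X, offset, a_mle)
    a_mle = _mle_dispersion(Yn, mu, X, cox_reid=cox_reid)

    base_mean_nz = (Yn / np.exp(offset)[None, :]).mean(axis=1)
    a0, a1 = _fit_trend(base_mean_nz, a_mle)
    trend = np.maximum(a0 + a1 / np.maximum(base_mean_nz, 1e-8), DISPERSION_FLOOR)

    # MAP shrinkage: maximize CR likelihood + normal prior about the trend
    log_trend = np.log(trend)
    final = _mle_dispersion(Yn, mu, X, cox_reid=cox_reid, prior_mean_log=log_trend)
    log_mle = np.log(np.maximum(a_mle, DISPERSION_FLOOR))
    outlier = log_mle > log_trend + 2.0 * PRIOR_LOG_SD
    final[outlier] = a_mle[outlier]
    # genuinely under-dispersed features (e.g. constant counts) stay at the floor
    resid_var = (Yn / np.exp(offset)[None, :]).var(axis=1, ddof=1)
    at_floor = (a_mle <= DISPERSION_FLOOR * 10) & (resid_var <= 0.5 * base_mean_nz)
    final[at_floor] = DISPERSION_FLOOR
    final = np.clip(final, DISPERSION_FLOOR, DISPERSION_CEIL)

    idx = counts.index
    full = lambda v: pd.Series(  # noqa: E731
        np.where(nonzero, _expand(v, nonzero), np.nan), index=idx
    )
    base_mean = pd.Series(
        np.where(nonzero, _expand(base_mean_nz, nonzero), 0.0), index=idx
    )
    return DispersionFit(
        dispersion=full(final),
        mle=full(a_mle),
        trend=full(trend),
        trend_coef=(a0, a1),
        base_mean=base_mean,
    )


def _expand(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape[0], np.nan)
    out[mask] = values
    return out


# ---------------------------------------------------------------------------
# Wald test


def nb_wald_test(
    matrix: CountMatrix,
    design: DesignSpec | None = None,
    contrast: tuple[str, str, str] = ("status", "cancer", "healthy"),
    dispersions: DispersionFit | None = None,
    wald_dist: str = "t",
) -> pd.DataFrame:
    """Per-feature NB Wald test of the contrast, adjusting for covariates.

    The Wald statistic is referred to a t distribution with residual
    degrees of freedom by default (``wald_dist="t"``), which keeps tail
    p-values calibrated when dispersions are estimated from a few dozen
    samples; ``wald_dist="normal"`` gives the asymptotic reference.
    Returns a DataFrame indexed by feature with columns base_mean,
    log2fc, se (log2 scale), stat, pvalue, qvalue. All-zero features get
    NaN statistics and are excluded from FDR adjustment.
    """
    design = design or DesignSpec()
    X, names, _ = build_design_matrix(matrix.metadata, design, contrast)
    counts = matrix.counts
    Y = counts.to_numpy(dtype=float)
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, design, contrast)
    nonzero = Y.sum(axis=1) > 0
    Yn = Y[nonzero]
    alpha = dispersions.dispersion.to_numpy()[nonzero]
    beta, covdiag, _ = _irls_nb(Yn, X, offset, alpha)
    b = beta[:, -1]
    se_nat = np.sqrt(np.maximum(covdiag[:, -1], 0.0))
    stat = np.where(se_nat > 0, b / se_nat, 0.0)
    if wald_dist == "t":
        df = max(X.shape[0] - X.shape[1], 1)
        pvals = 2.0 * student_t.sf(np.abs(stat), df)
    elif wald_dist == "normal":
        pvals = 2.0 * norm.sf(np.abs(stat))
    else:
        raise ValueError(f"unknown wald_dist {wald_dist!r}")

    idx = counts.index
    out = pd.DataFrame(
        {
            "base_mean": dispersions.base_mean,
            "log2fc": pd.Series(_expand(b / LN2, nonzero), index=idx),
            "se": pd.Series(_expand(se_nat / LN2, nonzero), index=idx),
            "stat": pd.Series(_expand(stat, nonzero), index=idx),
            "pvalue": pd.Series(_expand(pvals, nonzero), index=idx),
        }
    )
    q = np.full(len(idx), np.nan)
    mask = out["pvalue"].notna().to_numpy()
    if mask.any():
        q[mask] = bh_fdr(out.loc[mask, "pvalue"].to_numpy())
    out["qvalue"] = q
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(
    result: pd.DataFrame, fdr: float = 0.05, fold: float = 1.2
) -> list[str]:
    """Features with q < fdr and |log2fc| > log2(fold), either direction."""
    if fold <= 1.0:
        raise ValueError("fold threshold must exceed 1")
    mask = (result["qvalue"] < fdr) & (result["log2fc"].abs() > math.log2(fold))
    return result.index[mask.fillna(False)].tolist()


# ---------------------------------------------------------------------------
# Regularized log transform, frozen to a training reference


@dataclass
class NormalizationReference:
    """Everything needed to rlog-transform new samples like the training batch."""

    feature_ids: list[str]
    log_geo_mean: pd.Series  # ln geometric mean of training counts (NaN if any zero)
    baseline_mean: pd.Series  # per-feature mean log2 normalized value (shrink target)
    alpha_trend: pd.Series  # trend-predicted dispersion per feature
    trend_coef: tuple[float, float]
    size_factor_summary: dict = field(default_factory=dict)
    pseudocount: float = RLOG_PSEUDOCOUNT
    shrink_scale: float = RLOG_SHRINK_SCALE

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "log_geo_mean": [None if not np.isfinite(v) else float(v) for v in self.log_geo_mean],
            "baseline_mean": list(map(float, self.baseline_mean)),
            "alpha_trend": list(map(float, self.alpha_trend)),
            "trend_coef": list(self.trend_coef),
            "size_factor_summary": self.size_factor_summary,
            "pseudocount": self.pseudocount,
            "shrink_scale": self.shrink_scale,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "NormalizationReference":
        fid = obj["feature_ids"]
        lg = pd.Series(
            [np.nan if v is None else v for v in obj["log_geo_mean"]], index=fid
        )
        return cls(
            feature_ids=fid,
            log_geo_mean=lg,
            baseline_mean=pd.Series(obj["baseline_mean"], index=fid),
            alpha_trend=pd.Series(obj["alpha_trend"], index=fid),
            trend_coef=tuple(obj["trend_coef"]),
            size_factor_summary=obj.get("size_factor_summary", {}),
            pseudocount=obj["pseudocount"],
            shrink_scale=obj["shrink_scale"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationReference":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rlog_fit(training: CountMatrix) -> tuple[NormalizationReference, pd.DataFrame]:
    """Fit the rlog reference on a training batch and transform it.

    The shrink target is the feature's cross-sample mean of
    log2(count / size_factor + pseudocount); the shrink weight is
    1 / (1 + shrink_scale * alpha_trend(mu)), so low-count, high-noise
    features are pulled harder toward their mean.
    """
    counts = training.counts
    if counts.shape[1] < 2:
        raise ValueError("rlog_fit requires at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    log_geo = np.full(arr.shape[0], np.nan)
    log_geo[all_pos] = np.log(arr[all_pos]).mean(axis=1)
    log_geo = pd.Series(log_geo, index=counts.index)
    sf = _size_factors_vs_reference(counts, log_geo)
    norm_counts = arr / sf.to_numpy()[None, :]
    base_mean = norm_counts.mean(axis=1)

    disp = estimate_dispersions(training)
    a0, a1 = disp.trend_coef
    alpha_trend = np.maximum(a0 + a1 / np.maximum(base_mean, 1e-8), DISPERSION_FLOOR)

    values = np.log2(norm_counts + RLOG_PSEUDOCOUNT)
    target = values.mean(axis=1)
    ref = NormalizationReference(
        feature_ids=list(counts.index),
        log_geo_mean=log_geo,
        baseline_mean=pd.Series(target, index=counts.index),
        alpha_trend=pd.Series(alpha_trend, index=counts.index),
        trend_coef=(a0, a1),
        size_factor_summary={
            "n_training_samples": int(counts.shape[1]),
            "median": float(np.median(sf)),
        },
    )
    return ref, rlog_apply(training, ref)


def rlog_apply(test: CountMatrix, reference: NormalizationReference) -> pd.DataFrame:
    """Transform samples against a frozen training reference.

    Size factors are computed against the reference geometric means, and
    shrinkage targets/weights are the frozen training statistics; no
    quantity is re-estimated from the test samples.
    """
    counts = test.counts
    missing = set(counts.index) - set(reference.feature_ids)
    if missing:
        raise ValueError(f"features absent from reference: {sorted(missing)[:10]}")
    lg = reference.log_geo_mean.reindex(counts.index)
    sf = _size_factors_vs_reference(counts, lg)
    norm_counts = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    values = np.log2(norm_counts + reference.pseudocount)
    target = reference.baseline_mean.reindex(counts.index).to_numpy()
    alpha = reference.alpha_trend.reindex(counts.index).to_numpy()
    w = 1.0 / (1.0 + reference.shrink_scale * alpha)
    out = target[:, None] + w[:, None] * (values - target[:, None])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
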