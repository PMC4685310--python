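"""Covariate-adjusted observational models.

Linear and logistic regressions of outcomes on alcohol intake with the
study's confounder set, returning tidy effect records (beta or OR per
g/day with Wald 95% CIs), plus an exact sufficient-statistics regression
that reproduces a simple-regression slope and F from group means, SDs
and sizes alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr
from statsmodels.tools.sm_exceptions import (
    HessianInversionWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "EstimateRecord",
    "SufficientStatsFit",
    "fit_linear",
    "fit_logistic",
    "regression_from_sufficient_stats",
    "build_design",
]

Z_95 = 1.96  # normal multiplier for all 95% Wald intervals

#: Covariates expanded to reference-coded indicators (first level =
#: reference): 4-level education -> 3 indicators, 3-level smoking -> 2.
DEFAULT_CATEGORICAL = ("education", "smoking")


@dataclass
class EstimateRecord:
    """One fitted exposure effect.

    ``scale`` is "beta" (estimate, se, CI all on the outcome scale) or
    "or" (estimate and CI are odds ratios; ``se`` is the SE of the
    log-OR, on which the CI was built).
    """
    scale: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in ("beta", "or"):
            raise ValueError("scale must be 'beta' or 'or'")
        lo, est, hi = self.ci_low, self.estimate, self.ci_high
        if self.scale == "or":
            lo, est, hi = np.log(lo), np.log(est), np.log(hi)
        if not (lo <= est + 1e-12 and est <= hi + 1e-12):
            raise ValueError("estimate outside its confidence interval")


def build_design(df: pd.DataFrame, covars: Sequence[str],
                 categorical: Sequence[str] = DEFAULT_CATEGORICAL):
    """Design matrix (constant first) from covariate columns.

    Columns named in ``categorical`` are expanded into indicator
    variables with the lowest level as reference; all other columns
    enter as-is. Returns (matrix, column names).
    """
    cols = [np.ones(len(df))]
    names = ["const"]
    for c in covars:
        if c in categorical:
            levels = np.sort(pd.unique(df[c].dropna()))
            for lev in levels[1:]:
                cols.append((df[c] == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer complete cases than design columns")
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _complete_cases(cohort: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    missing = set(cols) - set(cohort.columns)
    if missing:
        raise KeyError(f"columns absent from cohort: {sorted(missing)}")
    return cohort[list(cols)].dropna()


def fit_linear(cohort: pd.DataFrame, outcome: str, exposure: str,
               covars: Sequence[str] = (),
               categorical: Sequence[str] = DEFAULT_CATEGORICAL) -> EstimateRecord:
    """OLS of a continuous outcome on the exposure plus covariates.

    Complete-case on the model variables; the record carries the
    exposure coefficient with SE, 95% Wald CI (+-1.96 SE) and a normal
    Wald p-value.
    """
    df = _complete_cases(cohort, [outcome, exposure, *covars])
    W, names = build_design(df, covars, categorical)
    X = np.column_stack([df[exposure].to_numpy(dtype=float), W])
    names = [exposure] + names
    _check_full_rank(X, names)
    y = df[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    est, se = float(fit.params[0]), float(fit.bse[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return EstimateRecord(
        scale="beta", estimate=est, se=se,
        ci_low=est - Z_95 * se, ci_high=est + Z_95 * se, pvalue=p,
        n=len(df),
        model={"outcome": outcome, "exposure": exposure,
               "covariates": list(covars), "family": "linear"})


def fit_logit_mle(y: np.ndarray, X: np.ndarray, maxiter: int = 100):
    """Logistic maximum likelihood with a quasi-Newton fallback.

    Newton/IRLS is the default; if its Hessian turns singular (it can on
    rare outcomes with skewed regressors) the fit is retried with
    L-BFGS. Perfect separation raises; non-convergence raises with the
    gradient norm.
    """
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", HessianInversionWarning)
        try:
            fit = model.fit(disp=0, maxiter=maxiter)
        except np.linalg.LinAlgError:
            fit = model.fit(method="lbfgs", disp=0, maxiter=10 * maxiter)
        if (not fit.mle_retvals["converged"]
                or not np.all(np.isfinite(fit.bse))):
            fit = model.fit(method="lbfgs", disp=0, maxiter=10 * maxiter)
    if not fit.mle_retvals["converged"]:
        raise RuntimeError(
            "logistic fit did not converge "
            f"(|grad| = {np.abs(model.score(fit.params)).max():.3g})")
    if not np.all(np.isfinite(fit.bse)):
        raise RuntimeError(
            "unstable logistic fit: information matrix not invertible "
            "(too few outcome events for the design?)")
    return fit


def fit_logistic(cohort: pd.DataFrame, outcome: str, exposure: str,
                 covars: Sequence[str] = (),
                 categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                 maxiter: int = 100) -> EstimateRecord:
    """Logistic regression of a binary outcome on the exposure.

    Maximum likelihood via iteratively reweighted least squares; the
    record carries OR = exp(coefficient) with a CI exponentiated from
    the log scale. Perfect separation and non-convergence raise.
    """
    df = _complete_cases(cohort, [outcome, exposure, *covars])
    y = df[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class among "
                         "complete cases")
    W, names = build_design(df, covars, categorical)
    X = np.column_stack([df[exposure].to_numpy(dtype=float), W])
    names = [exposure] + names
    _check_full_rank(X, names)
    try:
        fit = fit_logit_mle(y, X, maxiter=maxiter)
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise ValueError(f"perfect separation fitting {outcome!r}") from err
    b, se = float(fit.params[0]), float(fit.bse[0])
    p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else 0.0
    return EstimateRecord(
        scale="or", estimate=float(np.exp(b)), se=se,
        ci_low=float(np.exp(b - Z_95 * se)),
        ci_high=float(np.exp(b + Z_95 * se)), pvalue=p, n=len(df),
        model={"outcome": outcome, "exposure": exposure,
               "covariates": list(covars), "family": "logistic"})


@dataclass
class SufficientStatsFit:
    """Simple regression reconstructed exactly from group summaries."""
    slope: float
    intercept: float
    fstat: float
    df_resid: int
    pvalue: float


def regression_from_sufficient_stats(group_means, group_sds, group_ns,
                                     codes) -> SufficientStatsFit:
    """Simple regression of an outcome on coded groups from summaries.

    Given per-group means, SDs, sizes and numeric codes (e.g. allele
    counts 0/1/2), returns the slope and F statistic of the simple
    regression y ~ code computed exactly from the sufficient statistics;
    identical to the individual-level fit on any data with these group
    statistics (within-group variation is orthogonal to the coded
    regressor).
    """
    m = np.asarray(group_means, dtype=float)
    s = np.asarray(group_sds, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    c = np.asarray(codes, dtype=float)
    if not (m.shape == s.shape == n.shape == c.shape):
        raise ValueError("group summaries must have equal length")
    if m.size < 2:
        raise ValueError("need at least two groups")
    if np.any(s < 0) or np.any(n < 1):
        raise ValueError("SDs must be >= 0 and sizes >= 1")
    total = n.sum()
    sxx = float(n @ c ** 2 - (n @ c) ** 2 / total)
    if sxx == 0:
        raise ValueError("zero variance in group codes")
    sxy = float(n @ (c * m) - (n @ c) * (n @ m) / total)
    slope = sxy / sxx
    ybar = float(n @ m / total)
    cbar = float(n @ c / total)
    intercept = ybar - slope * cbar
    fitted = intercept + slope * c
    ss_within = float((n - 1) @ s ** 2)
    ss_lack = float(n @ (m - fitted) ** 2)
    ss_res = ss_within + ss_lack
    if ss_res == 0 and slope == 0:
        return SufficientStatsFit(0.0, intercept, 0.0, int(total - 2), 1.0)
    df_resid = int(total - 2)
    mse = ss_res / df_resid
    fstat = slope ** 2 * sxx / mse if mse > 0 else np.inf
    p = float(stats.f.sf(fstat, 1, df_resid)) if np.isfinite(fstat) else 0.0
    return SufficientStatsFit(slope, intercept, float(fstat), df_resid, p)
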