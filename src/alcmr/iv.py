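"""Instrumental-variable estimation for one-sample Mendelian randomisation.

Exactly-identified 2SLS for continuous outcomes (one genetic instrument,
one exposure, exogenous covariates; SEs from structural residuals), a
two-stage logistic estimator for binary outcomes (first-stage linear
prediction of the exposure substituted into a logistic second stage,
naive or bootstrap SEs), first-stage weak-instrument diagnostics
(partial F), and the genotype-by-sex interaction instrument for
population-level estimation when the exposure is sex-stratified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .estimators import (
    DEFAULT_CATEGORICAL,
    Z_95,
    EstimateRecord,
    _check_full_rank,
    _complete_cases,
    build_design,
    fit_logit_mle,
)

__all__ = [
    "IVEstimate",
    "FirstStage",
    "WeakInstrumentWarning",
    "first_stage",
    "tsls_linear",
    "two_stage_logistic",
    "interaction_iv",
    "recode_genotype",
]

#: Conventional first-stage partial-F threshold below which a
#: weak-instrument warning is attached.
WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """First-stage partial F below the weak-instrument threshold."""


@dataclass
class IVEstimate(EstimateRecord):
    """An IV effect record with first-stage diagnostics attached."""
    instrument: str = ""
    first_stage_f: float = np.nan
    first_stage_coef: float = np.nan
    se_mode: str = "analytic"
    bootstrap_reps: int = 0
    bootstrap_failures: int = 0
    weak_instrument: bool = False


@dataclass
class FirstStage:
    """First-stage fit: predicted exposure plus instrument diagnostics."""
    fitted: pd.Series
    coef: float
    se: float
    partial_f: float
    n: int
    resid: np.ndarray


def recode_genotype(genotype, coding: str = "additive") -> np.ndarray:
    """Recode 0/1/2 allele counts (additive, dominant or recessive)."""
    g = np.asarray(genotype, dtype=float)
    if coding == "additive":
        return g
    if coding == "dominant":
        return (g >= 1).astype(float)
    if coding == "recessive":
        return (g == 2).astype(float)
    raise ValueError("coding must be additive, dominant or recessive")


def _first_stage_arrays(x: np.ndarray, z: np.ndarray, W: np.ndarray,
                        names: Sequence[str]):
    """OLS of exposure on instrument + exogenous design; partial F = t^2."""
    if np.ptp(z) == 0:
        raise ValueError("monomorphic instrument: no variation to exploit")
    D = np.column_stack([z, W])
    _check_full_rank(D, ["instrument", *names])
    fit = sm.OLS(x, D).fit()
    coef, se = float(fit.params[0]), float(fit.bse[0])
    partial_f = (coef / se) ** 2 if se > 0 else np.inf
    return fit.fittedvalues, coef, se, float(partial_f), fit.resid


def first_stage(cohort: pd.DataFrame, exposure: str, instrument: str,
                covars: Sequence[str] = (),
                categorical: Sequence[str] = DEFAULT_CATEGORICAL) -> FirstStage:
    """Regress the exposure on the instrument plus covariates.

    Returns fitted exposure values (indexed by the complete-case rows),
    the instrument coefficient and its partial F (squared Wald t) — the
    standard weak-instrument diagnostic.
    """
    df = _complete_cases(cohort, [exposure, instrument, *covars])
    W, names = build_design(df, covars, categorical)
    x = df[exposure].to_numpy(dtype=float)
    z = df[instrument].to_numpy(dtype=float)
    fitted, coef, se, f, resid = _first_stage_arrays(x, z, W, names)
    return FirstStage(fitted=pd.Series(fitted, index=df.index),
                      coef=coef, se=se, partial_f=f, n=len(df), resid=resid)


def tsls_linear(cohort: pd.DataFrame, outcome: str, exposure: str,
                instrument: str, covars: Sequence[str] = (),
                categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                weak_f_threshold: float = WEAK_F_THRESHOLD,
                robust: bool = False,
                instrument_label: Optional[str] = None) -> IVEstimate:
    """Exactly-identified two-stage least squares.

    beta_hat = (Z'X)^-1 Z'y with Z = [instrument, covariates, 1] and
    X = [exposure, covariates, 1]; equal to the covariate-adjusted Wald
    ratio. The SE uses structural residuals y - X beta_hat (not
    second-stage OLS residuals) with homoskedastic variance by default;
    ``robust=True`` switches to the heteroskedasticity-robust sandwich.
    A first-stage partial F below ``weak_f_threshold`` attaches a
    :class:`WeakInstrumentWarning` rather than failing.
    """
    df = _complete_cases(cohort, [outcome, exposure, instrument, *covars])
    W, names = build_design(df, covars, categorical)
    y = df[outcome].to_numpy(dtype=float)
    x = df[exposure].to_numpy(dtype=float)
    z = df[instrument].to_numpy(dtype=float)

    _, fs_coef, _, fs_f, _ = _first_stage_arrays(x, z, W, names)

    X = np.column_stack([x, W])
    Z = np.column_stack([z, W])
    _check_full_rank(X, [exposure, *names])
    zx = Z.T @ X
    try:
        beta = np.linalg.solve(zx, Z.T @ y)
    except np.linalg.LinAlgError as err:
        raise ValueError("instrument orthogonal to exposure given "
                         "covariates: 2SLS not identified") from err
    resid = y - X @ beta
    n, k = X.shape
    zx_inv = np.linalg.inv(zx)
    if robust:
        meat = (Z * resid[:, None]).T @ (Z * resid[:, None])
        cov = zx_inv @ meat @ zx_inv.T
        cov *= n / (n - k)
    else:
        sigma2 = float(resid @ resid) / (n - k)
        cov = sigma2 * zx_inv @ (Z.T @ Z) @ zx_inv.T
    est, se = float(beta[0]), float(np.sqrt(cov[0, 0]))
    weak = fs_f < weak_f_threshold
    if weak:
        warnings.warn(
            f"first-stage partial F = {fs_f:.2f} below {weak_f_threshold}: "
            "weak instrument, IV estimate may be biased", WeakInstrumentWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
    return IVEstimate(
        scale="beta", estimate=est, se=se,
        ci_low=est - Z_95 * se, ci_high=est + Z_95 * se, pvalue=p, n=n,
        model={"outcome": outcome, "exposure": exposure,
               "covariates": list(covars), "family": "linear"},
        instrument=instrument_label or instrument,
        first_stage_f=fs_f, first_stage_coef=fs_coef,
        se_mode="robust" if robust else "analytic", weak_instrument=weak)


def _fit_second_stage_logit(y, xhat, W, maxiter=100):
    X2 = np.column_stack([xhat, W])
    fit = fit_logit_mle(y, X2, maxiter=maxiter)
    return float(fit.params[0]), float(fit.bse[0])


def two_stage_logistic(cohort: pd.DataFrame, outcome: str, exposure: str,
                       instrument: str, covars: Sequence[str] = (),
                       categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                       bootstrap: Optional[int] = None, seed=None,
                       weak_f_threshold: float = WEAK_F_THRESHOLD,
                       instrument_label: Optional[str] = None) -> IVEstimate:
    """Two-stage predictor-substitution logistic IV estimator.

    Stage 1: linear regression of the exposure on the instrument plus
    covariates. Stage 2: logistic regression of the binary outcome on
    the stage-1 fitted exposure plus the same covariates; the exposure
    coefficient is exponentiated to an OR per unit. The default SE comes
    from the second-stage information matrix and ignores first-stage
    uncertainty (``se_mode="naive"``); passing ``bootstrap=B`` resamples
    individuals and reruns both stages B times, replacing SE and CI
    (failed replicates are counted, not silently dropped).
    """
    df = _complete_cases(cohort, [outcome, exposure, instrument, *covars])
    y = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    W, names = build_design(df, covars, categorical)
    x = df[exposure].to_numpy(dtype=float)
    z = df[instrument].to_numpy(dtype=float)
    xhat, fs_coef, _, fs_f, _ = _first_stage_arrays(x, z, W, names)
    try:
        b, se_naive = _fit_second_stage_logit(y, xhat, W)
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise ValueError(f"perfect separation fitting {outcome!r}") from err

    n = len(df)
    se, se_mode, reps, failures = se_naive, "naive", 0, 0
    if bootstrap:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(int(bootstrap)):
            idx = rng.integers(0, n, size=n)
            yb, xb, zb, Wb = y[idx], x[idx], z[idx], W[idx]
            try:
                if np.ptp(zb) == 0 or len(np.unique(yb)) < 2:
                    raise ValueError("degenerate resample")
                xhat_b = _first_stage_arrays(xb, zb, Wb, names)[0]
                bb, _ = _fit_second_stage_logit(yb, xhat_b, Wb)
                draws.append(bb)
            except (ValueError, RuntimeError, PerfectSeparationError,
                    PerfectSeparationWarning, np.linalg.LinAlgError):
                failures += 1
        if len(draws) < 2:
            raise RuntimeError(
                f"bootstrap failed in {failures}/{bootstrap} replicates")
        se = float(np.std(draws, ddof=1))
        se_mode, reps = "bootstrap", len(draws)

    weak = fs_f < weak_f_threshold
    if weak:
        warnings.warn(
            f"first-stage partial F = {fs_f:.2f} below {weak_f_threshold}: "
            "weak instrument, IV estimate may be biased", WeakInstrumentWarning)
    p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else 0.0
    return IVEstimate(
        scale="or", estimate=float(np.exp(b)), se=se,
        ci_low=float(np.exp(b - Z_95 * se)),
        ci_high=float(np.exp(b + Z_95 * se)), pvalue=p, n=n,
        model={"outcome": outcome, "exposure": exposure,
               "covariates": list(covars), "family": "logistic"},
        instrument=instrument_label or instrument,
        first_stage_f=fs_f, first_stage_coef=fs_coef,
        se_mode=se_mode, bootstrap_reps=reps,
        bootstrap_failures=failures, weak_instrument=weak)


def interaction_iv(cohort: pd.DataFrame, outcome: str, exposure: str,
                   genotype: str = "genotype", sex: str = "sex",
                   covars: Sequence[str] = (),
                   categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                   family: Optional[str] = None,
                   main_effects: Sequence[str] = ("genotype", "sex"),
                   genotype_coding: str = "additive",
                   bootstrap: Optional[int] = None, seed=None,
                   weak_f_threshold: float = WEAK_F_THRESHOLD) -> IVEstimate:
    """Population-level IV using the genotype-by-sex product instrument.

    When the exposure is concentrated in one sex, genotype alone is a
    weak population-level instrument; the product genotype x
    male-indicator recovers the genotype effect where the exposure
    actually varies. The genotype and sex main effects enter as
    exogenous covariates (``main_effects``) so the instrument carries
    only the interaction. Continuous outcomes go through
    :func:`tsls_linear`, binary through :func:`two_stage_logistic`.
    """
    needed = {outcome, exposure, genotype, sex, *covars}
    missing = needed - set(cohort.columns)
    if missing:
        raise KeyError(f"columns absent from cohort: {sorted(missing)}")
    work = cohort.copy()
    g = recode_genotype(work[genotype].to_numpy(), genotype_coding)
    work["_g"] = g
    if len(np.unique(g[~np.isnan(g)])) < 2:
        raise ValueError("genotype must take at least two values")
    if "sex" in main_effects and work[sex].dropna().nunique() < 2:
        raise ValueError(
            "single-sex cohort: the genotype-by-sex instrument is not "
            "identified; use the genotype instrument directly")
    work["genotype_x_sex"] = g * work[sex].to_numpy(dtype=float)

    exog = list(covars)
    if "genotype" in main_effects:
        exog.append("_g")
    if "sex" in main_effects:
        exog.append(sex)

    if family is None:
        vals = set(pd.unique(work[outcome].dropna()))
        family = "logistic" if vals <= {0, 1, 0.0, 1.0} else "linear"
    label = f"{genotype}*{sex}"
    if family == "linear":
        return tsls_linear(work, outcome, exposure, "genotype_x_sex",
                           covars=exog, categorical=categorical,
                           weak_f_threshold=weak_f_threshold,
                           instrument_label=label)
    return two_stage_logistic(work, outcome, exposure, "genotype_x_sex",
                              covars=exog, categorical=categorical,
                              bootstrap=bootstrap, seed=seed,
                              weak_f_threshold=weak_f_threshold,
                              instrument_label=label)
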