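"""Stratified cohort summaries and classical tests.

Mean ± SE / %(N) group summaries, t / chi-squared / one-way ANOVA tests,
allele-frequency and Hardy–Weinberg diagnostics for a single variant,
sufficient-statistics helpers, and the collider-stratification
interaction test (genotype x drinking-history product term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "GroupSummary",
    "allele_frequency",
    "hwe_test",
    "group_summary",
    "two_sample_t",
    "chisq_independence",
    "oneway_anova",
    "collider_interaction_test",
    "weighted_mean_from_groups",
]


@dataclass
class TestResult:
    """A classical test: statistic, degrees of freedom, p-value."""
    statistic: float
    df: float
    pvalue: float
    test: str

    def __post_init__(self):
        if not np.isnan(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class GroupSummary:
    """Per-stratum summary: mean±SE for continuous, %(N) for categorical."""
    stratum: str
    n: int
    continuous: pd.DataFrame = field(default_factory=pd.DataFrame)
    categorical: dict = field(default_factory=dict)


def allele_frequency(n_gg: int, n_ga: int, n_aa: int) -> float:
    """A-allele frequency from genotype counts: (het + 2 hom) / 2N."""
    counts = np.array([n_gg, n_ga, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype count")
    total = counts.sum()
    if total == 0:
        raise ValueError("all genotype counts are zero")
    return float((n_ga + 2 * n_aa) / (2 * total))


def hwe_test(n_gg: int, n_ga: int, n_aa: int) -> TestResult:
    """1-df chi-squared goodness of fit to Hardy–Weinberg proportions.

    Expected counts use the estimated allele frequency; one degree of
    freedom remains after estimating it. A monomorphic sample fits HWE
    trivially: statistic 0, p 1, with a warning.
    """
    n = n_gg + n_ga + n_aa
    if n < 3:
        raise ValueError("need at least 3 individuals")
    p = allele_frequency(n_gg, n_ga, n_aa)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic sample: HWE test degenerate")
        return TestResult(0.0, 1, 1.0, "hwe_chi2")
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    observed = np.array([n_gg, n_ga, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return TestResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), "hwe_chi2")


def weighted_mean_from_groups(means: Sequence[float],
                              ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of group means: sum(n*m)/sum(n)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape:
        raise ValueError("means and ns must have equal length")
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float(means @ ns / ns.sum())


def group_summary(cohort: pd.DataFrame,
                  strata: Sequence[str],
                  continuous: Optional[Sequence[str]] = None,
                  categorical: Optional[Sequence[str]] = None) -> list:
    """One GroupSummary per stratum of the grouping columns.

    Continuous variables are summarised as mean and SE = SD/sqrt(n) on
    non-missing values; categorical variables as per-level count and
    percentage of the non-missing denominator. A single-observation
    stratum has missing SE; an empty stratum is skipped by groupby.
    """
    if not set(strata).issubset(cohort.columns):
        missing = set(strata) - set(cohort.columns)
        raise KeyError(f"grouping columns absent: {sorted(missing)}")
    continuous = list(continuous or [])
    categorical = list(categorical or [])
    out = []
    for key, grp in cohort.groupby(list(strata), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        label = ", ".join(f"{c}={v}" for c, v in zip(strata, key))
        rows = []
        for var in continuous:
            vals = grp[var].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({"variable": var, "n": n, "mean": mean, "se": se})
        cat = {}
        for var in categorical:
            vals = grp[var].dropna()
            denom = len(vals)
            counts = vals.value_counts().sort_index()
            cat[var] = pd.DataFrame({
                "level": counts.index,
                "count": counts.values,
                "percent": 100.0 * counts.values / denom if denom else np.nan,
            })
        out.append(GroupSummary(
            stratum=label, n=len(grp),
            continuous=pd.DataFrame(rows, columns=["variable", "n", "mean", "se"]),
            categorical=cat))
    return out


def two_sample_t(x, y) -> TestResult:
    """Two-sample t-test (pooled variance), as used for sex contrasts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        return TestResult(0.0, len(x) + len(y) - 2, 1.0, "t")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), len(x) + len(y) - 2, float(p), "t")


def chisq_independence(table) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    if np.all(table == table[0, 0]):
        df = (table.shape[0] - 1) * (table.shape[1] - 1)
        return TestResult(0.0, df, 1.0, "chi2")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue), "chi2")


def oneway_anova(*groups) -> TestResult:
    """One-way ANOVA F test across two or more groups."""
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[~np.isnan(g)] for g in clean]
    if len(clean) < 2 or any(len(g) < 2 for g in clean):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(g, ddof=1) == 0 for g in clean):
        means = [np.mean(g) for g in clean]
        if np.ptp(means) == 0:
            raise ValueError("degenerate: zero variance within and between groups")
    f, p = stats.f_oneway(*clean)
    df1 = len(clean) - 1
    df2 = sum(len(g) for g in clean) - len(clean)
    return TestResult(float(f), (df1, df2), float(p), "anova_f")


def collider_interaction_test(cohort: pd.DataFrame, outcome: str,
                              genotype: str = "genotype",
                              history: str = "ever_drinker",
                              binary: Optional[bool] = None,
                              method: str = "wald") -> TestResult:
    """Test for collider-stratification bias across drinking history.

    Fits outcome ~ genotype + history + genotype:history (linear model
    for a continuous outcome, logistic for binary) and tests the product
    coefficient — a genotype effect that differs between never- and
    ever-drinkers signals that conditioning on drinking history opens a
    collider path. ``method`` selects the Wald z test (default) or a
    likelihood-ratio test.
    """
    cols = [outcome, genotype, history]
    df = cohort[cols].dropna()
    g = df[genotype].to_numpy(dtype=float)
    h = df[history].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("genotype is constant: interaction not identified")
    if len(np.unique(h)) < 2:
        raise ValueError("both drinking-history groups must be non-empty")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    design = sm.add_constant(np.column_stack([g, h, g * h]))

    if binary:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            se_prod = np.sqrt(fit.cov_params()[3, 3])
            if not fit.mle_retvals["converged"] or se_prod > 1e3:
                return TestResult(np.nan, 1, np.nan, "collider_wald_separated")
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            return TestResult(np.nan, 1, np.nan, "collider_wald_separated")
        if method == "lr":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reduced = sm.Logit(y, design[:, :3]).fit(disp=0, maxiter=100)
            lr = 2 * (fit.llf - reduced.llf)
            return TestResult(float(lr), 1, float(stats.chi2.sf(lr, 1)), "collider_lr")
        z = fit.params[3] / se_prod
        return TestResult(float(z), 1, float(2 * stats.norm.sf(abs(z))), "collider_wald")

    fit = sm.OLS(y, design).fit()
    if method == "lr":
        reduced = sm.OLS(y, design[:, :3]).fit()
        n = len(y)
        lr = n * np.log(reduced.ssr / fit.ssr)
        return TestResult(float(lr), 1, float(stats.chi2.sf(lr, 1)), "collider_lr")
    z = fit.params[3] / fit.bse[3]
    return TestResult(float(z), 1, float(2 * stats.norm.sf(abs(z))), "collider_wald")
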