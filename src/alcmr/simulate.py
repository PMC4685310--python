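"""Synthetic cohort generator.

Generates individual-level cohorts with the statistical structure a
one-sample Mendelian-randomisation analysis of alcohol intake assumes:

* a single biallelic variant (rs671-like) in Hardy–Weinberg equilibrium,
  coded additively as 0/1/2 copies of the low-intake A allele;
* strongly sex-stratified, zero-inflated alcohol intake whose mean falls
  with each A-allele copy, calibrated per (sex, genotype) cell;
* drinking-history categories (never / former / current) consistent with
  intake (current drinkers have positive intake, others zero);
* demographic confounders (age, residential area, education, physical
  activity, smoking) and simulated genotypic principal components;
* continuous and binary cardiovascular outcomes driven by a configurable
  causal alcohol effect, observed covariates, and a latent confounder
  that biases naive observational estimates but not the IV estimates.

The latent confounder enters the nonzero-intake draw through a Gaussian
copula, which correlates intake with the confounder while leaving the
calibrated Gamma marginal of intake untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit, logit

from .derive import friedewald_ldl, waist_hip_ratio

__all__ = [
    "OutcomeSpec",
    "SimParams",
    "simulate_genotypes",
    "simulate_cohort",
    "table2_preset",
    "null_effects",
    "expected_alcohol_mean",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

SEXES = ("female", "male")  # row index of every (2, 3) grid = sex code
GENOTYPES = ("GG", "GA", "AA")

# Covariate columns an OutcomeSpec may reference in covariate_effects.
# age_c is age centred at 52 years.
_COVARIATE_COLUMNS = (
    "age_c", "area", "activity",
    "smoke_former", "smoke_current",
    "educ_mid", "educ_high", "educ_univ",
)

#: Fixed, versioned cohort CSV header.
COHORT_COLUMNS = [
    "id", "sex", "genotype", "alcohol_gday",
    "current_drinker", "former_drinker", "never_drinker", "ever_drinker",
    "age", "area", "education", "activity", "smoking",
    "pc1", "pc2", "pc3", "pc4", "pc5",
    "sbp", "dbp", "bmi", "waist", "hip", "whr",
    "glucose", "tc", "hdl", "tg", "ldl", "ggt",
    "hypertension", "cvd", "chd", "diabetes",
]


@dataclass
class OutcomeSpec:
    """Generative specification of one outcome.

    Parameters
    ----------
    family : {"linear", "logistic"}
        Continuous outcome with Gaussian noise, or Bernoulli via a
        logistic link on the same linear predictor.
    alcohol_effect : float
        Causal effect per g/day of alcohol on the linear predictor
        (mmHg, mg/dL, ... for linear outcomes; log-odds for logistic;
        log units when ``log_scale``).
    target_by_sex : (float, float)
        Calibration target, indexed (female, male): the marginal mean
        (natural scale) for continuous outcomes, the prevalence for
        binary ones. The intercept is solved from this target given the
        realised covariate and intake means, so generated cohorts match
        it on average.
    residual_sd : float
        Gaussian residual SD (log-scale SD when ``log_scale``); ignored
        for logistic outcomes.
    confounder_effect : float
        Coefficient on the latent standard-normal confounder U, which is
        also copula-correlated with intake.
    covariate_effects : dict
        Coefficients on observed covariate codings (keys from
        ``age_c``, ``area``, ``activity``, ``smoke_former``,
        ``smoke_current``, ``educ_mid``, ``educ_high``, ``educ_univ``).
    log_scale : bool
        Generate on the log scale and exponentiate (right-skewed
        biomarkers: glucose, triglycerides, GGT).
    """

    family: str
    alcohol_effect: float
    target_by_sex: tuple
    residual_sd: float = 1.0
    confounder_effect: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    log_scale: bool = False

    def __post_init__(self):
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "linear" and self.residual_sd < 0:
            raise ValueError("negative residual SD")
        unknown = set(self.covariate_effects) - set(_COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariate codings: {sorted(unknown)}")


@dataclass
class SimParams:
    """Full generative specification of a synthetic cohort.

    All (2, 3) grids are indexed [sex, genotype] with sex 0=female,
    1=male and genotype columns GG, GA, AA (0, 1, 2 A-allele copies).
    """

    n_total: int = 7152
    prop_male: float = 3365 / 7152
    maf_A: float = 0.16
    # marginal mean alcohol g/day per cell
    intake_mean: np.ndarray = field(
        default_factory=lambda: np.array([[1.70, 0.41, 0.02],
                                          [23.78, 7.28, 0.41]]))
    # P(intake == 0) per cell = 1 - current-drinker proportion
    intake_zero_prob: np.ndarray = field(
        default_factory=lambda: np.array([[0.684, 0.875, 0.99],
                                          [0.171, 0.496, 0.905]]))
    # P(never drinker) per cell; former = zero_prob - never_prob
    never_prob: np.ndarray = field(
        default_factory=lambda: np.array([[0.644, 0.857, 0.99],
                                          [0.070, 0.393, 0.832]]))
    intake_dispersion: float = 0.8  # Gamma shape of nonzero intake
    confounding_rho: float = 0.3    # copula corr(latent U, nonzero intake)
    age_mean: float = 52.3
    age_sd: float = 8.9
    age_range: tuple = (39.0, 70.0)
    urban_prob_by_sex: tuple = (0.492, 0.569)
    education_probs_by_sex: np.ndarray = field(
        default_factory=lambda: np.array([[0.451, 0.233, 0.259, 0.057],
                                          [0.197, 0.224, 0.362, 0.217]]))
    activity_prob_by_sex: tuple = (0.962, 0.910)
    # smoking never/former/current
    smoking_probs_by_sex: np.ndarray = field(
        default_factory=lambda: np.array([[0.950, 0.027, 0.023],
                                          [0.195, 0.363, 0.442]]))
    pc_count: int = 5
    pc_sd: float = 0.2
    pc_genotype_assoc: float = 0.0  # shift of pc2 per A-allele copy
    outcomes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.intake_mean = np.asarray(self.intake_mean, dtype=float)
        self.intake_zero_prob = np.asarray(self.intake_zero_prob, dtype=float)
        self.never_prob = np.asarray(self.never_prob, dtype=float)
        self.education_probs_by_sex = np.asarray(
            self.education_probs_by_sex, dtype=float)
        self.smoking_probs_by_sex = np.asarray(
            self.smoking_probs_by_sex, dtype=float)
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        for name, frac in (("prop_male", self.prop_male), ("maf_A", self.maf_A)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, grid in (("intake_mean", self.intake_mean),
                           ("intake_zero_prob", self.intake_zero_prob),
                           ("never_prob", self.never_prob)):
            if grid.shape != (2, 3):
                raise ValueError(f"{name} must be a 2x3 (sex x genotype) grid")
        if np.any(self.intake_mean < 0):
            raise ValueError("intake means must be >= 0")
        for name, grid in (("intake_zero_prob", self.intake_zero_prob),
                           ("never_prob", self.never_prob)):
            if np.any(grid < 0) or np.any(grid > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.intake_dispersion <= 0:
            raise ValueError("intake_dispersion must be positive")
        if not -1.0 < self.confounding_rho < 1.0:
            raise ValueError("confounding_rho must lie in (-1, 1)")
        if self.pc_sd < 0 or self.age_sd <= 0:
            raise ValueError("negative scale parameter")
        if self.pc_count < 0:
            raise ValueError("pc_count must be >= 0")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("intake_mean", "intake_zero_prob", "never_prob",
                    "education_probs_by_sex", "smoking_probs_by_sex"):
            d[key] = np.asarray(d[key]).tolist()
        d["age_range"] = list(self.age_range)
        d["urban_prob_by_sex"] = list(self.urban_prob_by_sex)
        d["activity_prob_by_sex"] = list(self.activity_prob_by_sex)
        d["outcomes"] = {
            name: {**asdict(spec), "target_by_sex": list(spec.target_by_sex)}
            for name, spec in self.outcomes.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["outcomes"] = {
            name: OutcomeSpec(**{**spec,
                                 "target_by_sex": tuple(spec["target_by_sex"])})
            for name, spec in d.get("outcomes", {}).items()
        }
        for key in ("age_range", "urban_prob_by_sex", "activity_prob_by_sex"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Draw n additive genotypes (0/1/2 copies) under Hardy–Weinberg.

    Two alleles are drawn independently per individual with A-allele
    probability ``maf``, so genotype frequencies converge to
    ((1-p)^2, 2p(1-p), p^2).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(np.int64)


def expected_alcohol_mean(params: SimParams, sex: int) -> float:
    """Population mean alcohol g/day for one sex under HWE genotype mix."""
    p = params.maf_A
    freqs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    return float(freqs @ params.intake_mean[sex])


def _truncnorm_ppf(u, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _categorical(rng, probs_row, n):
    """Draw n categories from a probability row (renormalised)."""
    p = np.asarray(probs_row, dtype=float)
    p = p / p.sum()
    return rng.choice(len(p), size=n, p=p)


def simulate_cohort(params: SimParams, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a cohort table under ``params``.

    Deterministic given (params, seed); ``seed=None`` uses
    ``params.seed``. Returns a DataFrame with the fixed
    :data:`COHORT_COLUMNS` header (principal-component columns adapt to
    ``pc_count``).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_total

    sex = (rng.random(n) < params.prop_male).astype(np.int64)
    genotype = simulate_genotypes(n, params.maf_A, rng)

    # drinking status: current / former / never, from per-cell probabilities
    p_zero = params.intake_zero_prob[sex, genotype]
    p_never = params.never_prob[sex, genotype]
    p_former = np.clip(p_zero - p_never, 0.0, None)
    p_current = 1.0 - p_zero
    u_status = rng.random(n)
    current = u_status < p_current
    former = ~current & (u_status < p_current + p_former)
    never = ~current & ~former

    # latent confounder, copula-coupled with the nonzero intake draw
    latent_u = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    rho = params.confounding_rho
    z_mix = rho * latent_u + np.sqrt(1.0 - rho ** 2) * eps
    quantile = stats.norm.cdf(z_mix)

    k = params.intake_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero_mean = np.where(p_current > 0,
                                params.intake_mean[sex, genotype] / np.where(p_current > 0, p_current, 1.0),
                                0.0)
    alcohol = np.zeros(n)
    alcohol[current] = stats.gamma.ppf(quantile[current], k) * (nonzero_mean[current] / k)

    # confounders
    age = _truncnorm_ppf(rng.random(n), params.age_mean, params.age_sd,
                         *params.age_range)
    area = (rng.random(n) < np.asarray(params.urban_prob_by_sex)[sex]).astype(np.int64)
    education = np.empty(n, dtype=np.int64)
    activity = np.empty(n, dtype=np.int64)
    smoking = np.empty(n, dtype=np.int64)
    for s in (0, 1):
        mask = sex == s
        m = int(mask.sum())
        if m == 0:
            continue
        education[mask] = _categorical(rng, params.education_probs_by_sex[s], m)
        activity[mask] = (rng.random(m) < params.activity_prob_by_sex[s]).astype(np.int64)
        smoking[mask] = _categorical(rng, params.smoking_probs_by_sex[s], m)

    pcs = rng.normal(0.0, params.pc_sd, size=(n, params.pc_count))
    if params.pc_count >= 2 and params.pc_genotype_assoc != 0.0:
        pcs[:, 1] += params.pc_genotype_assoc * (genotype - 2 * params.maf_A)

    covariates = {
        "age_c": age - 52.0,
        "area": area.astype(float),
        "activity": activity.astype(float),
        "smoke_former": (smoking == 1).astype(float),
        "smoke_current": (smoking == 2).astype(float),
        "educ_mid": (education == 1).astype(float),
        "educ_high": (education == 2).astype(float),
        "educ_univ": (education == 3).astype(float),
    }

    data = {
        "id": np.arange(1, n + 1),
        "sex": sex,
        "genotype": genotype,
        "alcohol_gday": alcohol,
        "current_drinker": current.astype(np.int64),
        "former_drinker": former.astype(np.int64),
        "never_drinker": never.astype(np.int64),
        "ever_drinker": (current | former).astype(np.int64),
        "age": np.round(age, 1),
        "area": area,
        "education": education,
        "activity": activity,
        "smoking": smoking,
    }
    for j in range(params.pc_count):
        data[f"pc{j + 1}"] = pcs[:, j]

    # outcomes: intercepts solved per sex from the calibration target and
    # the realised means of intake, the latent confounder and covariates
    for name, spec in params.outcomes.items():
        lp = spec.alcohol_effect * alcohol + spec.confounder_effect * latent_u
        for col, beta in spec.covariate_effects.items():
            lp = lp + beta * covariates[col]
        intercept = np.zeros(n)
        for s in (0, 1):
            mask = sex == s
            if not mask.any():
                continue
            drift = float(np.mean(lp[mask]))
            target = spec.target_by_sex[s]
            if spec.family == "logistic":
                intercept[mask] = logit(target) - drift
            elif spec.log_scale:
                intercept[mask] = (np.log(target)
                                   - 0.5 * spec.residual_sd ** 2 - drift)
            else:
                intercept[mask] = target - drift
        lp = lp + intercept
        if spec.family == "logistic":
            data[name] = (rng.random(n) < expit(lp)).astype(np.int64)
        elif spec.log_scale:
            data[name] = np.exp(lp + rng.normal(0.0, spec.residual_sd, n))
        else:
            # physical measurements are non-negative; at calibrated scales
            # the floor binds with vanishing probability
            vals = lp + rng.normal(0.0, spec.residual_sd, n)
            data[name] = np.maximum(vals, 0.0)

    cohort = pd.DataFrame(data)
    if {"tc", "hdl", "tg"}.issubset(cohort.columns):
        cohort["ldl"] = friedewald_ldl(cohort["tc"], cohort["hdl"], cohort["tg"])
    if {"waist", "hip"}.issubset(cohort.columns):
        cohort["whr"] = waist_hip_ratio(cohort["waist"], cohort["hip"])

    ordered = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in ordered]
    return cohort[ordered + extra]


# -- presets -----------------------------------------------------------

# IV point estimates used as the default generative causal effects
# (per g/day; log-odds for binary outcomes).
TABLE5_MALE_EFFECTS = {
    "sbp": 0.159, "dbp": 0.085, "bmi": 0.012, "waist": 0.060,
    "hip": 0.005, "glucose": 0.0010, "tc": -0.040, "hdl": 0.170,
    "tg": 0.002, "ggt": 0.008,
    "hypertension": float(np.log(1.020)), "cvd": float(np.log(0.990)),
    "chd": float(np.log(0.994)), "diabetes": float(np.log(1.018)),
}


def _default_outcomes(effects: dict) -> dict:
    """Outcome specs calibrated to published cohort marginal summaries."""
    e = effects
    return {
        "sbp": OutcomeSpec("linear", e["sbp"], (124.1, 125.7), 18.0,
                           confounder_effect=3.0,
                           covariate_effects={"age_c": 0.35}),
        "dbp": OutcomeSpec("linear", e["dbp"], (80.2, 83.4), 11.0,
                           confounder_effect=2.0,
                           covariate_effects={"age_c": 0.15}),
        "bmi": OutcomeSpec("linear", e["bmi"], (24.90, 24.24), 3.0,
                           confounder_effect=0.5),
        "waist": OutcomeSpec("linear", e["waist"], (81.8, 83.7), 8.0,
                             confounder_effect=2.0,
                             covariate_effects={"age_c": 0.10}),
        "hip": OutcomeSpec("linear", e["hip"], (93.7, 93.6), 6.0,
                           confounder_effect=1.0),
        "glucose": OutcomeSpec("linear", e["glucose"], (85.0, 90.6), 0.18,
                               confounder_effect=0.05, log_scale=True,
                               covariate_effects={"age_c": 0.002}),
        "tc": OutcomeSpec("linear", e["tc"], (191.8, 192.0), 35.0,
                          confounder_effect=3.0,
                          covariate_effects={"age_c": 0.30}),
        "hdl": OutcomeSpec("linear", e["hdl"], (45.5, 43.8), 10.0,
                           confounder_effect=1.0),
        "tg": OutcomeSpec("linear", e["tg"], (150.2, 179.9), 0.5,
                          confounder_effect=0.12, log_scale=True),
        "ggt": OutcomeSpec("linear", e["ggt"], (19.0, 55.4), 0.8,
                           confounder_effect=0.10, log_scale=True),
        "hypertension": OutcomeSpec("logistic", e["hypertension"],
                                    (0.373, 0.417), confounder_effect=0.30,
                                    covariate_effects={"age_c": 0.05}),
        "cvd": OutcomeSpec("logistic", e["cvd"], (0.026, 0.039),
                           confounder_effect=0.20,
                           covariate_effects={"age_c": 0.05}),
        "chd": OutcomeSpec("logistic", e["chd"], (0.013, 0.021),
                           confounder_effect=0.20,
                           covariate_effects={"age_c": 0.05}),
        "diabetes": OutcomeSpec("logistic", e["diabetes"], (0.060, 0.083),
                                confounder_effect=0.20,
                                covariate_effects={"age_c": 0.03}),
    }


def table2_preset(n_total: int = 7152, effects: str = "iv",
                  seed: int = 0) -> SimParams:
    """SimParams calibrated to published genotype-stratified cohort summaries.

    A-allele frequency 0.16, male fraction 3365/7152, per-cell intake
    means (g/day, sex x genotype)::

        female: 1.70  0.41  0.02
        male:  23.78  7.28  0.41

    with abstention and never-drinker probabilities taken from the
    per-cell current/former/never drinker proportions.

    Parameters
    ----------
    effects : {"iv", "null"}
        "iv" uses the male IV point estimates as the common causal
        alcohol effects (the fixed-effect assumption of one effect in
        both sexes); "null" sets every alcohol effect to zero.
    """
    if effects == "iv":
        eff = TABLE5_MALE_EFFECTS
    elif effects == "null":
        eff = {k: 0.0 for k in TABLE5_MALE_EFFECTS}
    else:
        raise ValueError("effects must be 'iv' or 'null'")
    return SimParams(n_total=n_total, outcomes=_default_outcomes(eff),
                     seed=seed)


def null_effects(params: SimParams) -> SimParams:
    """Copy of ``params`` with every causal alcohol effect set to zero."""
    out = SimParams.from_dict(params.to_dict())
    for spec in out.outcomes.values():
        spec.alcohol_effect = 0.0
    return out


# -- CSV round trip ----------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV; missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    return pd.read_csv(path)
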