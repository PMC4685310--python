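"""End-to-end analysis pipeline.

Runs the full chain — simulate or load a cohort, derive phenotypes,
stratified descriptives and genotype diagnostics, observational OLS and
logistic models per sex, genotype-instrument IV per sex, population-level
genotype-by-sex interaction IV, and men-vs-women fixed-effect
heterogeneity — and writes one tidy CSV per stage plus a run log.
Deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .derive import add_derived_columns
from .describe import (
    allele_frequency,
    collider_interaction_test,
    group_summary,
    hwe_test,
)
from .estimators import EstimateRecord, fit_linear, fit_logistic
from .heterogeneity import cochran_q
from .iv import IVEstimate, interaction_iv, tsls_linear, two_stage_logistic
from .simulate import SimParams, simulate_cohort, table2_preset, write_cohort_csv

__all__ = ["AnalysisConfig", "run_full_analysis", "make_fixtures"]

#: (outcome column, family) analysed by default; log_* columns are the
#: natural-log transforms added by the derive stage.
DEFAULT_OUTCOMES = [
    ("hypertension", "logistic"), ("cvd", "logistic"),
    ("chd", "logistic"), ("diabetes", "logistic"),
    ("sbp", "linear"), ("dbp", "linear"), ("bmi", "linear"),
    ("waist", "linear"), ("hip", "linear"), ("whr", "linear"),
    ("log_glucose", "linear"), ("tc", "linear"), ("hdl", "linear"),
    ("ldl", "linear"), ("log_tg", "linear"),
]

DEFAULT_COVARIATES = ["age", "area", "education", "activity", "smoking"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Exactly one of ``input_csv`` / ``sim_params`` supplies the cohort.
    PC adjustment enters only the IV models; the per-sex lists default
    to the second PC in men and the fourth in women (the components
    associated with genotype in the source cohorts), and their union in
    the whole-population interaction-IV model.
    """
    input_csv: Optional[str] = None
    sim_params: Optional[SimParams] = None
    outcomes: Sequence = tuple(DEFAULT_OUTCOMES)
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES)
    exposure: str = "alcohol_gday"
    genotype: str = "genotype"
    pcs_male: Sequence[str] = ("pc2",)
    pcs_female: Sequence[str] = ("pc4",)
    pcs_all: Sequence[str] = ("pc2", "pc4")
    bootstrap: Optional[int] = None
    #: minimum outcome events (and non-events) per stratum for a
    #: logistic model; rarer outcomes are reported as not estimable
    #: rather than risking quasi-separated fits
    min_events: int = 50
    output_dir: str = "alcmr_results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim_params" in raw and raw["sim_params"] is not None:
            raw["sim_params"] = SimParams.from_dict(raw["sim_params"])
        if "outcomes" in raw:
            raw["outcomes"] = [tuple(o) for o in raw["outcomes"]]
        return cls(**raw)


def _skipped_row(stratum, outcome, family, n_events, min_events) -> dict:
    return {"stratum": stratum, "outcome": outcome, "family": family,
            "scale": "or", "estimate": np.nan, "se": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "pvalue": np.nan,
            "n": 0, "note": f"skipped: {n_events} events < {min_events}"}


def _too_rare(cohort, outcome, family, min_events) -> Optional[int]:
    """Events count if a binary outcome is too rare/common to model."""
    if family != "logistic":
        return None
    y = cohort[outcome].dropna()
    events = int(min(y.sum(), (1 - y).sum()))
    return events if events < min_events else None


def _record_row(rec: EstimateRecord, stratum: str) -> dict:
    row = {
        "stratum": stratum,
        "outcome": rec.model.get("outcome"),
        "family": rec.model.get("family"),
        "scale": rec.scale,
        "estimate": rec.estimate,
        "se": rec.se,
        "ci_low": rec.ci_low,
        "ci_high": rec.ci_high,
        "pvalue": rec.pvalue,
        "n": rec.n,
        "note": "",
    }
    if isinstance(rec, IVEstimate):
        row.update(instrument=rec.instrument,
                   first_stage_f=rec.first_stage_f,
                   first_stage_coef=rec.first_stage_coef,
                   se_mode=rec.se_mode,
                   weak_instrument=int(rec.weak_instrument))
    return row


def _heterogeneity_column(table: pd.DataFrame) -> pd.DataFrame:
    """Join a men-vs-women Cochran's Q p-value onto a stratified table."""
    rows = []
    for outcome, grp in table.groupby("outcome", sort=False):
        male = grp[(grp["stratum"] == "male") & grp["estimate"].notna()]
        female = grp[(grp["stratum"] == "female") & grp["estimate"].notna()]
        if len(male) == 1 and len(female) == 1:
            scale = male["scale"].iloc[0]
            res = cochran_q(
                [male["estimate"].iloc[0], female["estimate"].iloc[0]],
                [male["se"].iloc[0], female["se"].iloc[0]], scale=scale)
            rows.append({"outcome": outcome, "heterogeneity_q": res.q,
                         "heterogeneity_p": res.pvalue})
    het = pd.DataFrame(rows)
    return table.merge(het, on="outcome", how="left")


def _fit_observational(cohort, outcome, family, config) -> EstimateRecord:
    if family == "logistic":
        return fit_logistic(cohort, outcome, config.exposure,
                            covars=list(config.covariates))
    return fit_linear(cohort, outcome, config.exposure,
                      covars=list(config.covariates))


def _fit_iv(cohort, outcome, family, config, pcs) -> IVEstimate:
    covars = list(config.covariates) + list(pcs)
    if family == "logistic":
        return two_stage_logistic(cohort, outcome, config.exposure,
                                  config.genotype, covars=covars,
                                  bootstrap=config.bootstrap,
                                  seed=config.seed)
    return tsls_linear(cohort, outcome, config.exposure, config.genotype,
                       covars=covars)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write its outputs under ``config.output_dir``.

    Returns the result tables as a dict of DataFrames (keys: cohort,
    descriptives, genotype_diagnostics, collider_tests, ols, iv_by_sex,
    iv_interaction). Any stage failure aborts with the stage name and
    the offending model.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- cohort -------------------------------------------------------
    if config.input_csv is not None:
        cohort = pd.read_csv(config.input_csv)
    elif config.sim_params is not None:
        cohort = simulate_cohort(config.sim_params, seed=config.seed)
    else:
        raise ValueError("config needs input_csv or sim_params")
    cohort = add_derived_columns(cohort)
    write_cohort_csv(cohort, outdir / "cohort.csv")

    results = {"cohort": cohort}
    log = {
        "alcmr_version": __version__,
        "seed": config.seed,
        "n_records": int(len(cohort)),
        "n_male": int((cohort["sex"] == 1).sum()),
        "n_female": int((cohort["sex"] == 0).sum()),
        "models": [],
    }

    continuous = [o for o, fam in config.outcomes if fam == "linear"]
    categorical = [o for o, fam in config.outcomes if fam == "logistic"]

    # --- descriptives -------------------------------------------------
    stage = "descriptives"
    try:
        rows = []
        for gs in group_summary(cohort, ["sex", "genotype"],
                                continuous=[config.exposure, *continuous],
                                categorical=categorical):
            for _, r in gs.continuous.iterrows():
                rows.append({"stratum": gs.stratum, "variable": r["variable"],
                             "kind": "continuous", "n": r["n"],
                             "mean": r["mean"], "se": r["se"],
                             "level": np.nan, "count": np.nan,
                             "percent": np.nan})
            for var, tab in gs.categorical.items():
                for _, r in tab.iterrows():
                    rows.append({"stratum": gs.stratum, "variable": var,
                                 "kind": "categorical", "n": gs.n,
                                 "mean": np.nan, "se": np.nan,
                                 "level": r["level"], "count": r["count"],
                                 "percent": r["percent"]})
        descriptives = pd.DataFrame(rows)
        descriptives.to_csv(outdir / "descriptives.csv", index=False)
        results["descriptives"] = descriptives

        diag_rows = []
        for sex_code, label in ((1, "male"), (0, "female")):
            sub = cohort[cohort["sex"] == sex_code]
            counts = [int((sub[config.genotype] == g).sum()) for g in (0, 1, 2)]
            freq = allele_frequency(*counts)
            hwe = hwe_test(*counts)
            diag_rows.append({"stratum": label, "n_GG": counts[0],
                              "n_GA": counts[1], "n_AA": counts[2],
                              "allele_frequency": freq,
                              "hwe_chi2": hwe.statistic,
                              "hwe_p": hwe.pvalue})
        diagnostics = pd.DataFrame(diag_rows)
        diagnostics.to_csv(outdir / "genotype_diagnostics.csv", index=False)
        results["genotype_diagnostics"] = diagnostics
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- collider-bias interaction tests (male stratum) ---------------
    stage = "collider_tests"
    try:
        male = cohort[cohort["sex"] == 1]
        col_rows = []
        if male["ever_drinker"].nunique() > 1:
            for outcome, fam in config.outcomes:
                res = collider_interaction_test(
                    male, outcome, genotype=config.genotype,
                    history="ever_drinker", binary=(fam == "logistic"))
                col_rows.append({"outcome": outcome,
                                 "statistic": res.statistic,
                                 "pvalue": res.pvalue, "test": res.test})
        collider = pd.DataFrame(col_rows)
        collider.to_csv(outdir / "collider_tests.csv", index=False)
        results["collider_tests"] = collider
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- observational models per sex ---------------------------------
    stage = "ols"
    ols_rows = []
    for sex_code, label in ((1, "male"), (0, "female")):
        sub = cohort[cohort["sex"] == sex_code]
        for outcome, fam in config.outcomes:
            rare = _too_rare(sub, outcome, fam, config.min_events)
            if rare is not None:
                ols_rows.append(_skipped_row(label, outcome, fam, rare,
                                             config.min_events))
                continue
            try:
                rec = _fit_observational(sub, outcome, fam, config)
            except Exception as err:
                raise RuntimeError(
                    f"stage {stage!r} failed for outcome {outcome!r} "
                    f"({label}): {err}") from err
            ols_rows.append(_record_row(rec, label))
            log["models"].append({"stage": stage, "outcome": outcome,
                                  "stratum": label, "n_used": rec.n})
    ols = _heterogeneity_column(pd.DataFrame(ols_rows))
    ols.to_csv(outdir / "ols_estimates.csv", index=False)
    results["ols"] = ols

    # --- genotype-instrument IV per sex --------------------------------
    stage = "iv_by_sex"
    iv_rows = []
    for sex_code, label, pcs in ((1, "male", config.pcs_male),
                                 (0, "female", config.pcs_female)):
        sub = cohort[cohort["sex"] == sex_code]
        for outcome, fam in config.outcomes:
            rare = _too_rare(sub, outcome, fam, config.min_events)
            if rare is not None:
                iv_rows.append(_skipped_row(label, outcome, fam, rare,
                                            config.min_events))
                continue
            try:
                rec = _fit_iv(sub, outcome, fam, config, pcs)
            except Exception as err:
                raise RuntimeError(
                    f"stage {stage!r} failed for outcome {outcome!r} "
                    f"({label}): {err}") from err
            iv_rows.append(_record_row(rec, label))
            log["models"].append({"stage": stage, "outcome": outcome,
                                  "stratum": label, "n_used": rec.n,
                                  "first_stage_f": rec.first_stage_f})
    iv_by_sex = _heterogeneity_column(pd.DataFrame(iv_rows))
    iv_by_sex.to_csv(outdir / "iv_by_sex.csv", index=False)
    results["iv_by_sex"] = iv_by_sex

    # --- population-level interaction IV -------------------------------
    stage = "iv_interaction"
    int_rows = []
    covars = list(config.covariates) + list(config.pcs_all)
    for outcome, fam in config.outcomes:
        rare = _too_rare(cohort, outcome, fam, config.min_events)
        if rare is not None:
            int_rows.append(_skipped_row("all", outcome, fam, rare,
                                         config.min_events))
            continue
        try:
            rec = interaction_iv(cohort, outcome, config.exposure,
                                 genotype=config.genotype, sex="sex",
                                 covars=covars, family=fam,
                                 bootstrap=config.bootstrap,
                                 seed=config.seed)
        except Exception as err:
            raise RuntimeError(
                f"stage {stage!r} failed for outcome {outcome!r}: "
                f"{err}") from err
        int_rows.append(_record_row(rec, "all"))
        log["models"].append({"stage": stage, "outcome": outcome,
                              "stratum": "all", "n_used": rec.n,
                              "first_stage_f": rec.first_stage_f})
    iv_interaction = pd.DataFrame(int_rows)
    iv_interaction.to_csv(outdir / "iv_interaction.csv", index=False)
    results["iv_interaction"] = iv_interaction

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["log"] = log
    return results


def make_fixtures(outdir, seed: int = 0, sizes=(500, 7152)) -> list:
    """Write small preset cohort CSVs for tests and documentation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in sizes:
        params = table2_preset(n_total=n, seed=seed)
        cohort = add_derived_columns(simulate_cohort(params))
        path = outdir / f"cohort_n{n}.csv"
        write_cohort_csv(cohort, path)
        paths.append(path)
    return paths
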