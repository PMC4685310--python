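"""Deterministic derived-phenotype rules.

Pure, vectorised functions applied identically to simulated and
user-supplied cohorts: Friedewald LDL, natural-log transforms of skewed
biomarkers, the hypertension case definition, and waist-to-hip ratio.
Missing inputs propagate to missing outputs; invalid inputs raise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "friedewald_ldl",
    "log_transform",
    "define_hypertension",
    "waist_hip_ratio",
    "add_derived_columns",
]

#: Triglyceride ceiling (mg/dL) above which the Friedewald estimate is
#: unreliable and LDL is set missing.
TG_FRIEDEWALD_LIMIT = 400.0


def friedewald_ldl(tc, hdl, tg):
    """Estimate LDL cholesterol (mg/dL) as TC − HDL − TG/5.

    Returns NaN where TG ≥ 400 mg/dL (the estimate is invalid there) or
    where any input is missing. Raises ``ValueError`` on negative inputs.

    Parameters
    ----------
    tc, hdl, tg : scalar or array-like
        Total cholesterol, HDL cholesterol and triglycerides in mg/dL.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, arr in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"negative {name} concentration")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(tg >= TG_FRIEDEWALD_LIMIT, np.nan, ldl)
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


def log_transform(values, name: str = "value"):
    """Natural logarithm of strictly positive values; NaN propagates.

    Zero or negative entries raise ``ValueError`` naming the first
    offending record (glucose, GGT and triglycerides are physically
    positive, so such a value indicates corrupt input, not censoring).
    """
    arr = np.asarray(values, dtype=float)
    bad = ~np.isnan(arr) & (arr <= 0)
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        raise ValueError(
            f"log transform of {name} requires positive values; "
            f"record {idx} has {np.atleast_1d(arr)[idx]!r}"
        )
    out = np.log(arr)
    if out.ndim == 0:
        return float(out)
    return out


def define_hypertension(sbp, dbp, self_report, meds, *, inclusive: bool = False):
    """Hypertension case definition.

    A participant is hypertensive if they self-report a diagnosis, use
    blood-pressure medication, or have measured SBP > 140 mmHg or
    DBP > 90 mmHg. The blood-pressure cut-offs are strict inequalities by
    default; ``inclusive=True`` switches to the clinical ≥140/≥90
    convention. Records with all four inputs missing yield NaN.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    sr = np.asarray(self_report, dtype=float)
    md = np.asarray(meds, dtype=float)
    if np.any(sbp[~np.isnan(sbp)] < 0) or np.any(dbp[~np.isnan(dbp)] < 0):
        raise ValueError("negative blood pressure")
    if inclusive:
        bp_high = (sbp >= 140) | (dbp >= 90)
    else:
        bp_high = (sbp > 140) | (dbp > 90)
    positive = bp_high | (sr == 1) | (md == 1)
    all_missing = np.isnan(sbp) & np.isnan(dbp) & np.isnan(sr) & np.isnan(md)
    out = np.where(all_missing, np.nan, positive.astype(float))
    if out.ndim == 0:
        return float(out)
    return out


def waist_hip_ratio(waist, hip):
    """Waist circumference divided by hip circumference (both cm).

    Missing inputs propagate; a zero hip circumference raises.
    """
    waist = np.asarray(waist, dtype=float)
    hip = np.asarray(hip, dtype=float)
    if np.any(hip[~np.isnan(hip)] == 0):
        raise ValueError("hip circumference of 0 cm")
    out = waist / hip
    if out.ndim == 0:
        return float(out)
    return out


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append/refresh derived columns on a cohort table, in place rules.

    Adds ``ldl`` (Friedewald), ``whr``, and natural-log columns
    ``log_glucose``, ``log_tg``, ``log_ggt`` where the source columns
    exist. Returns a new DataFrame; the input is not modified.
    """
    out = cohort.copy()
    if {"tc", "hdl", "tg"}.issubset(out.columns):
        out["ldl"] = friedewald_ldl(out["tc"], out["hdl"], out["tg"])
    if {"waist", "hip"}.issubset(out.columns):
        out["whr"] = waist_hip_ratio(out["waist"], out["hip"])
    for src, dst in (("glucose", "log_glucose"), ("tg", "log_tg"), ("ggt", "log_ggt")):
        if src in out.columns:
            out[dst] = log_transform(out[src], name=src)
    return out
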