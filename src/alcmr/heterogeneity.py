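"""Fixed-effect heterogeneity between stratum estimates.

Cochran's Q compares stratum-specific effect estimates (e.g. men vs
women) under the fixed-effect null of a common true effect, with
inverse-variance pooling. Odds-ratio estimates are compared on the
log-OR scale. Includes CI-to-SE reconstruction for working from
published 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import Z_95

__all__ = ["HeterogeneityResult", "se_from_ci", "cochran_q"]


@dataclass
class HeterogeneityResult:
    """Cochran's Q with the inverse-variance pooled estimate."""
    q: float
    df: int
    pvalue: float
    pooled: float
    pooled_se: float
    scale: str

    def __post_init__(self):
        if self.q < 0 or not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("invalid heterogeneity result")


def se_from_ci(lower: float, upper: float, scale: str = "beta") -> float:
    """Standard error reconstructed from a 95% Wald interval.

    SE = (upper - lower) / (2 * 1.96). For ``scale="or"`` the bounds are
    odds ratios and the SE is returned on the log-OR scale.
    """
    if upper < lower:
        raise ValueError("upper CI bound below lower bound")
    if scale == "or":
        if lower <= 0:
            raise ValueError("OR bounds must be positive")
        lower, upper = np.log(lower), np.log(upper)
    elif scale != "beta":
        raise ValueError("scale must be 'beta' or 'or'")
    return float((upper - lower) / (2 * Z_95))


def cochran_q(estimates, ses, scale: str = "beta") -> HeterogeneityResult:
    """Cochran's Q test of estimate homogeneity across k strata.

    Q = sum w_i (b_i - b_pooled)^2 with w_i = 1/se_i^2 and the
    inverse-variance-weighted pooled estimate; p from chi-squared(k-1).
    For ``scale="or"`` the estimates are odds ratios (log-transformed
    internally) and ``ses`` are already on the log-OR scale; the pooled
    estimate is returned as an OR.
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.shape != se.shape or b.size < 2:
        raise ValueError("need k >= 2 estimates with matching SEs")
    if np.any(se <= 0):
        raise ValueError("SEs must be positive")
    if scale == "or":
        if np.any(b <= 0):
            raise ValueError("OR estimates must be positive")
        b = np.log(b)
    elif scale != "beta":
        raise ValueError("scale must be 'beta' or 'or'")
    w = 1.0 / se ** 2
    pooled = float(w @ b / w.sum())
    q = float(w @ (b - pooled) ** 2)
    df = b.size - 1
    p = float(stats.chi2.sf(q, df))
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    if scale == "or":
        pooled = float(np.exp(pooled))
    return HeterogeneityResult(q=q, df=df, pvalue=p, pooled=pooled,
                               pooled_se=pooled_se, scale=scale)
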