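"""Shared simulation helpers for the test suite.

Small controlled data-generating processes, independent of the package's
cohort generator, used as oracles for the estimation machinery.
"""

import numpy as np
import pandas as pd
from scipy.special import expit

MAF = 0.16


def iv_frame(n, beta, f_target, rng, sigma_x=10.0, confounding=0.5,
             binary=False, intercept=0.0, u_effect=0.5):
    """Linear-IV data with a chosen expected first-stage F.

    z ~ Binomial(2, MAF); x = a z + confounded noise with total residual
    SD ``sigma_x``; a is solved from E[F] ~= 1 + n a^2 var(z) / sigma_x^2.
    y = beta x + confounder + noise (or Bernoulli via a logistic link),
    so OLS is biased but the instrument is valid.
    """
    z = rng.binomial(2, MAF, n).astype(float)
    var_z = 2 * MAF * (1 - MAF)
    a = sigma_x * np.sqrt(max(f_target - 1.0, 0.0) / (n * var_z))
    u = rng.standard_normal(n)
    e_sd = sigma_x * np.sqrt(1.0 - confounding ** 2)
    x = a * z + confounding * sigma_x * u + e_sd * rng.standard_normal(n)
    if binary:
        p = expit(intercept + beta * x + u_effect * u)
        y = (rng.random(n) < p).astype(float)
    else:
        y = beta * x + 2.0 * u + rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


def collider_frame(n, rng, interaction=0.0, binary=False):
    """Genotype + drinking-history data with a controllable interaction.

    Genotype is HWE at MAF; history (ever-drinker) probability falls
    with allele count, as in the study; the outcome has a common
    genotype slope in both strata plus ``interaction`` extra slope among
    never-drinkers.
    """
    g = rng.binomial(2, MAF, n).astype(float)
    p_ever = np.array([0.93, 0.61, 0.17])[g.astype(int)]
    h = (rng.random(n) < p_ever).astype(float)
    lp = 0.3 * g + 0.8 * h + interaction * g * (1 - h)
    if binary:
        y = (rng.random(n) < expit(lp - 1.0)).astype(float)
    else:
        y = lp + rng.standard_normal(n)
    return pd.DataFrame({"y": y, "genotype": g, "ever_drinker": h})
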