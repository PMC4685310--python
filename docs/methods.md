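# Methods

## Synthetic cohort model

The generator (`alcmr.simulate`) emulates a middle-aged East Asian
cohort in which a single *ALDH2*-like variant drives alcohol intake.

**Genotype.** Two alleles drawn independently per individual with
A-allele probability 0.16, giving Hardy–Weinberg genotype frequencies
((1−p)², 2p(1−p), p²) and an additive 0/1/2 coding. No linkage
structure, arrays or imputation dosages are simulated — the instrument
is a single variant by design.

**Alcohol intake.** Intake is zero-inflated and calibrated per
(sex, genotype) cell. The calibration preset (`table2_preset`) uses the
six published cell means (men 23.78/7.28/0.41 g/day across GG/GA/AA,
women 1.70/0.41/0.02) together with per-cell current/former/never
drinker proportions. The published summaries are internally consistent
with "current drinkers drink, others do not": in every cell the
marginal mean ≈ P(current) × (mean among current drinkers), so the
preset sets P(intake = 0) = 1 − P(current) and gives current drinkers a
Gamma intake with mean = cell mean / P(current). Drinking history is a
three-level categorical (current/former/never) from the same cell
proportions; never-drinkers and former drinkers have zero current
intake, `ever = current ∨ former`.

The shared Gamma shape k = 0.8 was chosen so the male within-genotype
intake variance matches the SD reconstruction from the published cell
SEs (weighted within-cell variance ≈ 730 vs ≈ 754 (g/day)²), which
puts the simulated male first-stage partial F near the published 262.
A single shared shape cannot simultaneously match the female cells:
real female intake is far more dispersed relative to its mean (rare
heavy drinkers), so the simulated female first-stage F runs around 100
rather than the published 38. Analyses of the female stratum in this
package therefore see a *stronger* instrument than the source cohort —
conservative for weak-instrument behaviour in men, optimistic in women.

**Confounding.** A latent standard-normal confounder U enters every
outcome's linear predictor and is coupled to the nonzero intake draw
through a Gaussian copula (default correlation 0.3). The copula leaves
the calibrated Gamma marginal of intake untouched, so observational
estimates are biased while the genotype — independent of U — remains a
valid instrument. Observed confounders (age, area, education, activity,
smoking) are drawn from sex-specific marginals matching the published
cohort proportions; by default they do not influence intake (the
variant showed no association with lifestyle factors), but several
carry modest outcome effects so that covariate adjustment is exercised.

**Principal components.** `pc_count` (default 5) independent Gaussians
with SD 0.2 (matching the published SE × √n scale), uncorrelated with
genotype by default; `pc_genotype_assoc` shifts PC2 per allele copy to
emulate mild population stratification and exercise the PC-adjustment
path.

**Outcomes.** Continuous outcomes are linear in intake, covariates and
U with Gaussian noise; glucose, triglycerides and GGT are generated on
the log scale and exponentiated (the −σ²/2 lognormal correction keeps
the natural-scale mean on target); binary outcomes use a logistic link
on the same linear predictor — matching the logistic analysis models.
Intercepts are solved per sex from the target marginal mean/prevalence
given the realised covariate and intake means, so generated cohorts
match the published marginals on average. Physical measurements are
floored at zero (binding with negligible probability at calibrated
scales). LDL is **derived** from generated TC/HDL/TG by the Friedewald
rule rather than given its own causal effect; the implied LDL effect,
≈ −0.28 mg/dL per g/day under the default effects, is negative as in
the source estimates. WHR is derived as waist/hip.

**Default causal effects** are the male IV point estimates (e.g.
SBP +0.159 mmHg per g/day, hypertension OR 1.020), applied to both
sexes under the fixed-effect assumption of a common causal effect; a
null preset (`effects="null"`, `null_effects`) zeroes them for
calibration studies.

What passing tests on these cohorts do **not** show about real data:
real intake is self-reported with measurement error; outcome errors are
not Gaussian; confounding is not a single latent factor; genotype
imputation error, missing-data mechanisms and sampling design are not
modelled.

## Derived phenotypes

Friedewald LDL = TC − HDL − TG/5 (mg/dL), missing at TG ≥ 400 mg/dL.
Hypertension = self-report ∨ medication ∨ SBP > 140 ∨ DBP > 90, with
*strict* inequalities following the verbatim case definition; an
`inclusive` flag switches to the clinical ≥140/≥90 convention.
Log transforms use the natural logarithm (the choice only rescales
regression coefficients). Any derived value with a missing input is
missing; models are complete-case.

## Estimators

**Design matrices.** Education (4 levels) and smoking (3 levels:
never/former/current) enter as reference-coded indicators against their
lowest level; area and activity are binary. Smoking is 3-level by
default (a binary override is a one-line change to the covariate list).
Rank deficiency is detected by pivoted QR and reported with the names
of the collinear columns.

**Wald intervals** use the fixed normal multiplier 1.96 everywhere
(rather than t quantiles); at the cohort sizes targeted the difference
is negligible, and it makes CI reconstruction by
SE = (upper − lower)/3.92 exact and self-consistent with the
heterogeneity module.

**Logistic fits** are maximum likelihood via Newton/IRLS with an
L-BFGS fallback when the Hessian is numerically singular; perfect
separation and non-invertible information matrices raise informative
errors. ORs and their CIs are constructed on the log scale.

**2SLS** is restricted to the exactly-identified case (one instrument,
one exposure): β̂ = (Z'X)⁻¹Z'y, equal to the covariate-adjusted Wald
ratio. The variance uses *structural* residuals y − Xβ̂ with a
homoskedastic σ̂² (n−k denominator); a heteroskedasticity-robust
sandwich is available behind a flag. A first-stage partial F (squared
Wald t of the instrument) below 10 attaches a warning, never a failure
— F is reported alongside every IV estimate.

**Two-stage logistic** substitutes the first-stage fitted exposure into
a logistic second stage. The default SE is the naive second-stage
information-matrix SE, which ignores first-stage uncertainty — the mode
that most plausibly matches published IV odds-ratio CIs of this design;
the nonparametric bootstrap (individuals resampled, both stages re-run;
failed replicates counted and reported) is the honest alternative and
is systematically at least as wide. Both modes are recorded on the
estimate. As a predictor-substitution estimator it recovers conditional
ORs only approximately: with large residual exposure variance the OR is
attenuated toward 1 (noticeably so for ORs ≳ 1.05 per unit at intake
SDs near 30 g/day). The recovery tests therefore run it within its
validity regime (modest residual exposure variance) and this
attenuation is a documented limitation, not a bug.

**Interaction instrument.** Z = genotype × male-indicator with genotype
and sex main effects entered as exogenous covariates, so identification
comes only from the product term. With a single-sex cohort the model is
not identified and the error directs users to the genotype instrument.
Genotype coding is additive by default; dominant/recessive recodings
are provided for sensitivity analysis. PCs enter IV models only (they
exist to absorb population structure of the genotype), defaulting to
PC2 in men, PC4 in women, and their union in the whole-population
model.

**Cochran's Q** pools by inverse variance and compares strata under the
common-effect null with χ²(k−1). OR heterogeneity is computed on the
log-OR scale — standard meta-analytic practice and the scale on which
published heterogeneity p-values reproduce. Degenerate inputs (zero
SEs, single stratum) raise.

**Collider interaction test.** Outcome ~ genotype + history +
genotype·history (linear or logistic), Wald z on the product term by
default with a likelihood-ratio alternative. Separation in the logistic
case is flagged with a missing p rather than an exception, since the
test is run in batch over many outcomes.

**Sufficient-statistics regression** reproduces the simple-regression
slope and F exactly from group means, SDs, sizes and codes: the
between-group cross-products give the slope; the residual sum of
squares is within-group SS plus lack-of-fit SS. It exists as an
independent oracle connecting published cell summaries to first-stage
strength (the male cells give F ≈ 266, bracketing the published
covariate-adjusted 262 within ~2%).

## Pipeline

`run_full_analysis` chains simulate/load → derive → descriptives and
genotype diagnostics → collider tests (male stratum) → per-sex OLS →
per-sex genotype IV → whole-population interaction IV → men-vs-women
heterogeneity joined onto the stratified tables, writing one tidy CSV
per stage plus a JSON run log (seed, version, per-model complete-case
n; no timestamps, so identical config+seed reproduce byte-identical
outputs). Binary outcomes with fewer than `min_events` (default 50)
events or non-events in a stratum are reported as not estimable rather
than fitted — rare-event logistic fits with ~11 design columns below
that are numerically meaningless — and heterogeneity rows are computed
only where both strata were estimable. Configuration is a single YAML
document mirroring `AnalysisConfig`.

## Numerical and testing choices

Tolerances: exact algebraic identities are asserted at 1e-8–1e-10;
Monte-Carlo recoveries at 3 MC SEs of the replicate mean/median; size
and coverage properties at ±3 binomial SEs of the nominal level (93–97%
for 95% intervals at 500 replicates). Simulation sizes (e.g. 500
replicates at n = 2000 for the 2SLS grid, 200 replicates for OR
recovery, 24–30 preset cohorts for whole-pipeline recoveries) keep the
default suite in the low minutes while leaving the MC error well below
the asserted tolerances. Median (not mean) bias is asserted for 2SLS
because the just-identified estimator is a ratio without finite
moments. Percentage summaries are reported at one decimal, means/SEs at
full precision internally.

## Known limitations

- Strictly one-sample, one-instrument: no over-identification,
  MR-Egger, weighted-median or two-sample summary-statistic methods.
- No robust/clustered SEs in observational models, no nonlinear
  exposure terms.
- Predictor-substitution OR attenuation as described above.
- The synthetic female stratum has a stronger instrument than the
  cohort it emulates (shared intake dispersion).
- No multiple-testing correction across outcomes (none is applied in
  the analysis design the pipeline mirrors).
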