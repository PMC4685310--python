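import warnings

import numpy as np
import pandas as pd
import pytest

from alcmr.derive import add_derived_columns
from alcmr.estimators import fit_linear
from alcmr.iv import (
    WeakInstrumentWarning,
    first_stage,
    interaction_iv,
    recode_genotype,
    tsls_linear,
    two_stage_logistic,
)
from alcmr.simulate import simulate_cohort, table2_preset
from _sim import iv_frame

IV_COVARS = ["age", "area", "education", "activity", "smoking"]


class TestFirstStage:
    def test_preset_male_strength(self, preset_cohort):
        """On the calibrated cohort the male-stratum instrument is
        strong: partial F in the low hundreds."""
        male = preset_cohort[preset_cohort.sex == 1]
        fs = first_stage(male, "alcohol_gday", "genotype",
                         covars=IV_COVARS + ["pc2"])
        assert 100 < fs.partial_f < 600
        assert fs.coef < 0  # intake falls with each A allele

    def test_null_instrument_f_near_one(self):
        """An instrument unrelated to the exposure has mean partial F
        close to 1 (its null F distribution)."""
        rng = np.random.default_rng(5)
        fs = []
        for _ in range(300):
            z = rng.binomial(2, 0.16, 500).astype(float)
            x = rng.standard_normal(500)
            df = pd.DataFrame({"x": x, "z": z})
            fs.append(first_stage(df, "x", "z").partial_f)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.2)

    def test_identity_instrument_fits_exactly(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "z": x})
        fs = first_stage(df, "x", "z")
        np.testing.assert_allclose(fs.fitted, x, atol=1e-10)

    def test_monomorphic_instrument_raises(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50), "z": np.ones(50)})
        with pytest.raises(ValueError, match="monomorphic"):
            first_stage(df, "x", "z")


class TestTSLS:
    def test_ratio_oracle_small_instances(self):
        """Without covariates the 2SLS estimate equals the covariance
        ratio cov(z,y)/cov(z,x) to 1e-10, on 100 random small problems."""
        rng = np.random.default_rng(99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WeakInstrumentWarning)
            for _ in range(100):
                n = int(rng.integers(20, 51))
                df = iv_frame(n, beta=rng.normal(), f_target=rng.uniform(2, 30),
                              rng=rng)
                rec = tsls_linear(df, "y", "x", "z")
                num = np.cov(df.z, df.y, ddof=1)[0, 1]
                den = np.cov(df.z, df.x, ddof=1)[0, 1]
                assert rec.estimate == pytest.approx(num / den, abs=1e-10 * max(1, abs(num / den)))

    def test_identity_instrument_equals_ols(self, rng):
        df = iv_frame(500, beta=0.7, f_target=100, rng=rng)
        df["zx"] = df["x"]
        rec_iv = tsls_linear(df, "y", "x", "zx")
        rec_ols = fit_linear(df, "y", "x")
        assert rec_iv.estimate == pytest.approx(rec_ols.estimate, abs=1e-10)

    def test_weak_instrument_warns_not_fails(self, rng):
        df = iv_frame(300, beta=0.2, f_target=3, rng=rng)
        with pytest.warns(WeakInstrumentWarning):
            rec = tsls_linear(df, "y", "x", "z")
        assert rec.weak_instrument

    def test_removes_confounding_bias(self):
        """OLS is biased by the shared confounder; 2SLS is not."""
        rng = np.random.default_rng(8)
        iv_err, ols_err = [], []
        for _ in range(50):
            df = iv_frame(4000, beta=0.3, f_target=200, rng=rng)
            iv_err.append(tsls_linear(df, "y", "x", "z").estimate - 0.3)
            ols_err.append(fit_linear(df, "y", "x").estimate - 0.3)
        assert abs(np.mean(iv_err)) < 0.02
        assert abs(np.mean(ols_err)) > 0.05

    def test_structural_se_and_robust_close_under_homoskedasticity(self, rng):
        df = iv_frame(5000, beta=0.3, f_target=150, rng=rng)
        plain = tsls_linear(df, "y", "x", "z")
        robust = tsls_linear(df, "y", "x", "z", robust=True)
        assert plain.estimate == pytest.approx(robust.estimate)
        assert robust.se == pytest.approx(plain.se, rel=0.15)


class TestTwoStageLogistic:
    def test_null_or_centred_on_one(self):
        rng = np.random.default_rng(31)
        log_ors = []
        for _ in range(100):
            df = iv_frame(2000, beta=0.0, f_target=150, rng=rng, binary=True)
            rec = two_stage_logistic(df, "y", "x", "z")
            log_ors.append(np.log(rec.estimate))
        se_mean = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert abs(np.mean(log_ors)) < 3 * se_mean

    def test_preset_hypertension_or_recovery(self):
        """On male preset cohorts the hypertension two-stage OR lands
        near the generative value 1.020 per g/day (median over seeds,
        within Monte-Carlo error)."""
        log_ors = []
        for seed in range(60):
            cohort = simulate_cohort(table2_preset(), seed=seed)
            male = cohort[cohort.sex == 1]
            rec = two_stage_logistic(male, "hypertension", "alcohol_gday",
                                     "genotype", covars=IV_COVARS + ["pc2"])
            log_ors.append(np.log(rec.estimate))
        med = np.median(log_ors)
        mc_se = 1.2533 * np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert abs(med - np.log(1.020)) < 3 * mc_se

    def test_bootstrap_se_at_least_naive(self):
        """Resampling both stages captures first-stage uncertainty the
        naive SE ignores, so bootstrap SE >= naive SE almost always."""
        rng = np.random.default_rng(12)
        wider = 0
        trials = 15
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WeakInstrumentWarning)
            for i in range(trials):
                df = iv_frame(800, beta=0.05, f_target=20, rng=rng,
                              binary=True)
                naive = two_stage_logistic(df, "y", "x", "z")
                boot = two_stage_logistic(df, "y", "x", "z", bootstrap=200,
                                          seed=100 + i)
                wider += boot.se >= naive.se
                assert boot.se_mode == "bootstrap"
        assert wider / trials >= 0.9

    def test_single_class_raises(self, rng):
        df = iv_frame(100, beta=0.0, f_target=50, rng=rng)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="single class"):
            two_stage_logistic(df, "y", "x", "z")


class TestInteractionIV:
    def test_all_male_reduces_to_genotype_iv(self, preset_cohort):
        """With one sex and no main effects the product instrument is
        the genotype itself: estimates agree exactly."""
        male = preset_cohort[preset_cohort.sex == 1]
        covars = IV_COVARS + ["pc2"]
        via_interaction = interaction_iv(male, "sbp", "alcohol_gday",
                                         covars=covars, main_effects=())
        direct = tsls_linear(male, "sbp", "alcohol_gday", "genotype",
                             covars=covars)
        assert via_interaction.estimate == pytest.approx(direct.estimate,
                                                         abs=1e-10)
        assert via_interaction.se == pytest.approx(direct.se, rel=1e-10)

    def test_single_sex_with_main_effect_raises(self, preset_cohort):
        male = preset_cohort[preset_cohort.sex == 1]
        with pytest.raises(ValueError, match="genotype instrument"):
            interaction_iv(male, "sbp", "alcohol_gday", covars=IV_COVARS)

    def test_population_estimate_tracks_male_estimate(self, preset_cohort):
        """With female exposure near zero, the population-level
        interaction-IV estimate agrees with the male genotype-IV
        estimate within 3 SEs."""
        pop = interaction_iv(preset_cohort, "sbp", "alcohol_gday",
                             covars=IV_COVARS + ["pc2", "pc4"])
        male = preset_cohort[preset_cohort.sex == 1]
        direct = tsls_linear(male, "sbp", "alcohol_gday", "genotype",
                             covars=IV_COVARS + ["pc2"])
        pooled_se = np.hypot(pop.se, direct.se)
        assert abs(pop.estimate - direct.estimate) < 3 * pooled_se
        assert pop.first_stage_f > 100

    def test_null_effect_recovered(self):
        from alcmr.simulate import null_effects
        params = null_effects(table2_preset(seed=23))
        cohort = add_derived_columns(simulate_cohort(params))
        rec = interaction_iv(cohort, "hdl", "alcohol_gday",
                             covars=IV_COVARS + ["pc2", "pc4"])
        assert abs(rec.estimate) < 3 * rec.se

    def test_binary_outcome_dispatches_to_logistic(self, preset_cohort):
        rec = interaction_iv(preset_cohort, "hypertension", "alcohol_gday",
                             covars=IV_COVARS + ["pc2", "pc4"])
        assert rec.scale == "or"
        assert rec.instrument == "genotype*sex"


def test_recode_genotype():
    g = [0, 1, 2]
    np.testing.assert_array_equal(recode_genotype(g, "dominant"), [0, 1, 1])
    np.testing.assert_array_equal(recode_genotype(g, "recessive"), [0, 0, 1])
    with pytest.raises(ValueError):
        recode_genotype(g, "codominant")
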