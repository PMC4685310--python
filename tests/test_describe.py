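import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from alcmr.describe import (
    allele_frequency,
    chisq_independence,
    collider_interaction_test,
    group_summary,
    hwe_test,
    oneway_anova,
    two_sample_t,
    weighted_mean_from_groups,
)
from _sim import collider_frame


class TestAlleleFrequency:
    def test_study_counts(self):
        # genotype counts from the male and female strata
        assert allele_frequency(2395, 874, 96) == pytest.approx(0.1584, abs=5e-4)
        assert round(100 * allele_frequency(2395, 874, 96)) == 16
        assert round(100 * allele_frequency(2684, 1003, 100)) == 16

    @pytest.mark.parametrize("counts,expected", [
        ((50, 0, 0), 0.0), ((0, 0, 50), 1.0), ((0, 10, 0), 0.5),
    ])
    def test_extremes(self, counts, expected):
        assert allele_frequency(*counts) == expected

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            allele_frequency(0, 0, 0)

    @given(gg=st.integers(1, 1000), ga=st.integers(0, 1000),
           aa=st.integers(0, 1000), k=st.integers(2, 20))
    def test_scaling_invariance(self, gg, ga, aa, k):
        f = allele_frequency(gg, ga, aa)
        assert 0.0 <= f <= 1.0
        assert allele_frequency(k * gg, k * ga, k * aa) == pytest.approx(f)


class TestHWE:
    def test_study_male_counts_fit(self):
        res = hwe_test(2395, 874, 96)
        assert res.statistic == pytest.approx(2.25, abs=0.05)
        assert res.pvalue > 0.05

    def test_exact_hwe_counts(self):
        # 10,000 individuals at p=0.1: expected counts exactly
        assert hwe_test(8100, 1800, 100).statistic == pytest.approx(0.0, abs=1e-9)

    def test_extreme_departure(self):
        assert hwe_test(50, 0, 50).pvalue < 1e-15

    def test_monomorphic_warns(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            res = hwe_test(100, 0, 0)
        assert res.statistic == 0.0 and res.pvalue == 1.0


class TestWeightedMean:
    @pytest.mark.parametrize("means,ns,expected", [
        ((23.78, 7.28, 0.41), (2395, 874, 96), 18.8),
        ((1.70, 0.41, 0.02), (2684, 1003, 100), 1.3),
        ((28.8, 14.6, 4.3), (1979, 437, 9), 26.2),  # current drinkers (26.15 from rounded inputs)
    ])
    def test_genotype_cells_reproduce_marginals(self, means, ns, expected):
        assert round(weighted_mean_from_groups(means, ns), 1) == expected

    def test_single_group(self):
        assert weighted_mean_from_groups([5.0], [10]) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_mean_from_groups([1.0, 2.0], [10])


class TestGroupSummary:
    def test_se_and_percent(self, rng):
        df = pd.DataFrame({
            "g": np.repeat([0, 1], 50),
            "x": rng.standard_normal(100),
            "c": rng.integers(0, 3, 100),
        })
        out = group_summary(df, ["g"], continuous=["x"], categorical=["c"])
        assert len(out) == 2
        grp0 = df[df.g == 0]
        row = out[0].continuous.iloc[0]
        assert row["mean"] == pytest.approx(grp0.x.mean())
        assert row["se"] == pytest.approx(grp0.x.std(ddof=1) / np.sqrt(50))
        assert out[0].categorical["c"]["percent"].sum() == pytest.approx(100.0)

    def test_single_record_stratum_has_missing_se(self):
        df = pd.DataFrame({"g": [0, 1, 1], "x": [1.0, 2.0, 3.0]})
        out = group_summary(df, ["g"], continuous=["x"])
        assert np.isnan(out[0].continuous.iloc[0]["se"])

    def test_study_prevalence_arithmetic(self):
        df = pd.DataFrame({"g": 0, "ever": [1] * 2763 + [0] * 586})
        out = group_summary(df, ["g"], categorical=["ever"])
        tab = out[0].categorical["ever"]
        pct = float(tab.loc[tab.level == 1, "percent"].iloc[0])
        assert round(pct, 1) == 82.5

    def test_missing_grouping_column(self):
        with pytest.raises(KeyError):
            group_summary(pd.DataFrame({"x": [1]}), ["nope"])


class TestClassicalTests:
    def test_identical_samples_t(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_flat_contingency_table(self):
        res = chisq_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0

    def test_chi2_matches_scipy_uncorrected(self, rng):
        tab = rng.integers(5, 50, size=(2, 3))
        res = chisq_independence(tab)
        ref = stats.chi2_contingency(tab, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_anova_degenerate(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 1.0], [1.0, 1.0])

    def test_anova_null_pvalues_uniform(self):
        """Under one common normal population, ANOVA p-values are
        uniform: a KS test over 500 seeded replicates does not reject."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(500):
            groups = rng.standard_normal((3, 100))
            pvals.append(oneway_anova(*groups).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestColliderInteraction:
    def test_constant_genotype_raises(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "genotype": [1, 1, 1, 1],
                           "ever_drinker": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="constant"):
            collider_interaction_test(df, "y")

    def test_single_history_group_raises(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "genotype": [0, 1, 2, 1],
                           "ever_drinker": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="history"):
            collider_interaction_test(df, "y")

    def test_detects_opposite_sign_effects(self):
        """A genotype effect that flips sign between never- and
        ever-drinkers (the smoking pattern) is detected with high power
        at a realistic male-stratum sample size."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            df = collider_frame(3349, rng, interaction=0.7, binary=True)
            res = collider_interaction_test(df, "y", binary=True)
            hits += res.pvalue < 0.05
        assert hits / 50 > 0.90

    def test_size_under_null(self):
        """With a common genotype slope in both strata the interaction
        test rejects at close to its nominal 5% level."""
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(3000 + seed)
            df = collider_frame(2000, rng, interaction=0.0)
            rejections += collider_interaction_test(df, "y").pvalue < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_lr_close_to_wald(self, rng):
        df = collider_frame(4000, rng, interaction=0.3)
        wald = collider_interaction_test(df, "y", method="wald")
        lr = collider_interaction_test(df, "y", method="lr")
        assert wald.pvalue == pytest.approx(lr.pvalue, abs=0.02)
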