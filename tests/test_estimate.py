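import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from corsurvey.estimate import (
    descriptive_tables,
    weighted_chisq,
    weighted_mean_sd,
    weighted_proportion,
    weighted_t_test,
)

int_weight_instances = st.lists(
    st.tuples(st.floats(-50, 50, allow_nan=False), st.integers(1, 5)),
    min_size=2,
    max_size=40,
)


class TestWeightedProportion:
    def test_unit_weights(self):
        est = weighted_proportion([1, 0, 1, 0], [1, 1, 1, 1])
        assert est.estimate == 0.5
        assert est.unweighted_n == 4

    def test_weighted_average_arithmetic(self):
        assert weighted_proportion([1, 0], [3, 1]).estimate == 0.75

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(1, 5)), min_size=1, max_size=40))
    def test_integer_weights_equal_replication(self, pairs):
        x = [p[0] for p in pairs]
        w = [p[1] for p in pairs]
        replicated = np.repeat(x, w)
        assert weighted_proportion(x, w).estimate == pytest.approx(replicated.mean(), abs=1e-12)

    def test_missing_excluded_pairwise(self):
        est = weighted_proportion([1, np.nan, 0], [1, 1, 1])
        assert est.estimate == 0.5
        assert est.unweighted_n == 2

    def test_empty_after_exclusion_raises(self):
        with pytest.raises(ValueError, match="no observations"):
            weighted_proportion([np.nan], [1.0])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            weighted_proportion([0.4], [1.0])


class TestWeightedMeanSD:
    def test_constant_vector_zero_sd(self):
        assert weighted_mean_sd([3.0, 3.0, 3.0], [1, 2, 5]).sd_or_se == 0.0

    def test_unit_weights_population_variance(self):
        x = [1.0, 2.0, 4.0, 8.0]
        est = weighted_mean_sd(x, np.ones(4))
        assert est.estimate == pytest.approx(np.mean(x))
        assert est.sd_or_se == pytest.approx(np.std(x))

    @settings(derandomize=True, max_examples=50)
    @given(int_weight_instances)
    def test_integer_weights_equal_replication(self, pairs):
        x = np.array([p[0] for p in pairs])
        w = np.array([p[1] for p in pairs])
        rep = np.repeat(x, w)
        est = weighted_mean_sd(x, w)
        assert est.estimate == pytest.approx(rep.mean(), abs=1e-9)
        assert est.sd_or_se == pytest.approx(rep.std(), abs=1e-9)

    def test_single_observation_flagged(self):
        assert weighted_mean_sd([2.0], [1.0]).sd_or_se is None


class TestWeightedChisq:
    def test_identical_distributions_null(self):
        group = ["a"] * 4 + ["b"] * 4
        cat = [0, 0, 1, 1] * 2
        stat, df, p = weighted_chisq(group, cat, np.ones(8))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_two_by_two(self):
        """Counts {{10,90},{20,80}} give the hand-computed Pearson 3.921."""
        group = ["g1"] * 100 + ["g2"] * 100
        cat = [1] * 10 + [0] * 90 + [1] * 20 + [0] * 80
        stat, df, p = weighted_chisq(group, cat, np.ones(200))
        assert df == 1
        assert stat == pytest.approx(50 / 15 + 50 / 85, abs=1e-9)
        assert round(stat, 2) == 3.92

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        group = rng.integers(0, 2, 60)
        cat = rng.integers(0, 3, 60)
        w = rng.uniform(0.5, 2.0, 60)
        a = weighted_chisq(group, cat, w)
        b = weighted_chisq(group, cat, 2.0 * w)
        assert a[0] == pytest.approx(b[0], rel=1e-12)
        assert a[2] == pytest.approx(b[2], rel=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate|2 groups"):
            weighted_chisq(["a", "a"], [0, 1], [1, 1])

    def test_matches_squared_z_on_two_by_two(self):
        """Pearson chi-squared equals the squared pooled z statistic for the
        proportion difference (unit weights)."""
        group = np.array(["g1"] * 50 + ["g2"] * 70)
        cat = np.concatenate([np.repeat([1, 0], [12, 38]), np.repeat([1, 0], [30, 40])])
        stat, _, _ = weighted_chisq(group, cat, np.ones(120))
        p1, n1 = 12 / 50, 50
        p2, n2 = 30 / 70, 70
        pp = (12 + 30) / 120
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z ** 2, abs=1e-6)


class TestWeightedTTest:
    def test_identical_groups_null(self):
        x = [1.0, 2.0, 3.0] * 2
        g = ["a"] * 3 + ["b"] * 3
        t, df, p = weighted_t_test(x, np.ones(6), g)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_unit_weights_match_welch(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)])
        g = ["a"] * 30 + ["b"] * 40
        t, df, p = weighted_t_test(x, np.ones(70), g)
        ref = stats.ttest_ind(x[:30], x[30:], equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        g = ["a"] * 20 + ["b"] * 20
        a = weighted_t_test(x, np.ones(40), g)
        b = weighted_t_test(x, np.full(40, 7.3), g)
        assert a == pytest.approx(b, rel=1e-10)

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            weighted_t_test([1.0, 1.0, 2.0, 2.0], np.ones(4), ["a", "a", "b", "b"])


class TestDescriptiveTables:
    def test_all_low_dataset_leaves_high_empty(self, derived_default):
        frame = derived_default.frame.copy()
        part = frame["responded"].fillna(False).astype(bool)
        frame.loc[part, "attempts"] = 3
        frame.loc[part, "contact_group"] = "1-6"
        _, drink = descriptive_tables(frame)
        assert drink["high_unweighted_n"].eq(0).all()
        assert drink["p_value"].isna().all()

    def test_heavy_episodic_pattern_by_group(self, derived_default):
        _, drink = descriptive_tables(derived_default)
        for sex in ("men", "women"):
            row = drink[(drink["sex"] == sex) & drink["measure"].str.startswith("Heavy episodic")].iloc[0]
            assert row["high_estimate"] > row["low_estimate"]

    def test_complete_case_counts_match_recount(self, derived_default):
        _, drink = descriptive_tables(derived_default)
        part = derived_default.frame[derived_default.frame["responded"]]
        women = part[part["sex"] == "women"]
        row = drink[(drink["sex"] == "women") & drink["measure"].str.startswith("Heavy episodic")].iloc[0]
        for grp, tag in (("1-6", "low"), ("7+", "high")):
            n = women[(women["contact_group"] == grp) & women["heavy_episodic"].notna()].shape[0]
            assert row[f"{tag}_unweighted_n"] == n
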