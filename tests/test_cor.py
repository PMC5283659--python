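import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from corsurvey.cor import COR_MEASURES, CORResult, cor_adjust, cor_table, sales_coverage


class TestCorAdjust:
    def test_equal_inputs_fixed_point(self):
        assert cor_adjust(0.5, 0.5, 0.7) == 0.5

    def test_full_response_returns_participant_estimate(self):
        assert cor_adjust(0.37, 0.92, 1.0) == pytest.approx(0.37)

    def test_percentage_arithmetic(self):
        # 0.58 * 12.8 + 0.42 * 17.2
        assert cor_adjust(12.8, 17.2, 0.58) == pytest.approx(14.648, abs=1e-12)

    @pytest.mark.parametrize("r", [0.0, -0.1, 1.5])
    def test_response_proportion_domain(self, r):
        with pytest.raises(ValueError, match="response proportion"):
            cor_adjust(0.5, 0.6, r)

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            cor_adjust(0.2, 17.2, 0.58)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0.01, 1.0, allow_nan=False),
    )
    def test_bounded_between_arguments(self, p, h, r):
        out = cor_adjust(p, h, r)
        assert min(p, h) - 1e-12 <= out <= max(p, h) + 1e-12

    def test_monotone_in_each_argument_and_linear_in_r(self):
        assert cor_adjust(0.3, 0.5, 0.6) <= cor_adjust(0.4, 0.5, 0.6)
        assert cor_adjust(0.3, 0.5, 0.6) <= cor_adjust(0.3, 0.6, 0.6)
        a, b, c = (cor_adjust(0.2, 0.8, r) for r in (0.2, 0.4, 0.6))
        assert b - a == pytest.approx(c - b, abs=1e-12)


class TestSalesCoverage:
    def test_full_coverage(self):
        assert sales_coverage(19.1, 19.1) == pytest.approx(100.0)

    def test_survey_weighted_coverage_value(self):
        assert sales_coverage(10.9, 19.1) == pytest.approx(57.07, abs=0.005)

    def test_adjusted_coverage_value(self):
        assert sales_coverage(12.7, 19.1) == pytest.approx(66.49, abs=0.005)

    @pytest.mark.parametrize("args", [(0.0, 19.1), (10.9, 0.0), (-1.0, 19.1)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            sales_coverage(*args)


def _identical_groups_frame():
    """LOW and HIGH groups with exactly the same drinking rows."""
    block = pd.DataFrame(
        {
            "sex": ["men"] * 4 + ["women"] * 4,
            "is_drinker": [1, 1, 0, 1] * 2,
            "drinks_now": [1, 1, 0, 1] * 2,
            "drink_days": [2, 7, 0, 1] * 2,
            "max_day_units": [5.0, 9.0, 0.0, 2.0] * 2,
            "weekly_units": [12.0, 30.0, 0.0, 4.0] * 2,
            "exceed_daily": [True, True, False, False] * 2,
            "heavy_episodic": [False, True, False, False] * 2,
            "exceed_weekly": [False, True, False, False] * 2,
        }
    )
    low = block.copy()
    low["contact_group"] = "1-6"
    low["attempts"] = 3
    high = block.copy()
    high["contact_group"] = "7+"
    high["attempts"] = 9
    frame = pd.concat([low, high], ignore_index=True)
    frame["responded"] = True
    frame["int_weight"] = 1.0
    return frame


class TestCorTable:
    def test_identical_groups_leave_estimates_unchanged(self):
        table = cor_table(_identical_groups_frame(), r=0.6)
        assert np.allclose(table["adjusted"], table["weighted"])
        assert np.allclose(table["difference"], 0.0)

    def test_full_response_equals_weighted(self, derived_default):
        table = cor_table(derived_default, r=1.0)
        valid = table["weighted"].notna()
        assert np.allclose(table.loc[valid, "adjusted"], table.loc[valid, "weighted"])

    def test_difference_and_pct_change_consistent(self, derived_default):
        table = cor_table(derived_default)
        diff = table["adjusted"] - table["weighted"]
        assert np.allclose(table["difference"], diff, atol=1e-10)
        pct = 100 * diff / table["weighted"]
        assert np.allclose(table["pct_change"], pct, atol=1e-10)

    def test_default_data_directional_pattern(self, derived_default):
        """Hard-to-contact drinking is heavier, so the adjustment raises
        heavy-episodic prevalence and weekly units and lowers drinking days."""
        table = cor_table(derived_default)
        for sex in ("men", "women"):
            sub = table[table["sex"] == sex].set_index("measure")
            hed = sub.loc[[m for m in sub.index if "heavy episodic" in m][0]]
            weekly = sub.loc[[m for m in sub.index if "weekly alcohol" in m][0]]
            days = sub.loc[[m for m in sub.index if "Drinking days" in m][0]]
            assert hed["adjusted"] > hed["weighted"]
            assert weekly["adjusted"] > weekly["weighted"]
            assert days["adjusted"] < days["weighted"]

    def test_has_seven_measures_per_sex(self, derived_default):
        table = cor_table(derived_default)
        assert len(table) == 2 * len(COR_MEASURES)

    def test_adjusted_between_weighted_and_hard_group(self, derived_default):
        table = cor_table(derived_default).dropna(subset=["weighted", "hard_group"])
        lo = np.minimum(table["weighted"], table["hard_group"]) - 1e-9
        hi = np.maximum(table["weighted"], table["hard_group"]) + 1e-9
        assert ((table["adjusted"] >= lo) & (table["adjusted"] <= hi)).all()
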