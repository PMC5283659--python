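import numpy as np
import pandas as pd
import pytest
from scipy import stats

import corsurvey as cs
from corsurvey.simulate import compute_weights, generate_population, simulate_fielding


def _extreme(cfg, willingness, contact):
    """Configuration with willingness/contact probabilities pinned to 0 or 1."""
    c = cfg.copy()
    c.willingness_intercept = 50.0 if willingness else -50.0
    c.willingness_slope = 0.0
    c.contact_intercept = 50.0 if contact else -50.0
    c.contact_slope = 0.0
    c.contact_escalation = 0.0
    return c


class TestGeneratePopulation:
    def test_degenerate_marginal_pins_category(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.demographic_marginals["region"] = {"london": 1.0}
        pop = generate_population(cfg, seed=3)
        assert (pop["region"] == "london").all()

    def test_zero_loadings_zero_noise_gives_zero_resistance(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.resistance_loadings = {}
        cfg.resistance_noise_sd = 0.0
        pop = generate_population(cfg, seed=3)
        assert (pop["resistance"] == 0.0).all()

    def test_marginal_frequencies_match_probabilities(self, default_cfg):
        pop = generate_population(default_cfg, seed=5)
        for var, probs in default_cfg.demographic_marginals.items():
            obs = pop[var].value_counts(normalize=True)
            for cat, p in probs.items():
                assert obs.get(cat, 0.0) == pytest.approx(p, abs=0.01)

    def test_resistance_drinking_coupling_orders_tertiles(self, default_cfg):
        """Higher latent resistance means heavier weekly drinking (via the
        hard-to-contact group), detectable at n=20,000."""
        cfg = default_cfg.copy()
        cfg.n_sampled = 20000
        ds = cs.simulate_survey(cfg, seed=11)
        truth = ds.truth
        lo, hi = truth["resistance"].quantile([1 / 3, 2 / 3])
        bottom = truth.loc[truth["resistance"] <= lo, "weekly_units"]
        top = truth.loc[truth["resistance"] > hi, "weekly_units"]
        t, p = stats.ttest_ind(top, bottom, equal_var=False)
        assert t > 0 and p / 2 < 1e-3


class TestSimulateFielding:
    def test_certain_willingness_and_contact(self, small_cfg):
        ds = simulate_fielding(generate_population(small_cfg, 2), _extreme(small_cfg, True, True), 2)
        assert ds.response_rate == 1.0
        assert (ds.participants["attempts"] == 1).all()

    def test_zero_willingness_empty_analytic_sample(self, small_cfg):
        ds = simulate_fielding(generate_population(small_cfg, 2), _extreme(small_cfg, False, True), 2)
        assert ds.response_rate == 0.0
        assert len(ds.participants) == 0

    def test_deterministic_given_config_and_seed(self, small_cfg):
        a = cs.simulate_survey(small_cfg, seed=9)
        b = cs.simulate_survey(small_cfg, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_participants_have_attempts_in_range(self, sim_default, default_cfg):
        att = sim_default.participants["attempts"]
        assert att.notna().all()
        assert att.min() >= 1 and att.max() <= default_cfg.max_attempts
        non = sim_default.frame[~sim_default.frame["responded"]]
        assert non["attempts"].isna().all()
        assert non["int_weight"].isna().all()
        assert non[["drinks_now", "drink_days", "max_day_units", "weekly_units"]].isna().all().all()

    def test_more_willingness_resistance_lowers_response(self, small_cfg):
        base, steep = [], []
        cfg2 = small_cfg.copy()
        cfg2.willingness_slope = small_cfg.willingness_slope * 2.5
        for seed in (1, 2, 3):
            base.append(cs.simulate_survey(small_cfg, seed).response_rate)
            steep.append(cs.simulate_survey(cfg2, seed).response_rate)
        assert np.mean(steep) < np.mean(base)

    def test_harder_contact_shifts_attempts_right(self, small_cfg):
        cfg2 = small_cfg.copy()
        cfg2.contact_intercept = small_cfg.contact_intercept - 0.5
        base, hard = [], []
        for seed in (1, 2, 3):
            base.append(cs.simulate_survey(small_cfg, seed).participants["attempts"].astype(float).mean())
            hard.append(cs.simulate_survey(cfg2, seed).participants["attempts"].astype(float).mean())
        assert np.mean(hard) > np.mean(base)

    def test_steeper_contact_slope_strengthens_resistance_coupling(self, small_cfg):
        """A larger resistance penalty in the contact hazard tightens the
        association between latent resistance and attempts needed."""
        cfg2 = small_cfg.copy()
        cfg2.contact_slope = small_cfg.contact_slope * 3.0
        base, steep = [], []
        for seed in (1, 2, 3):
            for cfg, acc in ((small_cfg, base), (cfg2, steep)):
                truth = cs.simulate_survey(cfg, seed).truth
                part = truth[truth["responded"]]
                acc.append(np.corrcoef(part["resistance"], part["attempts"].astype(float))[0, 1])
        assert np.mean(steep) > np.mean(base)

    def test_item_nonresponse_masks_dependent_items(self, small_cfg):
        cfg = small_cfg.copy()
        cfg.item_nonresponse_rate = 0.3
        part = cs.simulate_survey(cfg, seed=4).participants
        frac = part["drinks_now"].isna().mean()
        assert 0.2 < frac < 0.45
        screen_missing = part[part["drinks_now"].isna()]
        assert screen_missing[["drink_days", "max_day_units", "weekly_units"]].isna().all().all()


class TestDrinkingConsistency:
    def test_nondrinkers_have_zero_consumption(self, sim_default):
        truth = sim_default.truth
        non = truth[truth["drinks_now"] == 0]
        assert (non["drink_days"] == 0).all()
        assert (non["max_day_units"] == 0).all()
        assert (non["weekly_units"] == 0).all()

    def test_drink_days_in_week_range(self, sim_default):
        days = sim_default.truth["drink_days"]
        assert days.between(0, 7).all()
        assert (sim_default.truth["max_day_units"] >= 0).all()
        assert (sim_default.truth["weekly_units"] >= 0).all()

    def test_last_week_drinkers_have_positive_units(self, sim_default):
        truth = sim_default.truth
        lw = truth["drink_days"] >= 1
        assert (truth.loc[lw, "max_day_units"] > 0).all()
        assert (truth.loc[~lw, "max_day_units"] == 0).all()


class TestWeights:
    def test_full_response_gives_unit_weights(self, small_cfg):
        ds = simulate_fielding(generate_population(small_cfg, 2), _extreme(small_cfg, True, True), 2)
        assert np.allclose(ds.participants["int_weight"], 1.0)

    def test_half_response_cell_doubles_weight(self):
        frame = pd.DataFrame(
            {
                "sex": ["men"] * 4 + ["women"] * 4,
                "age_group": ["18-34"] * 8,
                "region": ["london"] * 8,
                "responded": [True, False, True, False, True, True, True, True],
            }
        )
        out = compute_weights(frame)
        w_men = out.loc[out["sex"] == "men", "int_weight"].dropna().unique()
        w_women = out.loc[out["sex"] == "women", "int_weight"].dropna().unique()
        assert len(w_men) == 1 and len(w_women) == 1
        assert w_men[0] / w_women[0] == pytest.approx(2.0)

    def test_weighted_totals_conserve_cell_counts(self, sim_default):
        """Pre-rescaling, weighted participant totals reproduce sampled totals
        per sex x age x region cell; after mean-1 rescaling the ratio is a
        single constant across cells."""
        frame = sim_default.frame
        resp = frame["responded"]
        ratios = []
        for _, cell in frame.groupby(["sex", "age_group", "region"], observed=True):
            sampled = len(cell)
            wsum = cell.loc[cell["responded"], "int_weight"].sum()
            if wsum > 0:
                ratios.append(sampled / wsum)
        assert np.std(ratios) / np.mean(ratios) < 1e-9

    def test_empty_cell_collapses_to_neighbour(self, caplog):
        import logging

        rows = []
        for age, responded in (("18-34", [True] * 4), ("35-54", [False] * 4), ("55+", [True] * 4)):
            for r in responded:
                rows.append({"sex": "men", "age_group": age, "region": "london", "responded": r})
        frame = pd.DataFrame(rows)
        with caplog.at_level(logging.WARNING):
            out = compute_weights(frame)
        assert "collapsing" in caplog.text
        w = out.loc[out["responded"], "int_weight"]
        assert w.notna().all() and (w > 0).all()
        # the 35-54 sampled adults are carried by the 55+ cell's participants
        assert out.loc[out["responded"] & (out["age_group"] == "55+"), "int_weight"].iloc[0] > \
            out.loc[out["responded"] & (out["age_group"] == "18-34"), "int_weight"].iloc[0]
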