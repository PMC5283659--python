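"""Synthetic survey population and fielding simulator.

The generative model, end to end:

1.  ``generate_population`` draws ``n_sampled`` adults with independent
    demographic marginals and a latent *resistance* score
    ``R = loadings(demographics) + Normal(0, sd)``.
2.  ``simulate_fielding`` fields the survey: each person is *willing* to
    ever cooperate with probability ``logistic(w0 − w1·R)``; willing people
    are contacted on attempt ``t`` with probability
    ``logistic(c0 + esc·(1 − ρ^(t−1)) − c1·R)`` and respond on the first
    successful attempt, capped at ``max_attempts`` (those never contacted
    within the cap are non-respondents).  The rising, saturating per-attempt
    hazard reflects appointment-making once first contact is established.
3.  ``draw_drinking`` assigns drinking behaviour conditional on demographics
    and the realised contact group, with non-participants treated as
    members of the hard-to-contact (7+) group — i.e. the
    continuum-of-resistance mechanism holds exactly in the generator, which
    is what makes it a usable test bed for the adjustment.
4.  ``compute_weights`` mimics an interview weight by cell-based inverse
    response propensity within sex × age group × region, rescaled to mean 1.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    AGE_GROUPS,
    DEMOGRAPHIC_LEVELS,
    GeneratorConfig,
    SEXES,
)
from .derive import DrinkingThresholds, HIGH_GROUP_MIN_ATTEMPTS

logger = logging.getLogger(__name__)

#: columns of the analytic export, in order
ANALYTIC_COLUMNS = [
    "person_id",
    "survey_year",
    "sex",
    "age_group",
    "econ_activity",
    "income_q",
    "imd_q",
    "region",
    "responded",
    "attempts",
    "int_weight",
    "drinks_now",
    "drink_days",
    "max_day_units",
    "weekly_units",
]

DEMOGRAPHIC_COLUMNS = ["sex", "age_group", "econ_activity", "income_q", "imd_q", "region"]
DRINKING_COLUMNS = ["drinks_now", "drink_days", "max_day_units", "weekly_units"]


@dataclass
class SurveyDataset:
    """A simulated (or imported) survey.

    ``frame`` is the analytic table (one row per sampled adult; fielding and
    drinking fields are missing for non-participants).  ``truth`` — present
    for simulated data only — additionally carries the latent resistance,
    willingness and the *true* drinking behaviour of every sampled adult,
    for oracle checks; it is never part of the analytic export.
    """

    frame: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    @property
    def participants(self) -> pd.DataFrame:
        return self.frame[self.frame["responded"].fillna(False).astype(bool)]

    @property
    def n_sampled(self) -> int:
        return len(self.frame)

    @property
    def response_rate(self) -> float:
        return float(self.frame["responded"].fillna(False).astype(bool).mean())


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def generate_population(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the sampled adult population: demographics plus latent resistance."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _stage_rng(seed, 0)
    n = config.n_sampled

    data = {"person_id": np.arange(1, n + 1)}
    years = list(config.survey_years)
    data["survey_year"] = rng.choice(years, size=n, p=[1.0 / len(years)] * len(years))
    for var in DEMOGRAPHIC_COLUMNS:
        probs = config.demographic_marginals[var]
        levels = [lv for lv in DEMOGRAPHIC_LEVELS[var] if lv in probs]
        p = np.array([probs[lv] for lv in levels], dtype=float)
        p = p / p.sum()
        data[var] = rng.choice(np.asarray(levels, dtype=object), size=n, p=p)

    frame = pd.DataFrame(data)
    lp = np.zeros(n)
    for var, loads in config.resistance_loadings.items():
        lp += frame[var].map(lambda c, L=loads: L.get(c, 0.0)).to_numpy(dtype=float)
    noise = rng.standard_normal(n) * config.resistance_noise_sd
    frame["resistance"] = lp + noise
    for var in ("income_q", "imd_q", "survey_year"):
        frame[var] = frame[var].astype(int)
    return frame


def _simulate_attempts(resistance: np.ndarray, config: GeneratorConfig, rng) -> np.ndarray:
    """First-success attempt number per person, 0 meaning never contacted."""
    n = resistance.shape[0]
    attempts = np.zeros(n, dtype=int)
    pending = np.ones(n, dtype=bool)
    for t in range(1, config.max_attempts + 1):
        if not pending.any():
            break
        rise = 1.0 - config.contact_saturation ** (t - 1)
        h = expit(
            config.contact_intercept
            + config.contact_escalation * rise
            - config.contact_slope * resistance[pending]
        )
        hit = rng.random(pending.sum()) < h
        idx = np.flatnonzero(pending)
        attempts[idx[hit]] = t
        pending[idx[hit]] = False
    return attempts


def draw_drinking(
    frame: pd.DataFrame,
    high_group: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    excess: np.ndarray | float = 0.0,
    thresholds: DrinkingThresholds | None = None,
) -> pd.DataFrame:
    """Draw drinking behaviour given demographics and contact group.

    The nested binary outcomes (heavy episodic ⊂ exceeded daily ⊂ drank
    last week ⊂ drinks nowadays) are generated from one uniform against the
    logistic exceedance probabilities, so each indicator's conditional
    log-odds is exactly the configured model; the continuous variables are
    then drawn within the band the indicators fix, making the thresholded
    derivation recover the intended indicator by construction.
    ``excess`` adds extra log-odds (non-participant mis-specification knob).
    """
    thresholds = thresholds or DrinkingThresholds()
    n = len(frame)
    high = np.asarray(high_group, dtype=bool)
    excess = np.broadcast_to(np.asarray(excess, dtype=float), (n,))

    drinks = np.zeros(n, dtype=int)
    days = np.zeros(n, dtype=int)
    max_day = np.zeros(n, dtype=float)
    weekly = np.zeros(n, dtype=float)

    # one uniform per person drives the nested chain; independent draws for
    # the weekly recall and the within-band values
    u_nest = rng.random(n)
    u_week = rng.random(n)

    for sex in SEXES:
        m = (frame["sex"] == sex).to_numpy()
        if not m.any():
            continue
        sub = frame.loc[m]
        hi = high[m]
        ex = excess[m]
        blocks = config.drinking_model.models[sex]

        def prob(name):
            return expit(blocks[name].linear_predictor(sub, hi) + ex)

        p_drink = prob("drinks_now")
        p_lw = prob("last_week")
        p_d = prob("exceed_daily")
        p_h = prob("heavy_episodic")
        p_w = prob("exceed_weekly")

        # enforce nesting; the daily/episodic models are left exact and the
        # unmodelled envelopes give way (violations are a calibration defect
        # and are logged)
        bad = int((p_h > p_d).sum())
        if bad:
            logger.warning("%s: %d rows with episodic prob above daily prob (clipped)", sex, bad)
        p_h = np.minimum(p_h, p_d)
        p_lw = np.minimum(np.maximum(p_lw, p_d), 1.0)
        p_drink = np.maximum(p_drink, p_lw)
        p_w = np.minimum(p_w, p_drink)

        u = u_nest[m]
        is_hed = u < p_h
        is_daily = u < p_d
        is_lw = u < p_lw
        is_drinker = u < p_drink
        with np.errstate(divide="ignore", invalid="ignore"):
            pw_cond = np.where(p_drink > 0, p_w / p_drink, 0.0)
        is_excw = is_drinker & (u_week[m] < pw_cond)

        n_sub = m.sum()
        # drinking days: 1 + beta-binomial(6) among last-week drinkers,
        # overdispersed to mimic the bimodal weekly pattern
        d_sub = np.zeros(n_sub, dtype=int)
        for grp, g_mask in (("low", ~hi), ("high", hi)):
            sel = is_lw & g_mask
            if sel.any():
                a, b = config.drinking_model.days_ab[sex][grp]
                pp = rng.beta(a, b, size=int(sel.sum()))
                d_sub[sel] = 1 + rng.binomial(6, pp)

        # heaviest-day units within the band the indicators fix
        thr_d = thresholds.daily_limit[sex]
        thr_h = thresholds.heavy_episodic[sex]
        shp = config.drinking_model.heaviest_shape[sex]
        md_sub = np.zeros(n_sub, dtype=float)
        sel = is_lw & ~is_daily
        if sel.any():
            a, b = shp["low_beta"]
            md_sub[sel] = thr_d * rng.beta(a, b, size=int(sel.sum()))
        sel = is_daily & ~is_hed
        if sel.any():
            a, b = shp["mid_beta"]
            md_sub[sel] = thr_d + (thr_h - thr_d) * rng.beta(a, b, size=int(sel.sum()))
        if is_hed.any():
            k, theta = shp["tail_gamma"]
            md_sub[is_hed] = thr_h + rng.gamma(k, theta, size=int(is_hed.sum()))

        # weekly units: zero for non-drinkers, banded around the weekly limit
        thr_w = thresholds.weekly_limit[sex]
        wshp = config.drinking_model.weekly_shape[sex]
        wk_sub = np.zeros(n_sub, dtype=float)
        sel = is_drinker & ~is_excw
        if sel.any():
            a, b = wshp["sub_beta"]
            wk_sub[sel] = thr_w * rng.beta(a, b, size=int(sel.sum()))
        # the 7+ group may carry its own (heavier) tail
        tail_by_group = (("low", ~hi), ("high", hi))
        for grp, g_mask in tail_by_group:
            sel = is_excw & g_mask
            if sel.any():
                k, theta = wshp["tail_gamma"] if grp == "low" else wshp.get(
                    "tail_gamma_high", wshp["tail_gamma"]
                )
                wk_sub[sel] = thr_w + rng.gamma(k, theta, size=int(sel.sum()))

        drinks[m] = is_drinker.astype(int)
        days[m] = d_sub
        max_day[m] = md_sub
        weekly[m] = wk_sub

    return pd.DataFrame(
        {
            "drinks_now": drinks,
            "drink_days": days,
            "max_day_units": max_day,
            "weekly_units": weekly,
        },
        index=frame.index,
    )


def simulate_fielding(
    population: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> SurveyDataset:
    """Field the survey over a generated population.

    Returns the full :class:`SurveyDataset` (analytic table with interview
    weights and item non-response applied, plus the truth table).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng_f = _stage_rng(seed, 1)
    rng_d = _stage_rng(seed, 2)

    n = len(population)
    R = population["resistance"].to_numpy(dtype=float)
    willing = rng_f.random(n) < expit(
        config.willingness_intercept - config.willingness_slope * R
    )
    attempt_no = np.zeros(n, dtype=int)
    if willing.any():
        attempt_no[willing] = _simulate_attempts(R[willing], config, rng_f)
    responded = willing & (attempt_no >= 1)

    truth = population.copy()
    truth["willing"] = willing
    truth["responded"] = responded
    truth["attempts"] = pd.array(
        np.where(responded, attempt_no, -1), dtype="Int64"
    )
    truth.loc[~responded, "attempts"] = pd.NA

    # drinking: participants by their realised group; non-participants as
    # the hard-to-contact group (plus any configured excess)
    high = np.where(responded, attempt_no >= HIGH_GROUP_MIN_ATTEMPTS, True)
    excess = np.where(responded, 0.0, config.nonparticipant_excess)
    drinking = draw_drinking(population, high, config, rng_d, excess=excess)
    truth["high_group"] = high
    for col in DRINKING_COLUMNS:
        truth[col] = drinking[col]

    frame = population.drop(columns=["resistance"]).copy()
    frame["responded"] = responded
    frame["attempts"] = truth["attempts"]
    for col in DRINKING_COLUMNS:
        frame[col] = drinking[col]
    frame["drinks_now"] = frame["drinks_now"].astype("Int64")
    frame["drink_days"] = frame["drink_days"].astype("Int64")
    frame.loc[~responded, "drinks_now"] = pd.NA
    frame.loc[~responded, "drink_days"] = pd.NA
    frame.loc[~responded, ["max_day_units", "weekly_units"]] = np.nan

    # item non-response among participants (MCAR); a missing screener blanks
    # the dependent items too
    q = config.item_nonresponse_rate
    if q > 0:
        part_idx = np.flatnonzero(responded)
        miss_screen = part_idx[rng_d.random(part_idx.size) < q]
        frame.loc[frame.index[miss_screen], DRINKING_COLUMNS] = pd.NA
        for col in ("drink_days", "max_day_units", "weekly_units"):
            miss = part_idx[rng_d.random(part_idx.size) < q]
            frame.loc[frame.index[miss], col] = pd.NA
        frame["max_day_units"] = frame["max_day_units"].astype(float)
        frame["weekly_units"] = frame["weekly_units"].astype(float)

    frame = compute_weights(frame)
    frame = frame[ANALYTIC_COLUMNS]
    return SurveyDataset(frame=frame, truth=truth)


def simulate_survey(config: GeneratorConfig, seed: int | None = None) -> SurveyDataset:
    """Convenience wrapper: population draw plus fielding with one seed."""
    seed = config.seed if seed is None else seed
    population = generate_population(config, seed)
    return simulate_fielding(population, config, seed)


def _collapse_age_weights(samp: dict, part: dict) -> dict:
    """Inverse response-propensity weights by age cell, collapsing empty cells.

    Collapse order: an age cell with sampled adults but no participants is
    merged with its next-older neighbour, falling back to next-younger
    (55+ merges downward); repeated until every block has participants.
    """
    blocks = [[ag] for ag in AGE_GROUPS if samp.get(ag, 0) > 0]
    changed = True
    while changed and len(blocks) > 1:
        changed = False
        for i, blk in enumerate(blocks):
            if sum(part.get(ag, 0) for ag in blk) == 0:
                j = i + 1 if i + 1 < len(blocks) else i - 1
                blocks[j] = blocks[j] + blk
                del blocks[i]
                changed = True
                break
    weights = {}
    for blk in blocks:
        s = sum(samp.get(ag, 0) for ag in blk)
        p = sum(part.get(ag, 0) for ag in blk)
        w = s / p if p > 0 else np.nan
        for ag in blk:
            weights[ag] = w
    return weights


def compute_weights(data) -> "pd.DataFrame | SurveyDataset":
    """(Re)compute interview weights by inverse response propensity.

    Cells are sex × age group × region; a participant's pre-rescaling weight
    is (sampled adults in cell) / (participants in cell); empty participant
    cells are collapsed over adjacent age groups (see
    :func:`_collapse_age_weights`).  Weights are rescaled to mean 1 over
    participants.  Accepts and returns either a bare analytic frame or a
    :class:`SurveyDataset`.
    """
    if isinstance(data, SurveyDataset):
        return SurveyDataset(frame=compute_weights(data.frame), truth=data.truth)
    frame = data.copy()
    resp = frame["responded"].fillna(False).astype(bool).to_numpy()
    if resp.sum() == 0:
        frame["int_weight"] = np.nan
        return frame
    w = np.full(len(frame), np.nan)
    for (sex, region), sub_idx in frame.groupby(["sex", "region"], observed=True).indices.items():
        sub = frame.iloc[sub_idx]
        sub_resp = resp[sub_idx]
        samp = sub["age_group"].value_counts().to_dict()
        part = sub.loc[sub_resp, "age_group"].value_counts().to_dict()
        if sum(part.values()) == 0:
            logger.warning("no participants in stratum %s/%s; weights undefined there", sex, region)
            continue
        if any(samp.get(ag, 0) > 0 and part.get(ag, 0) == 0 for ag in AGE_GROUPS):
            logger.warning("collapsing empty age cells in stratum %s/%s", sex, region)
        cell_w = _collapse_age_weights(samp, part)
        w[sub_idx] = sub["age_group"].map(cell_w).to_numpy(dtype=float)
    w[~resp] = np.nan
    mean_w = np.nanmean(w[resp])
    frame["int_weight"] = w / mean_w
    return frame
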