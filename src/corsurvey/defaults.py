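"""Packaged default generator configuration.

The defaults encode the study conditions of a three-year English
health-survey fielding: ~44,300 sampled adults, an individual response rate
of 58%, contact attempts 1-18 with mean 4.44 (SD 2.84) among participants,
18.8% of participants needing 7+ attempts and 90% interviewed within 8;
drinking levels per sex and contact group at the published weighted values,
with the hard-to-contact group's conditional (fully adjusted) odds ratios
for exceeding the daily guideline and heavy episodic drinking embedded
directly.  The fielding intercepts/slopes and the drinking-model intercepts
and demographic scalings below were obtained once by moment-matching
simulation against those targets and are frozen.
"""

from __future__ import annotations

import math

from .config import DrinkingModel, GeneratorConfig, LogisticBlock

#: weighted demographic composition used as sampling marginals
_MARGINALS = {
    "sex": {"men": 0.487, "women": 0.513},
    "age_group": {"18-34": 0.286, "35-54": 0.359, "55+": 0.355},
    "econ_activity": {"in_work": 0.580, "not_in_work": 0.420},
    "income_q": {1: 0.186, 2: 0.187, 3: 0.193, 4: 0.221, 5: 0.213},
    "imd_q": {1: 0.2012, 2: 0.2115, 3: 0.2108, 4: 0.1931, 5: 0.1834},
    "region": {
        "north_east": 0.0507,
        "north_west": 0.1331,
        "yorkshire_humber": 0.1012,
        "east_midlands": 0.0867,
        "west_midlands": 0.1057,
        "east_england": 0.1096,
        "london": 0.1475,
        "south_east": 0.1631,
        "south_west": 0.1024,
    },
}

#: latent-resistance loadings (centred within each variable); young, in-work
#: and London adults are hardest to pin down
_LOADINGS = {
    "age_group": {"18-34": 1.008, "35-54": 0.672, "55+": -1.488},
    "econ_activity": {"in_work": 0.528, "not_in_work": -0.720},
    "region": {
        "north_east": 0.288,
        "north_west": 0.072,
        "yorkshire_humber": -0.840,
        "east_midlands": -0.096,
        "west_midlands": 0.0,
        "east_england": -0.120,
        "london": 0.912,
        "south_east": -0.216,
        "south_west": -0.312,
    },
}

# fielding parameters frozen by moment-matching (see calibration note in
# docs/methods.md); placeholders here are replaced by _FIELDING below
_FIELDING = {
    "willingness_intercept": 0.3619,
    "willingness_slope": 0.2910,
    "contact_intercept": -2.8431,
    "contact_slope": 0.2172,
    "contact_escalation": 1.9796,
    "contact_saturation": 0.2584,
}

#: conditional (fully adjusted) log-odds of the 7+ group on each outcome
_GROUP_BETAS = {
    "men": {
        "drinks_now": math.log(1.14),
        "last_week": -0.1944,
        "exceed_daily": math.log(1.12),
        "heavy_episodic": math.log(1.10),
        "exceed_weekly": math.log(1.09),
    },
    "women": {
        "drinks_now": math.log(0.96),
        "last_week": -0.1234,
        "exceed_daily": math.log(1.19),
        "heavy_episodic": math.log(1.23),
        "exceed_weekly": math.log(1.05),
    },
}

#: unscaled demographic log-odds profiles; each outcome's profile is scaled
#: by a per-outcome factor during calibration (folded into the frozen coefs)
_RAW_PROFILES = {
    "drinks_now": {
        "age_group": {"18-34": 0.05, "35-54": 0.10, "55+": -0.15},
        "econ_activity": {"in_work": 0.20, "not_in_work": -0.28},
        "income_q": {1: -0.55, 2: -0.25, 3: 0.0, 4: 0.25, 5: 0.55},
        "imd_q": {1: 0.25, 2: 0.12, 3: 0.0, 4: -0.12, 5: -0.25},
        "region": {
            "north_east": 0.10, "north_west": 0.05, "yorkshire_humber": 0.05,
            "east_midlands": 0.0, "west_midlands": 0.0, "east_england": 0.0,
            "london": -0.30, "south_east": 0.05, "south_west": 0.05,
        },
    },
    "last_week": {
        "age_group": {"18-34": 0.0, "35-54": 0.10, "55+": -0.10},
        "econ_activity": {"in_work": 0.20, "not_in_work": -0.28},
        "income_q": {1: -0.45, 2: -0.20, 3: 0.0, 4: 0.20, 5: 0.45},
        "imd_q": {1: 0.15, 2: 0.08, 3: 0.0, 4: -0.08, 5: -0.15},
        "region": {
            "north_east": 0.08, "north_west": 0.04, "yorkshire_humber": 0.04,
            "east_midlands": 0.0, "west_midlands": 0.0, "east_england": 0.0,
            "london": -0.25, "south_east": 0.04, "south_west": 0.04,
        },
    },
    "exceed_daily": {
        "age_group": {"18-34": 0.60, "35-54": 0.25, "55+": -0.74},
        "econ_activity": {"in_work": 0.25, "not_in_work": -0.35},
        "income_q": {1: -0.25, 2: -0.10, 3: 0.0, 4: 0.12, 5: 0.25},
        "imd_q": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        "region": {
            "north_east": 0.25, "north_west": 0.15, "yorkshire_humber": 0.10,
            "east_midlands": 0.0, "west_midlands": 0.0, "east_england": -0.05,
            "london": -0.25, "south_east": 0.0, "south_west": 0.0,
        },
    },
    "heavy_episodic": {
        "age_group": {"18-34": 0.80, "35-54": 0.20, "55+": -0.86},
        "econ_activity": {"in_work": 0.25, "not_in_work": -0.35},
        "income_q": {1: -0.20, 2: -0.08, 3: 0.0, 4: 0.10, 5: 0.20},
        "imd_q": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        "region": {
            "north_east": 0.30, "north_west": 0.20, "yorkshire_humber": 0.12,
            "east_midlands": 0.0, "west_midlands": 0.0, "east_england": -0.05,
            "london": -0.30, "south_east": 0.0, "south_west": 0.0,
        },
    },
    "exceed_weekly": {
        "age_group": {"18-34": 0.10, "35-54": 0.10, "55+": -0.18},
        "econ_activity": {"in_work": 0.10, "not_in_work": -0.14},
        "income_q": {1: -0.30, 2: -0.12, 3: 0.0, 4: 0.15, 5: 0.30},
        "imd_q": {1: 0.05, 2: 0.02, 3: 0.0, 4: -0.02, 5: -0.05},
        "region": {
            "north_east": 0.15, "north_west": 0.10, "yorkshire_humber": 0.05,
            "east_midlands": 0.0, "west_midlands": 0.0, "east_england": 0.0,
            "london": -0.15, "south_east": 0.0, "south_west": 0.0,
        },
    },
}

#: frozen calibration output: per sex × outcome (intercept, profile scale)
_ALPHA_SCALE = {
    "men": {
        "drinks_now": (1.5097, 0.5254),
        "last_week": (0.6216, 1.0),
        "exceed_daily": (-0.5486, 0.7331),
        "heavy_episodic": (-1.4000, 0.5790),
        "exceed_weekly": (-1.2177, 0.3713),
    },
    "women": {
        "drinks_now": (1.0739, 0.9504),
        "last_week": (0.2317, 1.0),
        "exceed_daily": (-1.0362, 0.7044),
        "heavy_episodic": (-2.2015, 1.1215),
        "exceed_weekly": (-1.6821, 1.7405),
    },
}

#: beta-binomial (a, b) for drinking days (1 + BetaBin(6, a, b)) among
#: last-week drinkers, matched to the published group means/SDs
_DAYS_AB = {
    "men": {"low": (0.525, 0.845), "high": (0.500, 1.000)},
    "women": {"low": (0.391, 0.913), "high": (0.491, 1.350)},
}

#: within-band shapes for heaviest-day units and weekly units
_HEAVIEST_SHAPE = {
    "men": {"low_beta": (1.6, 1.0), "mid_beta": (1.0, 1.0), "tail_gamma": (1.15, 5.9)},
    "women": {"low_beta": (1.6, 1.0), "mid_beta": (1.0, 1.0), "tail_gamma": (1.1, 5.6)},
}
_WEEKLY_SHAPE = {
    "men": {"sub_beta": (0.85, 1.45), "tail_gamma": (0.8, 26.5), "tail_gamma_high": (0.8, 28.1)},
    "women": {"sub_beta": (0.85, 1.45), "tail_gamma": (0.8, 15.1), "tail_gamma_high": (0.8, 18.5)},
}


def _build_drinking_model() -> DrinkingModel:
    models = {}
    for sex in ("men", "women"):
        blocks = {}
        for outcome, profile in _RAW_PROFILES.items():
            alpha, scale = _ALPHA_SCALE[sex][outcome]
            coef = {
                var: {cat: scale * val for cat, val in cats.items()}
                for var, cats in profile.items()
            }
            blocks[outcome] = LogisticBlock(
                intercept=alpha, coef=coef, group_beta=_GROUP_BETAS[sex][outcome]
            )
        models[sex] = blocks
    return DrinkingModel(
        models=models,
        days_ab={s: dict(v) for s, v in _DAYS_AB.items()},
        heaviest_shape={s: dict(v) for s, v in _HEAVIEST_SHAPE.items()},
        weekly_shape={s: dict(v) for s, v in _WEEKLY_SHAPE.items()},
    )


def default_config() -> GeneratorConfig:
    """The packaged default configuration (see module docstring)."""
    cfg = GeneratorConfig(
        n_sampled=44303,
        survey_years=(2011, 2012, 2013),
        demographic_marginals={k: dict(v) for k, v in _MARGINALS.items()},
        resistance_loadings={k: dict(v) for k, v in _LOADINGS.items()},
        willingness_intercept=_FIELDING["willingness_intercept"],
        willingness_slope=_FIELDING["willingness_slope"],
        contact_intercept=_FIELDING["contact_intercept"],
        contact_slope=_FIELDING["contact_slope"],
        contact_escalation=_FIELDING["contact_escalation"],
        contact_saturation=_FIELDING["contact_saturation"],
        max_attempts=18,
        drinking_model=_build_drinking_model(),
        resistance_noise_sd=1.0,
        item_nonresponse_rate=0.012,
        nonparticipant_excess=0.0,
        seed=0,
    )
    cfg.validate()
    return cfg
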