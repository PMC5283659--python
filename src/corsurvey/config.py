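"""Configuration objects for the synthetic survey generator.

The generator is parameterised by a single :class:`GeneratorConfig` holding

* the demographic composition of the sampled adult population,
* a latent-resistance model linking demographics to how hard a person is
  to recruit,
* a two-stage fielding model (willingness to ever cooperate, then a
  per-attempt contact hazard), and
* a drinking model that sets the level of each alcohol measure and its
  conditional association with the hard-to-contact group.

Configurations round-trip through YAML with field names mirrored 1:1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

SEXES = ("men", "women")
AGE_GROUPS = ("18-34", "35-54", "55+")
ECON_ACTIVITY = ("in_work", "not_in_work")
QUINTILES = (1, 2, 3, 4, 5)
REGIONS = (
    "north_east",
    "north_west",
    "yorkshire_humber",
    "east_midlands",
    "west_midlands",
    "east_england",
    "london",
    "south_east",
    "south_west",
)

DEMOGRAPHIC_LEVELS: dict[str, tuple] = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "econ_activity": ECON_ACTIVITY,
    "income_q": QUINTILES,
    "imd_q": QUINTILES,
    "region": REGIONS,
}

#: Names of the binary drinking outcomes modelled on the log-odds scale.
OUTCOME_NAMES = (
    "drinks_now",
    "last_week",
    "exceed_daily",
    "heavy_episodic",
    "exceed_weekly",
)

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class LogisticBlock:
    """One log-odds model: intercept + categorical demographic effects + group effect.

    ``coef`` maps demographic variable name -> {category: log-odds offset};
    ``group_beta`` is the conditional log-odds effect of being in the
    hard-to-contact (7+ attempts) group given all the demographic terms.
    """

    intercept: float
    coef: dict[str, dict[Any, float]] = field(default_factory=dict)
    group_beta: float = 0.0

    def linear_predictor(self, frame, high) -> "Any":
        import numpy as np

        lp = np.full(len(frame), self.intercept, dtype=float)
        for var, levels in self.coef.items():
            lp += frame[var].map(levels).to_numpy(dtype=float)
        lp += self.group_beta * np.asarray(high, dtype=float)
        return lp


@dataclass
class DrinkingModel:
    """Per-sex drinking generator.

    ``models[sex][outcome]`` are :class:`LogisticBlock`\\ s for the nested
    binary outcomes (drinks nowadays ⊇ drank last week ⊇ exceeded daily
    guideline ⊇ heavy episodic; exceeding the weekly guideline is nested in
    drinks nowadays only).  The continuous variables are generated within
    the bands those indicators define:

    * ``days_ab[sex][group]``: (a, b) of the beta-binomial for drinking days
      among last-week drinkers, days = 1 + BetaBin(6, a, b);
    * ``heaviest_shape[sex]``: within-band shapes for heaviest-day units —
      ``low_beta`` on (0, daily], ``mid_beta`` on (daily, episodic],
      ``tail_gamma`` (shape, scale) above the episodic threshold;
    * ``weekly_shape[sex]``: ``sub_beta`` on (0, weekly] and ``tail_gamma``
      above the weekly threshold (optionally ``tail_gamma_high`` for the
      hard-to-contact group's heavier tail).
    """

    models: dict[str, dict[str, LogisticBlock]]
    days_ab: dict[str, dict[str, tuple[float, float]]]
    heaviest_shape: dict[str, dict[str, tuple[float, float]]]
    weekly_shape: dict[str, dict[str, tuple[float, float]]]

    def _group_betas(self, outcome: str) -> dict[str, float]:
        return {sex: self.models[sex][outcome].group_beta for sex in self.models}

    @property
    def p_drinker_beta(self) -> dict[str, float]:
        return self._group_betas("drinks_now")

    @property
    def exceed_daily_beta(self) -> dict[str, float]:
        return self._group_betas("exceed_daily")

    @property
    def heavy_episodic_beta(self) -> dict[str, float]:
        return self._group_betas("heavy_episodic")

    @property
    def exceed_weekly_beta(self) -> dict[str, float]:
        return self._group_betas("exceed_weekly")


@dataclass
class GeneratorConfig:
    """All simulation parameters for the synthetic survey."""

    n_sampled: int
    survey_years: tuple[int, ...]
    demographic_marginals: dict[str, dict[Any, float]]
    resistance_loadings: dict[str, dict[Any, float]]
    willingness_intercept: float
    willingness_slope: float
    contact_intercept: float
    contact_slope: float
    #: total rise of the contact logit over repeated attempts; attempt t has
    #: logit contact_intercept + contact_escalation·(1 − contact_saturation^(t−1))
    #: − contact_slope·resistance.  A positive value models appointment-making
    #: once first contact is established and underdisperses the attempts
    #: distribution relative to a geometric; contact_saturation in [0, 1)
    #: controls how quickly the rise levels off.
    contact_escalation: float
    contact_saturation: float
    max_attempts: int
    drinking_model: DrinkingModel
    #: SD of the person-level Gaussian noise added to the resistance linear
    #: predictor (1.0 = standard-normal, the reference scale of the latent)
    resistance_noise_sd: float = 1.0
    #: probability that each drinking item is independently missing for a
    #: participant (item non-response, missing completely at random)
    item_nonresponse_rate: float = 0.0
    #: extra log-odds added to every binary drinking outcome for true
    #: non-participants, beyond the hard-to-contact group effect.  Zero means
    #: non-participants are exchangeable with the 7+ group (the
    #: continuum-of-resistance assumption holds exactly).
    nonparticipant_excess: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sampled < 1:
            raise ConfigError("n_sampled must be >= 1")
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")
        if not (0.0 <= self.item_nonresponse_rate < 1.0):
            raise ConfigError("item_nonresponse_rate must be in [0, 1)")
        if not (0.0 <= self.contact_saturation < 1.0):
            raise ConfigError("contact_saturation must be in [0, 1)")
        for var, levels in DEMOGRAPHIC_LEVELS.items():
            probs = self.demographic_marginals.get(var)
            if probs is None:
                raise ConfigError(f"missing marginal for {var!r}")
            unknown = set(probs) - set(levels)
            if unknown:
                raise ConfigError(f"unknown categories for {var!r}: {sorted(map(str, unknown))}")
            vals = list(probs.values())
            if any(p < 0 for p in vals):
                raise ConfigError(f"negative probability in marginal for {var!r}")
            if abs(sum(vals) - 1.0) > _PROB_TOL:
                raise ConfigError(
                    f"marginal for {var!r} sums to {sum(vals)!r}, not 1"
                )
        for var in self.resistance_loadings:
            if var not in DEMOGRAPHIC_LEVELS:
                raise ConfigError(f"resistance loading on unknown variable {var!r}")

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)


def _block_to_dict(block: LogisticBlock) -> dict:
    return {
        "intercept": block.intercept,
        "coef": {v: dict(c) for v, c in block.coef.items()},
        "group_beta": block.group_beta,
    }


def _block_from_dict(d: dict) -> LogisticBlock:
    return LogisticBlock(
        intercept=float(d["intercept"]),
        coef={v: {k: float(x) for k, x in c.items()} for v, c in d.get("coef", {}).items()},
        group_beta=float(d.get("group_beta", 0.0)),
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["survey_years"] = list(config.survey_years)
    d["drinking_model"] = {
        "models": {
            sex: {name: _block_to_dict(b) for name, b in blocks.items()}
            for sex, blocks in config.drinking_model.models.items()
        },
        "days_ab": {
            sex: {g: list(ab) for g, ab in per.items()}
            for sex, per in config.drinking_model.days_ab.items()
        },
        "heaviest_shape": {
            sex: {k: list(v) for k, v in per.items()}
            for sex, per in config.drinking_model.heaviest_shape.items()
        },
        "weekly_shape": {
            sex: {k: list(v) for k, v in per.items()}
            for sex, per in config.drinking_model.weekly_shape.items()
        },
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    dm = d["drinking_model"]
    model = DrinkingModel(
        models={
            sex: {name: _block_from_dict(b) for name, b in blocks.items()}
            for sex, blocks in dm["models"].items()
        },
        days_ab={
            sex: {g: tuple(map(float, ab)) for g, ab in per.items()}
            for sex, per in dm["days_ab"].items()
        },
        heaviest_shape={
            sex: {k: tuple(map(float, v)) for k, v in per.items()}
            for sex, per in dm["heaviest_shape"].items()
        },
        weekly_shape={
            sex: {k: tuple(map(float, v)) for k, v in per.items()}
            for sex, per in dm["weekly_shape"].items()
        },
    )
    cfg = GeneratorConfig(
        n_sampled=int(d["n_sampled"]),
        survey_years=tuple(int(y) for y in d["survey_years"]),
        demographic_marginals={
            v: {k: float(p) for k, p in per.items()}
            for v, per in d["demographic_marginals"].items()
        },
        resistance_loadings={
            v: {k: float(p) for k, p in per.items()}
            for v, per in d.get("resistance_loadings", {}).items()
        },
        willingness_intercept=float(d["willingness_intercept"]),
        willingness_slope=float(d["willingness_slope"]),
        contact_intercept=float(d["contact_intercept"]),
        contact_slope=float(d["contact_slope"]),
        contact_escalation=float(d.get("contact_escalation", 0.0)),
        contact_saturation=float(d.get("contact_saturation", 0.0)),
        max_attempts=int(d["max_attempts"]),
        drinking_model=model,
        resistance_noise_sd=float(d.get("resistance_noise_sd", 1.0)),
        item_nonresponse_rate=float(d.get("item_nonresponse_rate", 0.0)),
        nonparticipant_excess=float(d.get("nonparticipant_excess", 0.0)),
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def config_to_yaml(config: GeneratorConfig, path=None) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> GeneratorConfig:
    """Load a configuration from a YAML string or file path."""
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            d = yaml.safe_load(fh)
    else:
        d = yaml.safe_load(source)
    return config_from_dict(d)
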