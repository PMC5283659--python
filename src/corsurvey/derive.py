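"""Analytic variable derivation: guideline indicators and the contact dichotomy.

The pre-2016 UK guidance thresholds are sex-specific and the comparison is
strictly greater-than throughout: a man whose heaviest day was exactly 4.0
units did not exceed the daily guideline.  Indicators inherit the
missingness of their source fields (complete-case propagation), and
non-drinkers stay in the denominators of all exceedance indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import SEXES


class ContactGroup(str, Enum):
    """Contact-attempt dichotomy: 1-6 calls vs 7 or more."""

    LOW = "1-6"
    HIGH = "7+"


#: attempts strictly below this count are the easy-to-contact group
HIGH_GROUP_MIN_ATTEMPTS = 7


@dataclass(frozen=True)
class DrinkingThresholds:
    """Sex-specific drinking thresholds in UK units (1 unit = 8 g ethanol).

    ``daily_limit``: heaviest-day units above which the (pre-2016) daily
    guideline is exceeded; ``heavy_episodic``: heaviest-day units defining
    heavy episodic drinking; ``weekly_limit``: weekly units above which the
    weekly guideline is exceeded.  All comparisons are strict.
    """

    daily_limit: dict = None
    heavy_episodic: dict = None
    weekly_limit: dict = None

    def __post_init__(self):
        object.__setattr__(self, "daily_limit", dict(self.daily_limit or {"men": 4.0, "women": 3.0}))
        object.__setattr__(
            self, "heavy_episodic", dict(self.heavy_episodic or {"men": 8.0, "women": 6.0})
        )
        object.__setattr__(
            self, "weekly_limit", dict(self.weekly_limit or {"men": 21.0, "women": 14.0})
        )
        for name in ("daily_limit", "heavy_episodic", "weekly_limit"):
            th = getattr(self, name)
            if set(th) != set(SEXES):
                raise ValueError(f"{name} must define thresholds for {SEXES}")
            if any(v <= 0 for v in th.values()):
                raise ValueError(f"{name} thresholds must be positive")
            if th["men"] <= th["women"]:
                raise ValueError(f"{name}: men's threshold must exceed women's")


def contact_group(attempts):
    """Classify contact attempts into the 1-6 / 7+ dichotomy.

    Accepts a scalar or an array-like; attempts must be integers >= 1
    (non-participants have no contact group).
    """
    arr = np.asarray(attempts, dtype=float)
    if arr.size == 0:
        return np.empty(0, dtype=object) if np.ndim(attempts) else None
    if np.any(~np.isfinite(arr)) or np.any(arr < 1) or np.any(arr != np.round(arr)):
        raise ValueError("attempts must be integers >= 1 (participants only)")
    groups = np.where(arr < HIGH_GROUP_MIN_ATTEMPTS, ContactGroup.LOW.value, ContactGroup.HIGH.value)
    if np.ndim(attempts) == 0:
        return ContactGroup(groups.item())
    return groups


def derive_indicators(frame: pd.DataFrame, thresholds: DrinkingThresholds | None = None) -> pd.DataFrame:
    """Add derived drinking indicators and the contact group to an analytic table.

    Adds (or recomputes, idempotently) ``is_drinker``, ``exceed_daily``,
    ``heavy_episodic``, ``exceed_weekly`` and ``contact_group``.  Each
    indicator is missing exactly where its source field is missing.
    ``drink_days`` and ``max_day_units`` remain conditional-on-drinking
    quantities and are left untouched.
    """
    thresholds = thresholds or DrinkingThresholds()
    out = frame.copy()
    unknown = set(out["sex"].dropna().unique()) - set(SEXES)
    if unknown:
        raise ValueError(f"unknown sex codes: {sorted(map(str, unknown))}")

    out["is_drinker"] = out["drinks_now"].astype("boolean")

    def _exceed(source: str, limits: dict) -> pd.Series:
        lim = out["sex"].map(limits)
        ind = pd.Series(out[source] > lim, dtype="boolean")
        ind[out[source].isna() | out["sex"].isna()] = pd.NA
        return ind

    out["exceed_daily"] = _exceed("max_day_units", thresholds.daily_limit)
    out["heavy_episodic"] = _exceed("max_day_units", thresholds.heavy_episodic)
    out["exceed_weekly"] = _exceed("weekly_units", thresholds.weekly_limit)

    grp = pd.Series(pd.NA, index=out.index, dtype="object")
    resp = out["responded"].fillna(False).astype(bool)
    att = out.loc[resp, "attempts"]
    if att.isna().any():
        raise ValueError("participant rows with missing attempts")
    if len(att):
        grp.loc[resp] = contact_group(att.to_numpy(dtype=int))
    out["contact_group"] = grp
    return out
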