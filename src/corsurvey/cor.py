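"""The continuum-of-resistance non-response adjustment.

The adjusted population estimate is the response-proportion-weighted blend

    adjusted = participant_estimate · r + nonparticipant_estimate · (1 − r)

with the non-participant estimate taken to be the estimate among the
participants who were hardest to contact (7+ attempts).  The same formula is
applied to prevalences and to means.  ``sales_coverage`` expresses a mean
weekly consumption as a percentage of per-capita sales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import weighted_mean_sd, weighted_proportion


@dataclass
class CORResult:
    """One measure's estimates before and after the adjustment."""

    measure: str
    participant_estimate: float
    hard_group_estimate: float
    response_proportion: float
    adjusted_estimate: float
    abs_difference: float
    pct_change: float


def cor_adjust(participant_estimate: float, hard_group_estimate: float, r: float) -> float:
    """Blend the participant estimate with the hard-to-contact estimate.

    ``r`` is the response proportion in (0, 1].  Both estimates must be the
    same kind of quantity (two proportions on [0, 1] scale, or two
    non-negative means); the output always lies between them.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError("response proportion r must be in (0, 1]")
    p, h = float(participant_estimate), float(hard_group_estimate)
    if p < 0 or h < 0:
        raise ValueError("estimates must be non-negative")
    both_prop = p <= 1.0 and h <= 1.0
    if not both_prop and (p <= 1.0) != (h <= 1.0) and min(p, h) < 0.5:
        # one argument looks like a proportion, the other like a mean
        raise ValueError("mixed estimate kinds (proportion vs mean)")
    return p * r + h * (1.0 - r)


def sales_coverage(mean_weekly_units: float, sales_units_per_capita: float) -> float:
    """Survey coverage of per-capita sales, in percent."""
    if mean_weekly_units <= 0 or sales_units_per_capita <= 0:
        raise ValueError("both arguments must be positive")
    return 100.0 * mean_weekly_units / sales_units_per_capita


#: adjusted measures: (column, label, kind, restrict to last-week drinkers)
COR_MEASURES = [
    ("is_drinker", "Prevalence of drinking nowadays", "binary", False),
    ("drink_days", "Drinking days in last week, among drinkers (mean number)", "mean", True),
    ("max_day_units", "Alcohol consumed on heaviest drinking day in the last week (mean units)", "mean", True),
    ("exceed_daily", "Prevalence of drinking above daily guidelines (>4/3 units)", "binary", False),
    ("heavy_episodic", "Prevalence of heavy episodic drinking (>8/6 units)", "binary", False),
    ("weekly_units", "Average weekly alcohol consumption (mean units)", "mean", False),
    ("exceed_weekly", "Prevalence of drinking above weekly guidelines (>21/14 units)", "binary", False),
]


def _estimate(sub: pd.DataFrame, col: str, kind: str, weights=None) -> float:
    vals = pd.to_numeric(sub[col], errors="coerce")
    if weights is None:
        w = pd.Series(1.0, index=sub.index)
    else:
        w = sub[weights]
    keep = ~(vals.isna() | w.isna())
    if keep.sum() == 0:
        return np.nan
    if kind == "binary":
        return weighted_proportion(vals[keep], w[keep]).estimate
    return weighted_mean_sd(vals[keep], w[keep]).estimate


def cor_table(dataset, r: float | None = None) -> pd.DataFrame:
    """Per-sex unadjusted / weighted / continuum-of-resistance estimates.

    ``r`` defaults to the simulated overall response proportion
    (participants / sampled adults).  Prevalences are reported in percent;
    means in their natural units.  Differences and percentage changes are
    computed from unrounded intermediates.
    """
    from .simulate import SurveyDataset

    frame = dataset.frame if isinstance(dataset, SurveyDataset) else dataset
    resp = frame["responded"].fillna(False).astype(bool)
    if r is None:
        r = float(resp.mean())
    if not (0.0 < r <= 1.0):
        raise ValueError("response proportion r must be in (0, 1]")
    part = frame[resp]
    if "contact_group" not in part.columns:
        raise ValueError("dataset must be derived first (missing contact_group)")

    rows = []
    for sex in ("men", "women"):
        ssub = part[part["sex"] == sex]
        for col, label, kind, lastweek_only in COR_MEASURES:
            sub = ssub
            if lastweek_only:
                sub = ssub[pd.to_numeric(ssub["drink_days"], errors="coerce") >= 1]
            unadj = _estimate(sub, col, kind)
            weighted = _estimate(sub, col, kind, weights="int_weight")
            hard = _estimate(sub[sub["contact_group"] == "7+"], col, kind, weights="int_weight")
            adjusted = cor_adjust(weighted, hard, r) if np.isfinite(weighted) and np.isfinite(hard) else np.nan
            diff = adjusted - weighted
            pct = 100.0 * diff / weighted if weighted not in (0.0,) and np.isfinite(weighted) else np.nan
            scale = 100.0 if kind == "binary" else 1.0
            rows.append(
                {
                    "sex": sex,
                    "measure": label,
                    "unadjusted": scale * unadj,
                    "weighted": scale * weighted,
                    "hard_group": scale * hard,
                    "adjusted": scale * adjusted,
                    "difference": scale * diff,
                    "pct_change": pct,
                    "response_proportion": r,
                }
            )
    return pd.DataFrame(rows)
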