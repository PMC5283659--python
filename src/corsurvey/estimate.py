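"""Weighted descriptive statistics and the paired significance tests.

Conventions, chosen so that unit weights reduce every statistic to its
textbook form:

* proportions and means use normalised weights (Σw·x / Σw);
* the descriptive SD is the population form sqrt(Σw·(x−m)² / Σw);
* the chi-squared test rescales weights to sum to the unweighted n before
  forming the contingency table (Pearson, no continuity correction);
* the t-test is Welch's, with each weighted mean's variance taken as the
  Bessel-corrected weighted variance over the Kish effective sample size
  n_eff = (Σw)² / Σw².

All statistics are invariant to multiplying the weights by a positive
constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class WeightedEstimate:
    """A weighted point estimate with its dispersion and bases."""

    estimate: float
    sd_or_se: Optional[float]
    weighted_n: float
    unweighted_n: int


def _clean(values, weights):
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    keep = ~(np.isnan(x) | np.isnan(w))
    x, w = x[keep], w[keep]
    if x.size == 0:
        raise ValueError("no observations left after missing-value exclusion")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return x, w


def weighted_proportion(values, weights) -> WeightedEstimate:
    """Weighted proportion of a binary variable (pairwise complete)."""
    x, w = _clean(values, weights)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("values must be binary (0/1)")
    p = float(np.sum(w * x) / np.sum(w))
    se = float(np.sqrt(p * (1 - p) / _kish_n(w)))
    return WeightedEstimate(p, se, float(np.sum(w)), int(x.size))


def weighted_mean_sd(values, weights) -> WeightedEstimate:
    """Weighted mean and population-form weighted SD."""
    x, w = _clean(values, weights)
    m = float(np.sum(w * x) / np.sum(w))
    if x.size == 1:
        return WeightedEstimate(m, None, float(np.sum(w)), 1)
    sd = float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w)))
    return WeightedEstimate(m, sd, float(np.sum(w)), int(x.size))


def _kish_n(w: np.ndarray) -> float:
    return float(np.sum(w) ** 2 / np.sum(w ** 2))


def weighted_chisq(group, category, weights):
    """Pearson chi-squared on the weighted contingency table.

    Weights are rescaled to sum to the unweighted n of the complete rows, so
    the statistic has its classical null distribution under unit weights.
    Returns (statistic, df, p).
    """
    g = pd.Series(group).reset_index(drop=True)
    c = pd.Series(category).reset_index(drop=True)
    w = pd.Series(np.asarray(weights, dtype=float)).reset_index(drop=True)
    keep = ~(g.isna() | c.isna() | w.isna())
    g, c, w = g[keep], c[keep], w[keep]
    if len(g) == 0:
        raise ValueError("no observations left after missing-value exclusion")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    w = w * (len(w) / w.sum())
    table = pd.crosstab(g, c, values=w, aggfunc="sum").fillna(0.0)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (need >=2 groups and categories)")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate contingency table (empty row or column)")
    stat, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), int(df), float(p)


def weighted_t_test(values, weights, group):
    """Two-sample Welch t-test on weighted means with Kish effective n.

    Returns (t, df, p).  With unit weights this is exactly the ordinary
    Welch test.
    """
    g = pd.Series(group).reset_index(drop=True)
    x = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    w = pd.Series(np.asarray(weights, dtype=float)).reset_index(drop=True)
    keep = ~(g.isna() | x.isna() | w.isna())
    g, x, w = g[keep], x[keep], w[keep]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("t-test requires exactly two groups")
    stats_per = []
    for lev in levels:
        xi = x[g == lev].to_numpy()
        wi = w[g == lev].to_numpy()
        if xi.size < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
        if np.any(wi <= 0):
            raise ValueError("weights must be positive")
        sw = wi.sum()
        m = np.sum(wi * xi) / sw
        denom = sw - np.sum(wi ** 2) / sw  # Bessel correction for reliability weights
        if denom <= 0:
            raise ValueError("degenerate weights (effective n <= 1)")
        s2 = np.sum(wi * (xi - m) ** 2) / denom
        neff = _kish_n(wi)
        stats_per.append((m, s2, neff))
    (m1, s1, n1), (m2, s2, n2) = stats_per
    if s1 == 0 and s2 == 0:
        raise ValueError("zero variance in both groups")
    v1, v2 = s1 / n1, s2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


_DEMOGRAPHIC_ROWS = [
    ("sex", "Sex"),
    ("age_group", "Age group"),
    ("econ_activity", "Economic activity"),
    ("income_q", "Equivalised income quintile"),
    ("imd_q", "Deprivation quintile"),
    ("region", "Region"),
]

#: drinking table rows: (column, label, kind, conditional-on-last-week flag)
_DRINKING_ROWS = [
    ("is_drinker", "Whether drinks nowadays", "binary", False),
    ("exceed_daily", "Drank more than daily guideline (>4/3 units)", "binary", False),
    ("heavy_episodic", "Heavy episodic drinking (>8/6 units)", "binary", False),
    ("exceed_weekly", "Drank more than weekly guideline (21/14 units)", "binary", False),
    ("drink_days", "Number of drinking days in the past week", "mean", True),
    ("max_day_units", "Units consumed on heaviest drinking day in the last week", "mean", True),
    ("weekly_units", "Weekly alcohol consumption (UK units)", "mean", False),
]


def _group_cells(sub: pd.DataFrame, col: str, kind: str):
    """Per contact-group weighted cell estimates plus the between-group test."""
    rows = {}
    for grp in ("1-6", "7+"):
        gsub = sub[sub["contact_group"] == grp]
        vals = gsub[col].astype(float)
        w = gsub["int_weight"].astype(float)
        keep = ~(vals.isna() | w.isna())
        if keep.sum() == 0:
            rows[grp] = None
            continue
        if kind == "binary":
            est = weighted_proportion(vals[keep], w[keep])
        else:
            est = weighted_mean_sd(vals[keep], w[keep])
        rows[grp] = est
    p = np.nan
    if rows["1-6"] is not None and rows["7+"] is not None:
        try:
            if kind == "binary":
                _, _, p = weighted_chisq(
                    sub["contact_group"], sub[col].astype(float), sub["int_weight"]
                )
            else:
                _, _, p = weighted_t_test(
                    sub[col].astype(float), sub["int_weight"], sub["contact_group"]
                )
        except ValueError:
            p = np.nan
    return rows, p


def descriptive_tables(dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted descriptive tables by contact group.

    Returns ``(demographic_table, drinking_table)``.  The demographic table
    gives, for each category, the weighted split between the 1-6 and 7+
    groups (row percentages) with per-variable chi-squared p-values; the
    drinking table gives per-sex weighted prevalences / means (SD) in each
    group with the between-group test.  Quantities conditional on having
    drunk in the last week are restricted to ``drink_days >= 1`` rows.
    """
    from .simulate import SurveyDataset

    frame = dataset.frame if isinstance(dataset, SurveyDataset) else dataset
    part = frame[frame["responded"].fillna(False).astype(bool)].copy()
    if "contact_group" not in part.columns:
        raise ValueError("dataset must be derived first (missing contact_group)")

    demo_rows = []
    for col, label in _DEMOGRAPHIC_ROWS:
        try:
            _, _, p_var = weighted_chisq(part["contact_group"], part[col], part["int_weight"])
        except ValueError:
            p_var = np.nan
        for cat in part[col].dropna().unique():
            sub = part[part[col] == cat]
            w = sub["int_weight"]
            high = (sub["contact_group"] == "7+").astype(float)
            try:
                est = weighted_proportion(high, w)
                share_high = est.estimate
                wn = est.weighted_n
                un = est.unweighted_n
            except ValueError:
                share_high, wn, un = np.nan, 0.0, 0
            demo_rows.append(
                {
                    "variable": label,
                    "category": str(cat),
                    "pct_low": 100 * (1 - share_high),
                    "pct_high": 100 * share_high,
                    "weighted_n": wn,
                    "unweighted_n": un,
                    "p_value": p_var,
                }
            )
    demo = pd.DataFrame(demo_rows)

    drink_rows = []
    for sex in ("men", "women"):
        sub_all = part[part["sex"] == sex]
        for col, label, kind, lastweek_only in _DRINKING_ROWS:
            sub = sub_all
            if lastweek_only:
                sub = sub_all[sub_all["drink_days"].astype(float) >= 1]
            cells, p = _group_cells(sub, col, kind)
            row = {"sex": sex, "measure": label, "p_value": p}
            for grp, tag in (("1-6", "low"), ("7+", "high")):
                est = cells[grp]
                if est is None:
                    row.update({f"{tag}_estimate": np.nan, f"{tag}_sd_or_se": np.nan,
                                f"{tag}_weighted_n": np.nan, f"{tag}_unweighted_n": 0})
                else:
                    scale = 100.0 if kind == "binary" else 1.0
                    row.update(
                        {
                            f"{tag}_estimate": scale * est.estimate,
                            f"{tag}_sd_or_se": (scale * est.sd_or_se) if est.sd_or_se is not None else np.nan,
                            f"{tag}_weighted_n": est.weighted_n,
                            f"{tag}_unweighted_n": est.unweighted_n,
                        }
                    )
            drink_rows.append(row)
    drink = pd.DataFrame(drink_rows)
    return demo, drink
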