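"""Sex-stratified weighted logistic regressions of drinking outcomes.

Fits follow the survey-analysis convention of weighted maximum likelihood
with the weights rescaled to mean 1 over the complete cases, so that
unit-weight fits are exactly classical logistic regression and the
model-based Wald standard errors are on the right scale.  The exposure is
the contact-attempt dichotomy with the easy-to-contact (1-6 calls) group as
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

ADJUSTMENT_SETS = {
    "unadjusted": [],
    "partly": ["age_group"],
    "fully": ["age_group", "econ_activity", "income_q", "imd_q", "region"],
}

OUTCOMES = ["is_drinker", "exceed_daily", "heavy_episodic", "exceed_weekly"]

Z95 = 1.959963984540054


@dataclass
class ORResult:
    """Odds ratio for the 7+ vs 1-6 contact group from one weighted fit."""

    stratum: str
    outcome: str
    adjustment: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_complete: int
    log_or: float = np.nan
    se_log_or: float = np.nan
    converged: bool = True
    flags: list = field(default_factory=list)


def _design(frame: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    X["high_group"] = (frame["contact_group"] == "7+").astype(float)
    for cov in covariates:
        dummies = pd.get_dummies(frame[cov].astype(str), prefix=cov, drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def fit_weighted_logistic(
    dataset,
    outcome: str,
    covariates: Optional[list[str]] = None,
    stratum: Optional[str] = None,
    adjustment: Optional[str] = None,
) -> ORResult:
    """Weighted logistic fit of a binary outcome on the contact dichotomy.

    ``covariates`` may be a list of column names or one of the named
    adjustment sets (via ``adjustment``: 'unadjusted', 'partly', 'fully').
    Complete-case: rows missing the outcome, any covariate, the contact
    group or the weight are dropped.  Non-convergence or separation is
    reported through ``converged``/``flags`` rather than raised.
    """
    from .simulate import SurveyDataset

    frame = dataset.frame if isinstance(dataset, SurveyDataset) else dataset
    if adjustment is not None:
        covariates = ADJUSTMENT_SETS[adjustment]
    covariates = list(covariates or [])
    label = adjustment or ("unadjusted" if not covariates else "custom")

    sub = frame[frame["responded"].fillna(False).astype(bool)]
    if stratum is not None:
        sub = sub[sub["sex"] == stratum]
        if len(sub) == 0:
            raise ValueError(f"empty stratum {stratum!r}")
    cols = [outcome, "contact_group", "int_weight"] + covariates
    sub = sub[cols].copy()
    y = pd.to_numeric(sub[outcome], errors="coerce")
    keep = ~(y.isna() | sub[["contact_group", "int_weight"]].isna().any(axis=1))
    for cov in covariates:
        keep &= ~sub[cov].isna()
    sub, y = sub[keep], y[keep]
    n = len(sub)
    if n == 0:
        raise ValueError("no complete cases")

    w = sub["int_weight"].to_numpy(dtype=float)
    w = w / w.mean()
    X = _design(sub, covariates)

    flags: list[str] = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(y.to_numpy(dtype=float), X, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200)
            converged = bool(res.converged)
            if not converged:
                flags.append("non-convergence")
        except Exception as exc:  # separation and numeric failure end up here
            flags.append(f"fit-error: {type(exc).__name__}")
            return ORResult(stratum or "all", outcome, label, np.nan, np.nan, np.nan,
                            np.nan, n, converged=False, flags=flags)

    beta = float(res.params["high_group"])
    se = float(res.bse["high_group"])
    if not np.isfinite(se) or se > 50:
        flags.append("separation-suspected")
        converged = False
    from scipy import stats as _st

    p = float(2 * _st.norm.sf(abs(beta / se))) if se > 0 else np.nan
    return ORResult(
        stratum=stratum or "all",
        outcome=outcome,
        adjustment=label,
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p_value=p,
        n_complete=n,
        log_or=beta,
        se_log_or=se,
        converged=converged,
        flags=flags,
    )


def regression_table(dataset) -> pd.DataFrame:
    """All 24 fits: 4 outcomes × 3 adjustment sets × 2 sex strata.

    Also reports, for reference, the marginal odds ratio implied by the
    weighted 2x2 table of outcome by contact group (``table_or``), which is
    generally *not* the unadjusted model OR convention-for-convention when
    weights differ between groups in printed sources.
    """
    from .estimate import weighted_proportion
    from .simulate import SurveyDataset

    frame = dataset.frame if isinstance(dataset, SurveyDataset) else dataset
    part = frame[frame["responded"].fillna(False).astype(bool)]
    rows = []
    for stratum in ("men", "women"):
        ssub = part[part["sex"] == stratum]
        for outcome in OUTCOMES:
            # weighted-table marginal OR for cross-reference
            table_or = np.nan
            try:
                ests = {}
                for grp in ("1-6", "7+"):
                    gsub = ssub[ssub["contact_group"] == grp]
                    vals = pd.to_numeric(gsub[outcome], errors="coerce")
                    wk = ~(vals.isna() | gsub["int_weight"].isna())
                    ests[grp] = weighted_proportion(vals[wk], gsub.loc[wk, "int_weight"]).estimate
                p0, p1 = ests["1-6"], ests["7+"]
                table_or = (p1 / (1 - p1)) / (p0 / (1 - p0))
            except (ValueError, ZeroDivisionError):
                pass
            for adj in ADJUSTMENT_SETS:
                r = fit_weighted_logistic(part, outcome, stratum=stratum, adjustment=adj)
                rows.append(
                    {
                        "stratum": stratum,
                        "outcome": outcome,
                        "adjustment": adj,
                        "or": r.or_point,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p_value": r.p_value,
                        "n_complete": r.n_complete,
                        "log_or": r.log_or,
                        "se_log_or": r.se_log_or,
                        "table_or": table_or,
                        "converged": r.converged,
                        "flags": ";".join(r.flags),
                    }
                )
    return pd.DataFrame(rows)
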