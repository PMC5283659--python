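"""CSV import/export of the analytic dataset (and the simulation truth table).

The analytic schema is one row per sampled adult with the columns of
:data:`corsurvey.simulate.ANALYTIC_COLUMNS`; missing values are empty
fields.  Reading validates the schema and the fielding invariants
(participants have attempts in range and a positive weight; non-participants
carry no fielding or drinking values) and reports the offending column and
row on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_GROUPS, ECON_ACTIVITY, QUINTILES, REGIONS, SEXES
from .simulate import ANALYTIC_COLUMNS, DRINKING_COLUMNS, SurveyDataset


class SchemaError(ValueError):
    """Raised when an analytic CSV violates the schema."""


_CATEGORY_DOMAINS = {
    "sex": set(SEXES),
    "age_group": set(AGE_GROUPS),
    "econ_activity": set(ECON_ACTIVITY),
    "income_q": set(QUINTILES),
    "imd_q": set(QUINTILES),
    "region": set(REGIONS),
}


def export_dataset(dataset: SurveyDataset, path, truth_path=None) -> None:
    """Write the analytic table (and optionally the truth table) to CSV."""
    frame = dataset.frame if isinstance(dataset, SurveyDataset) else dataset
    out = frame[ANALYTIC_COLUMNS].copy()
    out["responded"] = out["responded"].astype(int)
    out.to_csv(path, index=False, na_rep="")
    if truth_path is not None:
        if dataset.truth is None:
            raise ValueError("dataset has no truth table")
        dataset.truth.to_csv(truth_path, index=False, na_rep="")


def _fail(column: str, row) -> None:
    raise SchemaError(f"column {column!r}, row {row}: invalid value")


def read_dataset(path) -> SurveyDataset:
    """Read and validate an analytic CSV written by :func:`export_dataset`."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"sex": str, "age_group": str, "econ_activity": str, "region": str})
    missing = [c for c in ANALYTIC_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    frame = raw[ANALYTIC_COLUMNS].copy()

    for col in ("person_id", "survey_year"):
        if frame[col].isna().any():
            _fail(col, int(frame[frame[col].isna()].index[0]))
    for col, domain in _CATEGORY_DOMAINS.items():
        vals = frame[col].dropna()
        if col in ("income_q", "imd_q"):
            vals = vals.astype(int)
            frame[col] = frame[col].astype("Int64")
        bad = ~vals.isin(list(domain))
        if bad.any():
            _fail(col, int(vals[bad].index[0]))

    if not frame["responded"].isin([0, 1]).all():
        _fail("responded", int(frame[~frame["responded"].isin([0, 1])].index[0]))
    frame["responded"] = frame["responded"].astype(bool)
    resp = frame["responded"]

    frame["attempts"] = pd.to_numeric(frame["attempts"], errors="coerce").astype("Int64")
    if frame.loc[resp, "attempts"].isna().any():
        _fail("attempts", int(frame[resp & frame["attempts"].isna()].index[0]))
    if (frame.loc[resp, "attempts"] < 1).any():
        _fail("attempts", int(frame[resp & (frame["attempts"] < 1)].index[0]))
    nonresp_attempts = (~resp) & frame["attempts"].notna()
    if nonresp_attempts.any():
        _fail("attempts", int(frame[nonresp_attempts].index[0]))

    frame["int_weight"] = pd.to_numeric(frame["int_weight"], errors="coerce")
    if (frame.loc[resp, "int_weight"] <= 0).any() or frame.loc[resp, "int_weight"].isna().any():
        bad = resp & ~(frame["int_weight"] > 0)
        _fail("int_weight", int(frame[bad].index[0]))
    if frame.loc[~resp, "int_weight"].notna().any():
        _fail("int_weight", int(frame[(~resp) & frame["int_weight"].notna()].index[0]))

    for col in DRINKING_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        has_raw = frame[col].notna()
        if (has_raw & vals.isna()).any():
            _fail(col, int(frame[has_raw & vals.isna()].index[0]))
        if ((~resp) & has_raw).any():
            _fail(col, int(frame[(~resp) & has_raw].index[0]))
        frame[col] = vals
    frame["drinks_now"] = frame["drinks_now"].astype("Int64")
    if not frame["drinks_now"].dropna().isin([0, 1]).all():
        bad = frame["drinks_now"].notna() & ~frame["drinks_now"].isin([0, 1])
        _fail("drinks_now", int(frame[bad].index[0]))
    frame["drink_days"] = frame["drink_days"].astype("Int64")
    dd = frame["drink_days"].dropna()
    if ((dd < 0) | (dd > 7)).any():
        bad = frame["drink_days"].notna() & ((frame["drink_days"] < 0) | (frame["drink_days"] > 7))
        _fail("drink_days", int(frame[bad].index[0]))
    for col in ("max_day_units", "weekly_units"):
        if (frame[col].dropna() < 0).any():
            bad = frame[col].notna() & (frame[col] < 0)
            _fail(col, int(frame[bad].index[0]))

    frame["person_id"] = frame["person_id"].astype(int)
    frame["survey_year"] = frame["survey_year"].astype(int)
    return SurveyDataset(frame=frame, truth=None)
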