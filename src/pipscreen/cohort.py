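"""Cohort construction: eligibility, observation windows and event phasing.

Eligibility is age 45-64 in completed years at study start. Dispensing is
observed from study start until study end or the patient's 65th birthday
month, whichever comes first; a three-month lead-in before study start is
retained (tagged separately) to establish prior medication history.
"""

from __future__ import annotations

import pandas as pd
from dateutil.relativedelta import relativedelta

__all__ = ["build_cohort", "filter_events", "AGE_GROUPS", "age_group_label"]

AGE_GROUPS = ("45-49", "50-54", "55-59", "60-64")

DEFAULT_STUDY_START = pd.Timestamp("2012-01-01")
DEFAULT_STUDY_END = pd.Timestamp("2012-12-31")
LEADIN_MONTHS = 3


def age_group_label(age: int) -> str:
    if 45 <= age <= 49:
        return "45-49"
    if 50 <= age <= 54:
        return "50-54"
    if 55 <= age <= 59:
        return "55-59"
    if 60 <= age <= 64:
        return "60-64"
    raise ValueError(f"age outside cohort range: {age}")


def _completed_years(dob: pd.Timestamp, at: pd.Timestamp) -> int:
    return relativedelta(at.to_pydatetime(), dob.to_pydatetime()).years


def build_cohort(
    patients: pd.DataFrame,
    study_start: pd.Timestamp = DEFAULT_STUDY_START,
    study_end: pd.Timestamp = DEFAULT_STUDY_END,
    include_birthday_month: bool = False,
) -> pd.DataFrame:
    """Build per-patient observation windows for the eligible cohort.

    Parameters
    ----------
    patients
        Registry with columns ``patient_id``, ``date_of_birth``, ``gender``.
    include_birthday_month
        If False (default) the window ends on the last day of the month
        *before* the month containing the 65th birthday; if True it ends on
        the last day of the birthday month (capped at ``study_end``).

    Returns
    -------
    DataFrame with columns patient_id, gender, age, age_group, window_start,
    window_end, leadin_start — one row per eligible patient with a non-empty
    window. Patients aged <45 or >=65 at study start are excluded.
    """
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    if study_end < study_start:
        raise ValueError("study_end before study_start")
    if patients["date_of_birth"].isna().any():
        bad = patients.loc[patients["date_of_birth"].isna(), "patient_id"].tolist()
        raise ValueError(f"missing date of birth for patients: {bad[:5]}")

    leadin_start = study_start - relativedelta(months=LEADIN_MONTHS)
    rows = []
    for rec in patients.itertuples(index=False):
        dob = pd.Timestamp(rec.date_of_birth)
        age = _completed_years(dob, study_start)
        if age < 45 or age >= 65:
            continue
        birthday65 = dob + relativedelta(years=65)
        if birthday65 > study_end:
            window_end = study_end
        else:
            month_start = birthday65.replace(day=1)
            if include_birthday_month:
                window_end = min(
                    month_start + relativedelta(months=1, days=-1), study_end
                )
            else:
                window_end = month_start - relativedelta(days=1)
        if window_end < study_start:
            continue  # censored before the study window opens
        rows.append(
            {
                "patient_id": rec.patient_id,
                "gender": rec.gender,
                "age": age,
                "age_group": age_group_label(age),
                "window_start": study_start,
                "window_end": window_end,
                "leadin_start": leadin_start,
            }
        )
    cols = [
        "patient_id",
        "gender",
        "age",
        "age_group",
        "window_start",
        "window_end",
        "leadin_start",
    ]
    return pd.DataFrame(rows, columns=cols)


def filter_events(events: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Restrict events to each patient's [leadin_start, window_end] and tag phase.

    Events dated before the lead-in or after the (possibly censored) window
    end are dropped, as are events for patients outside the cohort. Retained
    events gain a ``phase`` column: ``"leadin"`` for dates before
    ``window_start``, ``"observation"`` otherwise.
    """
    if events.empty:
        out = events.copy()
        out["phase"] = pd.Series(dtype=object)
        return out
    merged = events.merge(
        windows[["patient_id", "window_start", "window_end", "leadin_start"]],
        on="patient_id",
        how="inner",
    )
    date = pd.to_datetime(merged["dispense_date"])
    keep = (date >= merged["leadin_start"]) & (date <= merged["window_end"])
    merged = merged.loc[keep].copy()
    merged["phase"] = (
        (pd.to_datetime(merged["dispense_date"]) < merged["window_start"])
        .map({True: "leadin", False: "observation"})
    )
    return merged.drop(columns=["window_start", "window_end", "leadin_start"]).reset_index(
        drop=True
    )
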