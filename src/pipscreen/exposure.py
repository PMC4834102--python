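"""Exposure reconstruction from dispensing events.

Two substrates feed every criterion rule:

* continuous-use *episodes* per patient x drug class — maximal runs of
  dispensings whose consecutive dates differ by at most a gap tolerance,
  each covering ``default_coverage_days`` beyond its last dispensing; and
* per-calendar-month *occupancy* — which distinct chemical codes of each
  class a patient received in each month.

Defaults (gap tolerance 63 days, coverage 28 days) reflect monthly-cycle
claims without days-supply fields; both are configurable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .vocabulary import CodingSystem, Vocabulary

__all__ = [
    "classify_events",
    "build_episodes",
    "mean_daily_dose",
    "month_occupancy",
]


def classify_events(
    events: pd.DataFrame, vocab: Vocabulary, system: CodingSystem
) -> pd.DataFrame:
    """Attach class membership, exploding events that belong to several classes.

    Events whose code resolves to no class are dropped (they still count for
    polypharmacy, which keys on the raw code, not on vocabulary classes).
    """
    if events.empty:
        out = events.copy()
        out["class_id"] = pd.Series(dtype=object)
        return out
    codes = events["drug_code"].unique()
    mapping = {c: sorted(vocab.resolve_class(c, system)) for c in codes}
    out = events.copy()
    out["class_id"] = out["drug_code"].map(mapping)
    out = out.explode("class_id")
    return out.dropna(subset=["class_id"]).reset_index(drop=True)


def build_episodes(
    events: pd.DataFrame,
    gap_tolerance_days: int = 63,
    default_coverage_days: int = 28,
) -> pd.DataFrame:
    """Chain classified events into continuous-use exposure episodes.

    Parameters
    ----------
    events
        Classified events (``classify_events`` output) with columns
        patient_id, class_id, dispense_date, drug_code and optionally
        quantity / strength_mg.
    gap_tolerance_days
        Two consecutive dispensings of the same class belong to one episode
        iff their dates differ by at most this many days.
    default_coverage_days
        Days of drug supply attributed to a dispensing; the episode ends
        ``default_coverage_days - 1`` days after its last dispensing.

    Returns
    -------
    DataFrame with one row per episode: patient_id, class_id, start_date,
    end_date, n_dispensings, duration_days, codes (tuple of distinct drug
    codes involved), total_mg, mean_daily_dose_mg (NaN when any event lacks
    quantity or strength).
    """
    if gap_tolerance_days < 0:
        raise ValueError("gap_tolerance_days must be >= 0")
    cols = [
        "patient_id",
        "class_id",
        "start_date",
        "end_date",
        "n_dispensings",
        "duration_days",
        "codes",
        "total_mg",
        "mean_daily_dose_mg",
    ]
    if events.empty:
        return pd.DataFrame(columns=cols)

    ev = events.copy()
    ev["dispense_date"] = pd.to_datetime(ev["dispense_date"])
    if "quantity" not in ev.columns:
        ev["quantity"] = np.nan
    if "strength_mg" not in ev.columns:
        ev["strength_mg"] = np.nan
    ev = ev.sort_values(["patient_id", "class_id", "dispense_date"], kind="mergesort")

    grp = ev.groupby(["patient_id", "class_id"], sort=False)
    gap = grp["dispense_date"].diff().dt.days
    new_episode = gap.isna() | (gap > gap_tolerance_days)
    ev["episode_idx"] = new_episode.cumsum()

    ev["event_mg"] = ev["quantity"] * ev["strength_mg"]
    agg = ev.groupby(["patient_id", "class_id", "episode_idx"], sort=False).agg(
        start_date=("dispense_date", "min"),
        last_date=("dispense_date", "max"),
        n_dispensings=("dispense_date", "size"),
        codes=("drug_code", lambda s: tuple(sorted(set(s)))),
        total_mg=("event_mg", "sum"),
        any_missing=("event_mg", lambda s: s.isna().any()),
    )
    agg = agg.reset_index().drop(columns="episode_idx")
    agg["end_date"] = agg["last_date"] + pd.to_timedelta(default_coverage_days - 1, "D")
    agg["duration_days"] = (agg["end_date"] - agg["start_date"]).dt.days + 1
    agg["mean_daily_dose_mg"] = np.where(
        agg["any_missing"], np.nan, agg["total_mg"] / agg["duration_days"]
    )
    agg.loc[agg["any_missing"], "total_mg"] = np.nan
    return agg[cols].reset_index(drop=True)


def mean_daily_dose(
    total_mg: float, duration_days: int
) -> Optional[float]:
    """Average daily dose over an episode: total dispensed mg / duration."""
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    if total_mg is None or np.isnan(total_mg):
        return None
    return total_mg / duration_days


def month_occupancy(
    events: pd.DataFrame, vocab: Vocabulary, system: CodingSystem
) -> pd.DataFrame:
    """Distinct chemical codes per patient x calendar month x class.

    ``events`` may be raw (classified on the fly) or already classified.
    Chemical granularity is the full dispensed code.
    """
    if "class_id" not in events.columns:
        events = classify_events(events, vocab, system)
    cols = ["patient_id", "month", "class_id", "distinct_chemicals", "n_events"]
    if events.empty:
        return pd.DataFrame(columns=cols)
    ev = events.copy()
    ev["month"] = pd.to_datetime(ev["dispense_date"]).dt.to_period("M")
    occ = (
        ev.groupby(["patient_id", "month", "class_id"], sort=False)
        .agg(
            distinct_chemicals=("drug_code", lambda s: frozenset(s)),
            n_events=("drug_code", "size"),
        )
        .reset_index()
    )
    return occ[cols]
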