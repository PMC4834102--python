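"""Polypharmacy covariate.

A patient's medication-class count is the number of distinct polypharmacy
class keys (five-character ATC / BNF section) dispensed at least three times
during the observation window; polypharmacy is four or more such classes.
Lead-in dispensings are excluded.
"""

from __future__ import annotations

import pandas as pd

from .vocabulary import CodingSystem, classify_for_polypharmacy

__all__ = ["compute_polypharmacy"]


def compute_polypharmacy(
    events: pd.DataFrame,
    system: CodingSystem,
    min_dispensings: int = 3,
    min_classes: int = 4,
) -> pd.DataFrame:
    """Per-patient polypharmacy record from observation-phase events.

    Parameters
    ----------
    events
        Observation-phase dispensing events (a ``phase`` column, if present,
        is used to drop lead-in rows defensively).
    system
        Coding system in force; determines the class key granularity.

    Returns
    -------
    DataFrame with columns patient_id, n_classes_ge3, polypharmacy. Patients
    absent from ``events`` are absent from the result (join with fillna(0)
    downstream).
    """
    if "phase" in events.columns:
        events = events[events["phase"] == "observation"]
    if events.empty:
        return pd.DataFrame(
            columns=["patient_id", "n_classes_ge3", "polypharmacy"]
        ).astype({"n_classes_ge3": int, "polypharmacy": bool})
    ev = events.copy()
    ev["pp_class"] = ev["drug_code"].map(lambda c: classify_for_polypharmacy(c, system))
    counts = ev.groupby(["patient_id", "pp_class"], sort=False).size()
    qualifying = counts[counts >= min_dispensings]
    n_classes = qualifying.groupby(level="patient_id").size()
    out = n_classes.reindex(ev["patient_id"].unique(), fill_value=0).rename(
        "n_classes_ge3"
    )
    out = out.reset_index().rename(columns={"index": "patient_id"})
    out["polypharmacy"] = out["n_classes_ge3"] >= min_classes
    return out
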