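from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pipscreen.vocabulary import CodingSystem, Vocabulary, load_vocabulary


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return load_vocabulary()


@pytest.fixture(scope="session")
def atc() -> CodingSystem:
    return CodingSystem.ATC


def make_events(rows, patient_id="P0", phase="observation"):
    """Build a phase-tagged event frame from (date, code[, quantity, strength]) tuples."""
    recs = []
    for row in rows:
        date, code = row[0], row[1]
        quantity = row[2] if len(row) > 2 else 28.0
        strength = row[3] if len(row) > 3 else 10.0
        ph = row[4] if len(row) > 4 else phase
        recs.append(
            {
                "patient_id": patient_id,
                "dispense_date": pd.Timestamp(date),
                "drug_code": code,
                "quantity": quantity,
                "strength_mg": strength,
                "phase": ph,
            }
        )
    return pd.DataFrame(
        recs,
        columns=["patient_id", "dispense_date", "drug_code", "quantity", "strength_mg", "phase"],
    )


def random_micro_cohort(rng: np.random.Generator, vocab: Vocabulary, system: CodingSystem):
    """Random registry + raw events for engine-vs-oracle comparison."""
    n_patients = int(rng.integers(1, 11))
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_patients)],
            "date_of_birth": [
                pd.Timestamp("2012-01-01")
                - pd.DateOffset(years=int(rng.integers(45, 65)))
                - pd.Timedelta(days=int(rng.integers(0, 365)))
                for _ in range(n_patients)
            ],
            "gender": rng.choice(["male", "female"], size=n_patients),
        }
    )
    codes = [
        c
        for cls in vocab.classes.values()
        for c in cls.example_codes.get(system, ())
    ] + (["ZZZZZ99"] if system is CodingSystem.ATC else ["99.9.9.nothing"])
    n_events = int(rng.integers(0, 51))
    start = pd.Timestamp("2011-10-01")
    events = pd.DataFrame(
        {
            "patient_id": rng.choice(patients["patient_id"], size=n_events),
            "dispense_date": [
                start + pd.Timedelta(days=int(d))
                for d in rng.integers(0, 458, size=n_events)
            ],
            "drug_code": rng.choice(codes, size=n_events),
            "quantity": rng.choice([7.0, 28.0, 56.0, 112.0], size=n_events),
            "strength_mg": rng.choice([5.0, 10.0, 20.0, 40.0], size=n_events),
        }
    )
    return patients, events
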