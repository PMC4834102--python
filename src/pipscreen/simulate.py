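"""Synthetic dispensing-data generator.

Produces a patient registry and a dispensing-event stream with the
structure the screening pipeline assumes: adults aged 45-64 at study start,
a 12-month study window plus a 3-month lead-in, monthly-cadence dispensing
of the drug classes the rule set reads, and *plantable* criterion-positive
and criterion-negative patterns at configurable rates, returned alongside a
ground-truth label table.

Guarantees (with zero background dispensing):

* every planted positive triggers its criterion under the engine's
  documented operationalization, and every planted hard negative — built
  exactly at the rule boundary (28 / 56 / 7 / 90 days, same-month
  co-prescription, single-chemical months) — does not;
* plants for different criteria never interfere: each rule is assigned a
  time slot such that rules sharing drug classes are separated by more than
  the episode gap tolerance and never share a calendar month.

Patterns that do not fit a (censored) patient's window are skipped and the
truth label stays 0. All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .cohort import build_cohort
from .vocabulary import CodingSystem, CriterionRule, RuleCategory, Vocabulary

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "generate_population",
    "plant_criterion_positive",
    "plant_criterion_negative",
    "generate_dataset",
    "write_registry",
    "write_events",
    "write_truth",
]

# Age-group weights loosely following a middle-aged population pyramid.
_DEFAULT_GROUP_WEIGHTS = {"45-49": 0.285, "50-54": 0.259, "55-59": 0.221, "60-64": 0.235}


def _default_age_weights() -> dict[int, float]:
    w: dict[int, float] = {}
    for group, gw in _DEFAULT_GROUP_WEIGHTS.items():
        lo, hi = (int(x) for x in group.split("-"))
        for age in range(lo, hi + 1):
            w[age] = gw / (hi - lo + 1)
    return w


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    n_patients: int
    seed: int = 0
    study_start: pd.Timestamp = pd.Timestamp("2012-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2012-12-31")
    female_fraction: float = 0.494
    age_distribution: Optional[Mapping[int, float]] = None
    coding_system: CodingSystem = CodingSystem.ATC
    background_class_rates: Mapping[str, float] = field(default_factory=dict)
    planted_rates: Mapping[str, float] = field(default_factory=dict)
    negative_rates: Mapping[str, float] = field(default_factory=dict)
    polypharmacy_target: float = 0.0
    pack_quantity: int = 28

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        self.study_start = pd.Timestamp(self.study_start)
        self.study_end = pd.Timestamp(self.study_end)
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for name, val in [
            ("female_fraction", self.female_fraction),
            ("polypharmacy_target", self.polypharmacy_target),
        ]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for label, rates in [
            ("background_class_rates", self.background_class_rates),
            ("planted_rates", self.planted_rates),
            ("negative_rates", self.negative_rates),
        ]:
            for k, v in rates.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{label}[{k!r}] must be in [0, 1]")
        if self.coding_system is not None:
            self.coding_system = CodingSystem(self.coding_system)


@dataclass
class SimulationResult:
    """Generated registry, events and ground-truth plant labels."""

    patients: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame            # patient_id x criterion_id -> 0/1 planted positive
    planted_negative: pd.DataFrame  # patient_id x criterion_id -> 0/1 hard negative


def generate_population(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Generate the patient registry (id, date of birth, gender).

    Deterministic given the config seed; ages in completed years at study
    start follow ``age_distribution`` (weights over 45..64) and gender
    follows ``female_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = dict(config.age_distribution or _default_age_weights())
    ages = np.array(sorted(weights))
    if ages.min() < 45 or ages.max() > 64:
        raise ValueError("age_distribution must be supported on 45..64")
    p = np.array([weights[a] for a in ages], dtype=float)
    p = p / p.sum()
    drawn_ages = rng.choice(ages, size=config.n_patients, p=p)
    day_offsets = rng.integers(0, 365, size=config.n_patients)
    female = rng.random(config.n_patients) < config.female_fraction
    width = len(str(config.n_patients))
    rows = []
    for i in range(config.n_patients):
        dob = (
            config.study_start
            - relativedelta(years=int(drawn_ages[i]))
            - relativedelta(days=int(day_offsets[i]))
        )
        rows.append(
            {
                "patient_id": f"P{i:0{width}d}",
                "date_of_birth": dob,
                "gender": "female" if female[i] else "male",
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "date_of_birth", "gender"])


# ---------------------------------------------------------------------------
# Plant patterns


def _class_code(vocab: Vocabulary, class_id: str, system: CodingSystem, idx: int = 0) -> str:
    codes = vocab.classes[class_id].example_codes.get(system, ())
    if len(codes) <= idx:
        raise ValueError(
            f"class {class_id!r} needs >= {idx + 1} example codes for {system.value}"
        )
    return codes[idx]


def _class_strength(vocab: Vocabulary, class_id: str) -> float:
    return float(vocab.classes[class_id].default_strength_mg or 1.0)


def _duration_offsets(span_days: int, gap_tolerance: int) -> list[int]:
    """Dispensing offsets 0..span_days with consecutive gaps <= tolerance."""
    offsets = [0]
    pos = 0
    while pos < span_days:
        pos = min(pos + gap_tolerance, span_days)
        offsets.append(pos)
    return offsets


def _pattern(
    rule: CriterionRule,
    vocab: Vocabulary,
    system: CodingSystem,
    positive: bool,
    coverage: int,
    gap_tolerance: int,
    pack_quantity: int,
) -> Optional[tuple[list[tuple[int, str, float, float]], list[tuple[int, str, float, float]]]]:
    """Event pattern guaranteeing a criterion fires (or sits on its boundary).

    Returns (observation_events, leadin_events) as lists of
    (day_offset, code, quantity, strength_mg); observation offsets are
    relative to the rule's slot day, lead-in offsets to the lead-in start.
    None when no pattern of the requested polarity is constructible.
    """
    cls = rule.target_class
    code = _class_code(vocab, cls, system, 0)
    strength = _class_strength(vocab, cls)
    q = float(pack_quantity)

    if rule.category in (RuleCategory.DURATION, RuleCategory.DOSE_DURATION):
        T = int(rule.max_duration_days)
        # last-dispensing offset so that episode duration is T+1 (positive)
        # or exactly T (boundary negative)
        last = T - coverage + (1 if positive else 0)
        if last < 0:
            if positive:
                offsets = [0]  # single pack already exceeds the threshold
            else:
                return None  # any dispensing at all would trigger
        else:
            offsets = _duration_offsets(last, gap_tolerance)
        if rule.category is RuleCategory.DOSE_DURATION:
            threshold = vocab.dose_table.lookup(code, system)
            if threshold is None:
                raise ValueError(f"no dose threshold for {code!r}")
            duration = offsets[-1] + coverage
            # quantity per dispensing giving ~2x the maintenance daily dose
            q = float(int(np.ceil(2 * threshold * duration / (len(offsets) * strength))))
        return [(o, code, q, strength) for o in offsets], []

    if rule.category is RuleCategory.CO_PRESCRIPTION:
        obs = [(0, code, q, strength)]
        if not positive:
            req = _class_code(vocab, rule.required_classes[0], system, 0)
            obs.append((0, req, q, _class_strength(vocab, rule.required_classes[0])))
        return obs, []

    if rule.category is RuleCategory.FIRST_LINE:
        obs = [(0, code, q, strength)]
        if positive:
            return obs, []
        alt = rule.preferred_alternative_classes[0]
        alt_code = _class_code(vocab, alt, system, 0)
        return obs, [(7, alt_code, q, _class_strength(vocab, alt))]

    if rule.category is RuleCategory.DUPLICATION:
        if positive:
            code2 = _class_code(vocab, cls, system, 1)
            obs = [(0, code, q, strength), (0, code2, q, strength)]
        else:
            obs = [(0, code, q, strength), (0, code, q, strength)]
        # keep any same-month co-prescription rule on this class satisfied
        for other in vocab.rules:
            if (
                other.category is RuleCategory.CO_PRESCRIPTION
                and other.target_class == cls
            ):
                req = other.required_classes[0]
                obs.append((0, _class_code(vocab, req, system, 0), q, _class_strength(vocab, req)))
        return obs, []

    raise ValueError(f"unknown rule category: {rule.category}")


def _pattern_classes(rule: CriterionRule, vocab: Vocabulary) -> set[str]:
    """Drug classes a rule's plants emit or whose events can affect the rule."""
    out = {rule.target_class}
    out.update(rule.required_classes)
    out.update(rule.preferred_alternative_classes)
    if rule.category is RuleCategory.DUPLICATION:
        for other in vocab.rules:
            if (
                other.category is RuleCategory.CO_PRESCRIPTION
                and other.target_class == rule.target_class
            ):
                out.add(other.required_classes[0])
    return out


def rule_slots(
    vocab: Vocabulary,
    system: CodingSystem,
    coverage: int,
    gap_tolerance: int,
    pack_quantity: int,
) -> dict[str, int]:
    """Assign each rule a slot day so plants for different rules cannot interact.

    Rules touching a common drug class are serialized with more than the
    episode gap tolerance between their patterns; unrelated rules share day 0.
    """
    next_free: dict[str, int] = {}
    slots: dict[str, int] = {}
    for rule in vocab.rules:
        span = 0
        for positive in (True, False):
            pat = _pattern(
                rule, vocab, system, positive, coverage, gap_tolerance, pack_quantity
            )
            if pat is not None:
                span = max(span, max((o for o, *_ in pat[0]), default=0) + coverage)
        involved = _pattern_classes(rule, vocab)
        slot = max((next_free.get(c, 0) for c in involved), default=0)
        slots[rule.criterion_id] = slot
        for c in involved:
            next_free[c] = slot + span + gap_tolerance + 1
    return slots


def _plant(
    window: Mapping,
    criterion_id: str,
    vocab: Vocabulary,
    system: CodingSystem,
    positive: bool,
    slot_day: int = 0,
    coverage: int = 28,
    gap_tolerance: int = 63,
    pack_quantity: int = 28,
) -> list[dict]:
    rule = vocab.rule(criterion_id)  # raises KeyError on unknown criterion
    pat = _pattern(rule, vocab, system, positive, coverage, gap_tolerance, pack_quantity)
    if pat is None:
        return []
    obs_pat, leadin_pat = pat
    window_start = pd.Timestamp(window["window_start"])
    window_end = pd.Timestamp(window["window_end"])
    leadin_start = pd.Timestamp(window["leadin_start"])
    last_off = max(o for o, *_ in obs_pat)
    if window_start + pd.Timedelta(days=slot_day + last_off) > window_end:
        return []  # pattern does not fit the (censored) window
    events = [
        {
            "patient_id": window["patient_id"],
            "dispense_date": window_start + pd.Timedelta(days=slot_day + off),
            "drug_code": code,
            "quantity": qty,
            "strength_mg": strength,
        }
        for off, code, qty, strength in obs_pat
    ]
    for off, code, qty, strength in leadin_pat:
        date = leadin_start + pd.Timedelta(days=off)
        if date >= window_start:
            return []
        events.append(
            {
                "patient_id": window["patient_id"],
                "dispense_date": date,
                "drug_code": code,
                "quantity": qty,
                "strength_mg": strength,
            }
        )
    return events


def plant_criterion_positive(
    window: Mapping,
    criterion_id: str,
    rng: Optional[np.random.Generator],
    vocab: Vocabulary,
    system: CodingSystem = CodingSystem.ATC,
    slot_day: int = 0,
    coverage: int = 28,
    gap_tolerance: int = 63,
    pack_quantity: int = 28,
) -> list[dict]:
    """Events guaranteed to trigger ``criterion_id`` for this patient window.

    Returns an empty list when the pattern does not fit the window (the
    caller must then record the patient as unplanted).
    """
    return _plant(
        window, criterion_id, vocab, system, True, slot_day, coverage, gap_tolerance,
        pack_quantity,
    )


def plant_criterion_negative(
    window: Mapping,
    criterion_id: str,
    rng: Optional[np.random.Generator],
    vocab: Vocabulary,
    system: CodingSystem = CodingSystem.ATC,
    slot_day: int = 0,
    coverage: int = 28,
    gap_tolerance: int = 63,
    pack_quantity: int = 28,
) -> list[dict]:
    """Boundary events exercising the criterion's classes without triggering it."""
    return _plant(
        window, criterion_id, vocab, system, False, slot_day, coverage, gap_tolerance,
        pack_quantity,
    )


_POLY_OFFSETS = (5, 65, 125)


def generate_dataset(
    config: SimulationConfig, vocab: Vocabulary
) -> SimulationResult:
    """Generate registry, events and ground-truth plant labels.

    Planting is independent per criterion per patient; a patient drawn for
    both polarities of one criterion receives the positive plant only.
    Background dispensing is an independent per-patient per-class per-month
    Bernoulli process (lead-in included) and can create genuine additional
    criterion triggers; label fidelity is exact only at zero background.
    """
    rng = np.random.default_rng(config.seed)
    patients = generate_population(config, rng)
    windows = build_cohort(patients, config.study_start, config.study_end)
    win_by_pid = {w["patient_id"]: w for w in windows.to_dict("records")}

    system = config.coding_system
    coverage = int(vocab.settings["default_coverage_days"])
    gap_tolerance = int(vocab.settings["gap_tolerance_days"])
    slots = rule_slots(vocab, system, coverage, gap_tolerance, config.pack_quantity)
    for cid in list(config.planted_rates) + list(config.negative_rates):
        vocab.rule(cid)  # raises KeyError for unknown criteria

    fillers = vocab.filler_classes()
    min_classes = int(vocab.settings["polypharmacy_min_classes"])
    min_disp = int(vocab.settings["polypharmacy_min_dispensings"])
    if config.polypharmacy_target > 0 and len(fillers) < min_classes:
        raise ValueError(
            f"polypharmacy planting needs >= {min_classes} filler classes"
        )

    all_events: list[dict] = []
    truth_rows: list[dict] = []
    neg_rows: list[dict] = []
    for pid in patients["patient_id"]:
        window = win_by_pid.get(pid)
        truth = {"patient_id": pid, **{r: 0 for r in vocab.rule_ids}}
        neg = {"patient_id": pid, **{r: 0 for r in vocab.rule_ids}}
        if window is not None:
            for rule in vocab.rules:
                rid = rule.criterion_id
                u = rng.random()
                p_pos = config.planted_rates.get(rid, 0.0)
                p_neg = config.negative_rates.get(rid, 0.0)
                if u < p_pos:
                    ev = plant_criterion_positive(
                        window, rid, rng, vocab, system, slots[rid], coverage,
                        gap_tolerance, config.pack_quantity,
                    )
                    if ev:
                        all_events.extend(ev)
                        truth[rid] = 1
                elif u < p_pos + p_neg:
                    ev = plant_criterion_negative(
                        window, rid, rng, vocab, system, slots[rid], coverage,
                        gap_tolerance, config.pack_quantity,
                    )
                    if ev:
                        all_events.extend(ev)
                        neg[rid] = 1
            if rng.random() < config.polypharmacy_target:
                all_events.extend(
                    _plant_polypharmacy(window, vocab, system, min_classes, min_disp)
                )
            all_events.extend(
                _background_events(window, config, vocab, system, rng)
            )
        truth_rows.append(truth)
        neg_rows.append(neg)

    events = pd.DataFrame(
        all_events,
        columns=["patient_id", "dispense_date", "drug_code", "quantity", "strength_mg"],
    )
    events = events.sort_values(
        ["patient_id", "dispense_date", "drug_code"], kind="mergesort"
    ).reset_index(drop=True)
    return SimulationResult(
        patients=patients,
        events=events,
        truth=pd.DataFrame(truth_rows),
        planted_negative=pd.DataFrame(neg_rows),
    )


def _plant_polypharmacy(
    window: Mapping,
    vocab: Vocabulary,
    system: CodingSystem,
    min_classes: int,
    min_dispensings: int,
) -> list[dict]:
    """Dispense ``min_classes`` filler classes ``min_dispensings`` times each."""
    window_start = pd.Timestamp(window["window_start"])
    window_end = pd.Timestamp(window["window_end"])
    offsets = _POLY_OFFSETS[:min_dispensings]
    if min_dispensings > len(_POLY_OFFSETS):
        offsets = tuple(range(5, 5 + 60 * min_dispensings, 60))
    if window_start + pd.Timedelta(days=max(offsets)) > window_end:
        return []
    events = []
    for cid in vocab.filler_classes()[:min_classes]:
        code = _class_code(vocab, cid, system, 0)
        strength = _class_strength(vocab, cid)
        for off in offsets:
            events.append(
                {
                    "patient_id": window["patient_id"],
                    "dispense_date": window_start + pd.Timedelta(days=off),
                    "drug_code": code,
                    "quantity": 28.0,
                    "strength_mg": strength,
                }
            )
    return events


def _background_events(
    window: Mapping,
    config: SimulationConfig,
    vocab: Vocabulary,
    system: CodingSystem,
    rng: np.random.Generator,
) -> list[dict]:
    if not config.background_class_rates:
        return []
    leadin_start = pd.Timestamp(window["leadin_start"])
    window_end = pd.Timestamp(window["window_end"])
    months = pd.period_range(leadin_start, window_end, freq="M")
    events = []
    for cid, rate in config.background_class_rates.items():
        if rate <= 0:
            continue
        codes = vocab.classes[cid].example_codes.get(system, ())
        if not codes:
            raise ValueError(f"class {cid!r} has no example codes for {system.value}")
        strength = _class_strength(vocab, cid)
        hits = rng.random(len(months)) < rate
        days = rng.integers(0, 28, size=len(months))
        code_idx = rng.integers(0, len(codes), size=len(months))
        for m, hit, day, ci in zip(months, hits, days, code_idx):
            if not hit:
                continue
            date = m.start_time + pd.Timedelta(days=int(day))
            if date < leadin_start or date > window_end:
                continue
            events.append(
                {
                    "patient_id": window["patient_id"],
                    "dispense_date": date,
                    "drug_code": codes[int(ci)],
                    "quantity": float(config.pack_quantity),
                    "strength_mg": strength,
                }
            )
    return events


# ---------------------------------------------------------------------------
# Writers (plain CSV, ISO-8601 dates)


def write_registry(patients: pd.DataFrame, path) -> None:
    out = patients.copy()
    out["date_of_birth"] = pd.to_datetime(out["date_of_birth"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
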