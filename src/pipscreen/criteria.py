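"""Criterion rule engine.

Evaluates declarative rules of five structural categories against exposure
episodes and month occupancy, producing per-patient criterion flags, the
any-PIP primary outcome and PIP-count categories.

Conventions (all configurable thresholds use strict inequalities):

* duration thresholds are exceeded only by *strictly* longer episodes
  (">4 weeks" means 29+ days with a 28-day threshold);
* co-prescription and duplication use calendar months;
* the first-line new-user condition looks back over the lead-in plus any
  earlier in-window dispensing of the target or preferred-alternative
  classes.

Duration-type, co-prescription and duplication rules read observation-phase
exposure only; first-line rules additionally read lead-in history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exposure import build_episodes, classify_events, month_occupancy
from .vocabulary import (
    CodingSystem,
    CriterionRule,
    DoseThresholdTable,
    RuleCategory,
    Vocabulary,
)

__all__ = [
    "EngineOptions",
    "eval_duration_rule",
    "eval_dose_duration_rule",
    "eval_coprescription_rule",
    "eval_first_line_rule",
    "eval_duplication_rule",
    "evaluate_patient",
    "evaluate_cohort",
    "pip_category",
]

log = logging.getLogger(__name__)

PIP_CATEGORIES = ("0", "1", "2", "3+")


@dataclass(frozen=True)
class EngineOptions:
    """Engine toggles; defaults mirror the shipped operationalization."""

    gap_tolerance_days: int = 63
    default_coverage_days: int = 28
    duplication_in_any_pip: bool = False
    require_any_dispensing: bool = True


def pip_category(n_pip: int) -> str:
    if n_pip < 0:
        raise ValueError("n_pip must be non-negative")
    return str(n_pip) if n_pip < 3 else "3+"


def _episode_threshold(codes, dose_table: DoseThresholdTable, system: CodingSystem):
    """Maintenance threshold for a (possibly multi-code) episode.

    Conservative choice: the maximum maintenance dose over the involved
    codes; None when any code is missing from the table (episode skipped).
    """
    thresholds = [dose_table.lookup(c, system) for c in codes]
    if any(t is None for t in thresholds):
        return None
    return max(thresholds)


def eval_duration_rule(rule: CriterionRule, episodes: pd.DataFrame) -> bool:
    """True iff any target-class episode is strictly longer than the threshold."""
    assert rule.category is RuleCategory.DURATION
    eps = episodes[episodes["class_id"] == rule.target_class]
    return bool((eps["duration_days"] > rule.max_duration_days).any())


def eval_dose_duration_rule(
    rule: CriterionRule,
    episodes: pd.DataFrame,
    dose_table: DoseThresholdTable,
    system: CodingSystem,
) -> bool:
    """True iff a target-class episode exceeds both maintenance dose and duration.

    Episodes with unknown dose (missing quantity/strength) or with a code
    absent from the dose table never trigger; both cases are logged.
    """
    assert rule.category is RuleCategory.DOSE_DURATION
    eps = episodes[episodes["class_id"] == rule.target_class]
    for ep in eps.itertuples(index=False):
        if ep.duration_days <= rule.max_duration_days:
            continue
        if pd.isna(ep.mean_daily_dose_mg):
            log.debug("%s: episode with unknown dose skipped", rule.criterion_id)
            continue
        threshold = _episode_threshold(ep.codes, dose_table, system)
        if threshold is None:
            log.warning(
                "%s: code(s) %s missing from dose table; episode skipped",
                rule.criterion_id,
                ep.codes,
            )
            continue
        if ep.mean_daily_dose_mg > threshold:
            return True
    return False


def eval_coprescription_rule(rule: CriterionRule, occupancy: pd.DataFrame) -> bool:
    """True iff some month has target-class use and none of the required classes."""
    assert rule.category is RuleCategory.CO_PRESCRIPTION
    target_months = set(
        occupancy.loc[occupancy["class_id"] == rule.target_class, "month"]
    )
    covered = set(
        occupancy.loc[occupancy["class_id"].isin(rule.required_classes), "month"]
    )
    return bool(target_months - covered)


def eval_first_line_rule(
    rule: CriterionRule, episodes: pd.DataFrame, events: pd.DataFrame
) -> bool:
    """Evaluate a first-line rule against full-history episodes and events.

    Triggers iff some target-class episode (i) starts in the observation
    phase, (ii) is strictly longer than ``max_duration_days`` when that is
    set, and (iii) is preceded by no dispensing of the target class or of any
    preferred-alternative class (new-user condition over lead-in plus earlier
    observation).
    """
    assert rule.category is RuleCategory.FIRST_LINE
    eps = episodes[episodes["class_id"] == rule.target_class]
    if eps.empty:
        return False
    dates = pd.to_datetime(events["dispense_date"])
    is_target = events["class_id"] == rule.target_class
    is_pref = events["class_id"].isin(rule.preferred_alternative_classes)
    obs_target_dates = set(dates[is_target & (events["phase"] == "observation")])
    target_dates = dates[is_target]
    pref_dates = dates[is_pref]
    for ep in eps.itertuples(index=False):
        if ep.start_date not in obs_target_dates:
            continue
        if (
            rule.max_duration_days is not None
            and ep.duration_days <= rule.max_duration_days
        ):
            continue
        if (target_dates < ep.start_date).any():
            continue
        if (pref_dates < ep.start_date).any():
            continue
        return True
    return False


def eval_duplication_rule(rule: CriterionRule, occupancy: pd.DataFrame) -> bool:
    """True iff >=2 distinct chemicals of the target class in one calendar month."""
    assert rule.category is RuleCategory.DUPLICATION
    occ = occupancy[occupancy["class_id"] == rule.target_class]
    return bool(occ["distinct_chemicals"].map(len).ge(2).any())


def _eval_rule(
    rule: CriterionRule,
    obs_episodes: pd.DataFrame,
    obs_occupancy: pd.DataFrame,
    all_episodes: pd.DataFrame,
    all_events: pd.DataFrame,
    vocab: Vocabulary,
    system: CodingSystem,
) -> bool:
    if rule.category is RuleCategory.DURATION:
        return eval_duration_rule(rule, obs_episodes)
    if rule.category is RuleCategory.DOSE_DURATION:
        return eval_dose_duration_rule(rule, obs_episodes, vocab.dose_table, system)
    if rule.category is RuleCategory.CO_PRESCRIPTION:
        return eval_coprescription_rule(rule, obs_occupancy)
    if rule.category is RuleCategory.FIRST_LINE:
        return eval_first_line_rule(rule, all_episodes, all_events)
    if rule.category is RuleCategory.DUPLICATION:
        return eval_duplication_rule(rule, obs_occupancy)
    raise ValueError(f"unknown rule category: {rule.category}")


def _profile_from_flags(
    flags: dict[str, bool], vocab: Vocabulary, options: EngineOptions
) -> dict:
    dup_ids = {
        r.criterion_id for r in vocab.rules if r.category is RuleCategory.DUPLICATION
    }
    counted = [
        cid
        for cid, v in flags.items()
        if v and (options.duplication_in_any_pip or cid not in dup_ids)
    ]
    n_pip = len(counted)
    return {
        **flags,
        "any_duplication": any(flags[cid] for cid in dup_ids if cid in flags),
        "n_pip": n_pip,
        "any_pip": n_pip >= 1,
        "pip_category": pip_category(n_pip),
    }


def evaluate_patient(
    vocab: Vocabulary,
    events: pd.DataFrame,
    system: CodingSystem,
    options: EngineOptions = EngineOptions(),
) -> dict:
    """Evaluate every rule for one patient's phase-tagged events.

    ``events`` must already be restricted to the patient's window and carry a
    ``phase`` column (see :func:`pipscreen.cohort.filter_events`). Returns a
    profile dict: one boolean per criterion plus any_pip, n_pip,
    pip_category and any_duplication.
    """
    cls_all = classify_events(events, vocab, system)
    cls_obs = cls_all[cls_all["phase"] == "observation"] if not cls_all.empty else cls_all
    obs_eps = build_episodes(
        cls_obs, options.gap_tolerance_days, options.default_coverage_days
    )
    all_eps = build_episodes(
        cls_all, options.gap_tolerance_days, options.default_coverage_days
    )
    occ = month_occupancy(cls_obs, vocab, system)
    flags = {
        rule.criterion_id: _eval_rule(
            rule, obs_eps, occ, all_eps, cls_all, vocab, system
        )
        for rule in vocab.rules
    }
    return _profile_from_flags(flags, vocab, options)


def evaluate_cohort(
    vocab: Vocabulary,
    events: pd.DataFrame,
    windows: pd.DataFrame,
    system: CodingSystem,
    options: EngineOptions = EngineOptions(),
) -> pd.DataFrame:
    """Evaluate the rule set for every cohort member.

    Parameters
    ----------
    events
        Phase-tagged events for cohort patients (``filter_events`` output).
    windows
        Cohort observation windows; defines the candidate denominator.
    options
        With ``require_any_dispensing`` (default) only patients with at
        least one observation-phase dispensing enter the denominator.

    Returns
    -------
    One row per denominator patient: patient_id, a boolean column per
    criterion, any_duplication, n_pip, any_pip, pip_category.
    """
    if options.require_any_dispensing:
        if events.empty:
            member_ids: list = []
        else:
            obs = events[events["phase"] == "observation"]
            member_ids = sorted(set(obs["patient_id"]) & set(windows["patient_id"]))
    else:
        member_ids = sorted(windows["patient_id"])

    cls_all = classify_events(events, vocab, system)
    if not cls_all.empty:
        cls_all = cls_all[cls_all["patient_id"].isin(member_ids)]
    cls_obs = cls_all[cls_all["phase"] == "observation"] if not cls_all.empty else cls_all
    obs_eps = build_episodes(
        cls_obs, options.gap_tolerance_days, options.default_coverage_days
    )
    all_eps = build_episodes(
        cls_all, options.gap_tolerance_days, options.default_coverage_days
    )
    occ = month_occupancy(cls_obs, vocab, system)

    flagged: dict[str, set] = {}
    for rule in vocab.rules:
        flagged[rule.criterion_id] = _flag_patients(
            rule, obs_eps, occ, all_eps, cls_all, vocab, system
        )

    rows = []
    for pid in member_ids:
        flags = {rid: pid in flagged[rid] for rid in vocab.rule_ids}
        rows.append({"patient_id": pid, **_profile_from_flags(flags, vocab, options)})
    cols = (
        ["patient_id"]
        + list(vocab.rule_ids)
        + ["any_duplication", "n_pip", "any_pip", "pip_category"]
    )
    return pd.DataFrame(rows, columns=cols)


def _flag_patients(
    rule: CriterionRule,
    obs_eps: pd.DataFrame,
    occ: pd.DataFrame,
    all_eps: pd.DataFrame,
    all_events: pd.DataFrame,
    vocab: Vocabulary,
    system: CodingSystem,
) -> set:
    """Vectorized per-rule flagging: the set of patient_ids triggering ``rule``."""
    if rule.category is RuleCategory.DURATION:
        hit = obs_eps[
            (obs_eps["class_id"] == rule.target_class)
            & (obs_eps["duration_days"] > rule.max_duration_days)
        ]
        return set(hit["patient_id"])

    if rule.category is RuleCategory.DOSE_DURATION:
        eps = obs_eps[
            (obs_eps["class_id"] == rule.target_class)
            & (obs_eps["duration_days"] > rule.max_duration_days)
            & obs_eps["mean_daily_dose_mg"].notna()
        ]
        out = set()
        for ep in eps.itertuples(index=False):
            threshold = _episode_threshold(ep.codes, vocab.dose_table, system)
            if threshold is None:
                log.warning(
                    "%s: code(s) %s missing from dose table; episode skipped",
                    rule.criterion_id,
                    ep.codes,
                )
                continue
            if ep.mean_daily_dose_mg > threshold:
                out.add(ep.patient_id)
        return out

    if rule.category is RuleCategory.CO_PRESCRIPTION:
        tm = occ.loc[occ["class_id"] == rule.target_class, ["patient_id", "month"]]
        rm = occ.loc[
            occ["class_id"].isin(rule.required_classes), ["patient_id", "month"]
        ].drop_duplicates()
        if tm.empty:
            return set()
        merged = tm.merge(rm, on=["patient_id", "month"], how="left", indicator=True)
        return set(merged.loc[merged["_merge"] == "left_only", "patient_id"])

    if rule.category is RuleCategory.FIRST_LINE:
        relevant = {rule.target_class, *rule.preferred_alternative_classes}
        ev = all_events[all_events["class_id"].isin(relevant)]
        out = set()
        for pid, pev in ev.groupby("patient_id", sort=False):
            peps = all_eps[
                (all_eps["patient_id"] == pid)
                & (all_eps["class_id"] == rule.target_class)
            ]
            if eval_first_line_rule(rule, peps, pev):
                out.add(pid)
        return out

    if rule.category is RuleCategory.DUPLICATION:
        hit = occ[
            (occ["class_id"] == rule.target_class)
            & (occ["distinct_chemicals"].map(len) >= 2)
        ]
        return set(hit["patient_id"])

    raise ValueError(f"unknown rule category: {rule.category}")
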