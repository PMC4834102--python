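"""Independent brute-force reference implementations used as test oracles.

Deliberately written in plain Python over lists/dicts with a different
algorithmic shape from the package (fixpoint O(n^2) episode merging, direct
per-month scans) so agreement is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pipscreen.vocabulary import CodingSystem, RuleCategory, Vocabulary


def ref_match(code: str, prefix: str, system: CodingSystem) -> bool:
    if system is CodingSystem.ATC:
        return code[: len(prefix)] == prefix
    return (code + ".").startswith(prefix + ".")


def ref_classes_of(code: str, vocab: Vocabulary, system: CodingSystem) -> set[str]:
    out = set()
    for cls in vocab.classes.values():
        for p in cls.prefixes.get(system, ()):
            if ref_match(code, p, system):
                out.add(cls.class_id)
    return out


@dataclass
class RefEpisode:
    dates: list          # dispense dates (sorted)
    codes: list          # one code per date
    mgs: list            # quantity*strength per dispensing, None if unknown

    def start(self):
        return min(self.dates)

    def end(self, coverage):
        return max(self.dates) + pd.Timedelta(days=coverage - 1)

    def duration(self, coverage):
        return (self.end(coverage) - self.start()).days + 1

    def mean_dose(self, coverage):
        if any(m is None for m in self.mgs):
            return None
        return sum(self.mgs) / self.duration(coverage)


def ref_episodes(events: list[dict], gap: int, coverage: int) -> list[RefEpisode]:
    """Fixpoint merging: each event starts as its own episode; merge any pair
    of same-class episodes whose adjacent dispense dates are within the gap."""
    eps = [
        RefEpisode([e["dispense_date"]], [e["drug_code"]], [e.get("mg")])
        for e in events
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(eps)):
            for j in range(len(eps)):
                if i == j:
                    continue
                a, b = eps[i], eps[j]
                # within gap in either direction, or overlapping in time
                forward = (min(b.dates) - max(a.dates)).days
                backward = (min(a.dates) - max(b.dates)).days
                if forward <= gap and backward <= gap:
                    merged = RefEpisode(
                        a.dates + b.dates, a.codes + b.codes, a.mgs + b.mgs
                    )
                    eps = [e for k, e in enumerate(eps) if k not in (i, j)] + [merged]
                    changed = True
                    break
            if changed:
                break
    for e in eps:
        order = sorted(range(len(e.dates)), key=lambda k: e.dates[k])
        e.dates = [e.dates[k] for k in order]
        e.codes = [e.codes[k] for k in order]
        e.mgs = [e.mgs[k] for k in order]
    return eps


def _class_events(events, cls, vocab, system):
    return [e for e in events if cls in ref_classes_of(e["drug_code"], vocab, system)]


def _dose_threshold(codes, vocab, system):
    thresholds = []
    for c in set(codes):
        t = vocab.dose_table.lookup(c, system)
        if t is None:
            return None
        thresholds.append(t)
    return max(thresholds)


def ref_evaluate_patient(
    vocab: Vocabulary,
    events: list[dict],
    system: CodingSystem,
    gap: int = 63,
    coverage: int = 28,
) -> dict[str, bool]:
    """Per-criterion flags for one patient's phase-tagged event dicts.

    Each event dict: dispense_date (Timestamp), drug_code, phase, and
    optionally mg (= quantity * strength, None when unknown).
    """
    obs = [e for e in events if e["phase"] == "observation"]
    flags = {}
    for rule in vocab.rules:
        tcls = rule.target_class
        if rule.category is RuleCategory.DURATION:
            hits = False
            for ep in ref_episodes(_class_events(obs, tcls, vocab, system), gap, coverage):
                if ep.duration(coverage) > rule.max_duration_days:
                    hits = True
            flags[rule.criterion_id] = hits

        elif rule.category is RuleCategory.DOSE_DURATION:
            hits = False
            for ep in ref_episodes(_class_events(obs, tcls, vocab, system), gap, coverage):
                if ep.duration(coverage) <= rule.max_duration_days:
                    continue
                dose = ep.mean_dose(coverage)
                if dose is None:
                    continue
                threshold = _dose_threshold(ep.codes, vocab, system)
                if threshold is not None and dose > threshold:
                    hits = True
            flags[rule.criterion_id] = hits

        elif rule.category is RuleCategory.CO_PRESCRIPTION:
            target_months = {
                (e["dispense_date"].year, e["dispense_date"].month)
                for e in _class_events(obs, tcls, vocab, system)
            }
            covered = set()
            for rc in rule.required_classes:
                covered |= {
                    (e["dispense_date"].year, e["dispense_date"].month)
                    for e in _class_events(obs, rc, vocab, system)
                }
            flags[rule.criterion_id] = bool(target_months - covered)

        elif rule.category is RuleCategory.FIRST_LINE:
            tev = _class_events(events, tcls, vocab, system)
            prior_dates = [e["dispense_date"] for e in tev]
            pref_dates = []
            for pc in rule.preferred_alternative_classes:
                pref_dates += [
                    e["dispense_date"] for e in _class_events(events, pc, vocab, system)
                ]
            obs_dates = {
                e["dispense_date"] for e in tev if e["phase"] == "observation"
            }
            hits = False
            for ep in ref_episodes(tev, gap, coverage):
                if ep.start() not in obs_dates:
                    continue
                if (
                    rule.max_duration_days is not None
                    and ep.duration(coverage) <= rule.max_duration_days
                ):
                    continue
                if any(d < ep.start() for d in prior_dates):
                    continue
                if any(d < ep.start() for d in pref_dates):
                    continue
                hits = True
            flags[rule.criterion_id] = hits

        elif rule.category is RuleCategory.DUPLICATION:
            by_month: dict[tuple, set] = {}
            for e in _class_events(obs, tcls, vocab, system):
                key = (e["dispense_date"].year, e["dispense_date"].month)
                by_month.setdefault(key, set()).add(e["drug_code"])
            flags[rule.criterion_id] = any(len(v) >= 2 for v in by_month.values())

        else:  # pragma: no cover
            raise AssertionError(rule.category)
    return flags


def ref_polypharmacy(
    events: list[dict], system: CodingSystem, min_disp: int = 3, min_classes: int = 4
) -> tuple[int, bool]:
    """(n_classes_ge3, polypharmacy) from observation-phase event dicts."""
    counts: dict[str, int] = {}
    for e in events:
        if e.get("phase", "observation") != "observation":
            continue
        code = e["drug_code"]
        if system is CodingSystem.ATC:
            key = code[:5]
        else:
            key = ".".join(code.split(".")[:3])
        counts[key] = counts.get(key, 0) + 1
    n = sum(1 for v in counts.values() if v >= min_disp)
    return n, n >= min_classes
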