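"""Drug vocabulary: classes, dose thresholds and criterion rules.

A :class:`Vocabulary` maps drug codes from either coding system (hierarchical
ATC codes or dotted BNF section codes) onto named drug classes via prefix
matching, carries the dose-threshold table used by dose-and-duration rules,
and holds the declarative criterion rule set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "CodingSystem",
    "RuleCategory",
    "DrugCode",
    "DrugClass",
    "DoseThresholdTable",
    "CriterionRule",
    "Vocabulary",
    "VocabularyError",
    "load_vocabulary",
]


class CodingSystem(str, Enum):
    """Supported drug coding systems."""

    ATC = "ATC"
    BNF = "BNF"


class RuleCategory(str, Enum):
    """Structural categories of criterion rules."""

    DURATION = "DURATION"
    DOSE_DURATION = "DOSE_DURATION"
    CO_PRESCRIPTION = "CO_PRESCRIPTION"
    FIRST_LINE = "FIRST_LINE"
    DUPLICATION = "DUPLICATION"


class VocabularyError(ValueError):
    """Raised on invalid vocabulary configuration; lists every problem found."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid vocabulary configuration:\n  - " + "\n  - ".join(self.problems)
        )


@dataclass(frozen=True)
class DrugCode:
    """A drug code in one coding system."""

    system: CodingSystem
    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("drug code must be non-empty")
        if self.system is CodingSystem.ATC and not self.code.isalnum():
            raise ValueError(f"ATC code must be alphanumeric: {self.code!r}")
        if self.system is CodingSystem.ATC and self.code != self.code.upper():
            raise ValueError(f"ATC code must be uppercase: {self.code!r}")


def code_matches_prefix(code: str, prefix: str, system: CodingSystem) -> bool:
    """Prefix match respecting the structure of each coding system.

    ATC codes match on plain string prefixes; BNF dotted codes match on whole
    dotted components, so ``4.1.1`` matches ``4.1.1.zopiclone`` but not
    ``4.1.10``.
    """
    if system is CodingSystem.ATC:
        return code.startswith(prefix)
    pc = prefix.split(".")
    cc = code.split(".")
    return cc[: len(pc)] == pc


@dataclass(frozen=True)
class DrugClass:
    """A named drug class defined by code prefixes per coding system."""

    class_id: str
    label: str
    prefixes: Mapping[CodingSystem, tuple[str, ...]]
    example_codes: Mapping[CodingSystem, tuple[str, ...]] = field(default_factory=dict)
    default_strength_mg: Optional[float] = None
    granularity_note: str = ""

    def matches(self, code: str, system: CodingSystem) -> bool:
        return any(
            code_matches_prefix(code, p, system) for p in self.prefixes.get(system, ())
        )


class DoseThresholdTable:
    """Maintenance daily-dose thresholds keyed by drug-code prefix.

    Lookup resolves by longest matching prefix within the code's system.
    """

    def __init__(self, entries: Iterable[tuple[CodingSystem, str, float]]):
        self._entries: list[tuple[CodingSystem, str, float]] = list(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, code: str, system: CodingSystem) -> Optional[float]:
        """Return the maintenance dose (mg/day) for ``code`` or None."""
        best: Optional[tuple[int, float]] = None
        for sys_, prefix, mg in self._entries:
            if sys_ is system and code_matches_prefix(code, prefix, system):
                key = len(prefix)
                if best is None or key > best[0]:
                    best = (key, mg)
        return None if best is None else best[1]


@dataclass(frozen=True)
class CriterionRule:
    """One declarative prescribing-appropriateness rule."""

    criterion_id: str
    category: RuleCategory
    target_class: str
    label: str = ""
    max_duration_days: Optional[int] = None
    required_classes: tuple[str, ...] = ()
    preferred_alternative_classes: tuple[str, ...] = ()
    window: str = "same_month"


@dataclass(frozen=True)
class Vocabulary:
    """Immutable bundle of drug classes, dose table, rules and settings."""

    classes: Mapping[str, DrugClass]
    dose_table: DoseThresholdTable
    rules: tuple[CriterionRule, ...]
    settings: Mapping[str, float]
    systems: tuple[CodingSystem, ...]

    def resolve_class(self, code: str, system: CodingSystem) -> set[str]:
        """All class_ids whose prefixes match ``code`` in ``system``.

        Unknown codes resolve to the empty set. Result is independent of
        class declaration order.
        """
        return {
            c.class_id for c in self.classes.values() if c.matches(code, system)
        }

    def rule(self, criterion_id: str) -> CriterionRule:
        for r in self.rules:
            if r.criterion_id == criterion_id:
                return r
        raise KeyError(f"unknown criterion: {criterion_id!r}")

    @property
    def rule_ids(self) -> tuple[str, ...]:
        return tuple(r.criterion_id for r in self.rules)

    def criterion_classes(self) -> set[str]:
        """Classes referenced by any rule (as target, required or preferred)."""
        out: set[str] = set()
        for r in self.rules:
            out.add(r.target_class)
            out.update(r.required_classes)
            out.update(r.preferred_alternative_classes)
        return out

    def filler_classes(self) -> list[str]:
        """Classes not referenced by any rule, in declaration order."""
        used = self.criterion_classes()
        return [cid for cid in self.classes if cid not in used]


def classify_for_polypharmacy(code: str, system: CodingSystem) -> str:
    """Reduce a drug code to its polypharmacy class key.

    ATC codes reduce to their first five characters (chemical subgroup); BNF
    dotted codes reduce to their section component — the leading numeric
    parts (up to three), dropping any trailing chemical-name component.
    """
    if system is CodingSystem.ATC:
        if len(code) < 5:
            raise ValueError(f"ATC code shorter than 5 characters: {code!r}")
        return code[:5]
    section = []
    for part in code.split(".")[:3]:
        if not part.isdigit():
            break
        section.append(part)
    return ".".join(section) if section else code


_CATEGORY_REQUIRED_FIELDS = {
    RuleCategory.DURATION: ("max_duration_days",),
    RuleCategory.DOSE_DURATION: ("max_duration_days",),
    RuleCategory.CO_PRESCRIPTION: ("required_classes",),
    # FIRST_LINE max_duration_days is optional (any-use rules omit it)
    RuleCategory.FIRST_LINE: ("preferred_alternative_classes",),
    RuleCategory.DUPLICATION: (),
}

_SYSTEM_PREFIX_KEY = {CodingSystem.ATC: "atc_prefixes", CodingSystem.BNF: "bnf_prefixes"}
_SYSTEM_EXAMPLE_KEY = {
    CodingSystem.ATC: "example_atc_codes",
    CodingSystem.BNF: "example_bnf_codes",
}


def default_config_path() -> Path:
    """Path of the shipped default vocabulary/rules configuration."""
    return Path(str(resources.files("pipscreen").joinpath("data/default_config.yaml")))


def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    """Load and validate a vocabulary configuration file.

    Parameters
    ----------
    path
        YAML configuration; defaults to the shipped rule set.

    Raises
    ------
    FileNotFoundError
        If the file is missing.
    VocabularyError
        Listing *every* validation problem found, not just the first.
    """
    if path is None:
        path = default_config_path()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vocabulary config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    problems: list[str] = []
    systems = tuple(CodingSystem(s) for s in raw.get("systems", ["ATC", "BNF"]))

    classes: dict[str, DrugClass] = {}
    raw_classes = raw.get("classes") or []
    if not raw_classes:
        problems.append("config defines zero drug classes")
    for entry in raw_classes:
        cid = entry.get("id", "")
        if not cid:
            problems.append("class with missing id")
            continue
        if cid in classes:
            problems.append(f"duplicate class_id: {cid!r}")
            continue
        prefixes: dict[CodingSystem, tuple[str, ...]] = {}
        examples: dict[CodingSystem, tuple[str, ...]] = {}
        for system in systems:
            plist = tuple(str(p) for p in entry.get(_SYSTEM_PREFIX_KEY[system], []) or [])
            if not plist:
                problems.append(f"class {cid!r}: no {system.value} prefixes")
            for a in plist:
                for b in plist:
                    if a != b and code_matches_prefix(b, a, system):
                        problems.append(
                            f"class {cid!r}: prefix {a!r} nests {b!r} ({system.value})"
                        )
            prefixes[system] = plist
            examples[system] = tuple(
                str(c) for c in entry.get(_SYSTEM_EXAMPLE_KEY[system], []) or []
            )
        classes[cid] = DrugClass(
            class_id=cid,
            label=str(entry.get("label", cid)),
            prefixes=prefixes,
            example_codes=examples,
            default_strength_mg=entry.get("default_strength_mg"),
            granularity_note=str(entry.get("granularity_note", "")),
        )

    dose_entries: list[tuple[CodingSystem, str, float]] = []
    seen_dose: set[tuple[CodingSystem, str]] = set()
    for entry in raw.get("dose_thresholds") or []:
        try:
            system = CodingSystem(entry["system"])
            prefix = str(entry["prefix"])
            mg = float(entry["maintenance_mg_per_day"])
        except (KeyError, ValueError) as exc:
            problems.append(f"malformed dose threshold entry {entry!r}: {exc}")
            continue
        if mg <= 0:
            problems.append(f"non-positive maintenance dose for {prefix!r}: {mg}")
        if (system, prefix) in seen_dose:
            problems.append(f"duplicate dose threshold for {system.value}:{prefix!r}")
        seen_dose.add((system, prefix))
        dose_entries.append((system, prefix, mg))

    rules: list[CriterionRule] = []
    seen_rules: set[str] = set()
    for entry in raw.get("criteria") or []:
        rid = entry.get("id", "")
        if not rid:
            problems.append("criterion with missing id")
            continue
        if rid in seen_rules:
            problems.append(f"duplicate criterion id: {rid!r}")
            continue
        seen_rules.add(rid)
        try:
            category = RuleCategory(entry["category"])
        except (KeyError, ValueError):
            problems.append(f"criterion {rid!r}: bad or missing category")
            continue
        target = entry.get("target_class", "")
        if target not in classes:
            problems.append(f"criterion {rid!r}: unknown target_class {target!r}")
        for name in ("required_classes", "preferred_alternative_classes"):
            for c in entry.get(name) or []:
                if c not in classes:
                    problems.append(f"criterion {rid!r}: unknown class {c!r} in {name}")
        maxdur = entry.get("max_duration_days")
        if maxdur is not None and maxdur <= 0:
            problems.append(f"criterion {rid!r}: non-positive max_duration_days")
        for req in _CATEGORY_REQUIRED_FIELDS[category]:
            if not entry.get(req):
                problems.append(f"criterion {rid!r}: {req} required for {category.value}")
        rules.append(
            CriterionRule(
                criterion_id=rid,
                category=category,
                target_class=target,
                label=str(entry.get("label", rid)),
                max_duration_days=maxdur,
                required_classes=tuple(entry.get("required_classes") or ()),
                preferred_alternative_classes=tuple(
                    entry.get("preferred_alternative_classes") or ()
                ),
                window=str(entry.get("window", "same_month")),
            )
        )

    if problems:
        raise VocabularyError(problems)

    settings = dict(raw.get("settings") or {})
    settings.setdefault("gap_tolerance_days", 63)
    settings.setdefault("default_coverage_days", 28)
    settings.setdefault("polypharmacy_min_dispensings", 3)
    settings.setdefault("polypharmacy_min_classes", 4)

    return Vocabulary(
        classes=classes,
        dose_table=DoseThresholdTable(dose_entries),
        rules=tuple(rules),
        settings=settings,
        systems=systems,
    )
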