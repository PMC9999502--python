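"""Explicit PIM criteria as data, and their harmonization to ATC code sets.

Explicit criteria (Beers, STOPP, Laroche, Meds75+ category D, ...) are lists
of avoid-statements.  Statements differ in kind: a plain "avoid drug X" can
be evaluated from dispensing data alone, whereas statements about concurrent
use, specific conditions, doses/durations, weak evidence, or unnamed
anticholinergics cannot, and are dropped before screening.  Class-level
statements ("avoid hypnotics, N05C") are expanded to the individual
substances named anywhere across the harmonized criteria, then the whole
summary is screened against the national formulary so that only marketed
products remain.  The result per criterion is a concrete set of 7-character
ATC codes, comparable across criteria.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .atc import is_substance_code, matches_prefix, validate_pattern

logger = logging.getLogger(__name__)

#: The nine criteria compared in this package, keyed by short id.
CRITERION_IDS = (
    "meds75",
    "beers",
    "eu7",
    "swedish",
    "laroche",
    "norgep_nh",
    "priscus",
    "ryg",
    "stopp",
)


class Scope(str, Enum):
    SUBSTANCE = "substance"
    DRUG_CLASS = "drug_class"


class StatementKind(str, Enum):
    """Kinds of avoid-statements found in explicit criteria.

    Only ``PLAIN_AVOID`` is admissible for register-based screening; the
    remaining kinds need clinical context a dispensing register lacks.
    """

    PLAIN_AVOID = "plain_avoid"
    CONCURRENT_USE = "concurrent_use"
    CONDITION_SPECIFIC = "condition_specific"
    DOSE_OR_DURATION_LIMITED = "dose_or_duration_limited"
    WEAK_EVIDENCE = "weak_evidence"
    ANTICHOLINERGIC_UNSPECIFIED = "anticholinergic_unspecified"


#: Human-readable exclusion reason per inadmissible statement kind.
EXCLUSION_REASONS: Mapping[StatementKind, str] = {
    StatementKind.CONCURRENT_USE: "concurrent use",
    StatementKind.CONDITION_SPECIFIC: "condition-specific",
    StatementKind.DOSE_OR_DURATION_LIMITED: "dose/duration-limited",
    StatementKind.WEAK_EVIDENCE: "weak evidence",
    StatementKind.ANTICHOLINERGIC_UNSPECIFIED: (
        "anticholinergic without specific substance"
    ),
}


class AvailabilityMode(str, Enum):
    SINGLE_ONLY = "single_only"
    COMBINATION_ONLY = "combination_only"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class PimStatement:
    """One avoid-statement of one criterion, scoped to an ATC pattern."""

    criterion_id: str
    statement_id: str
    atc_pattern: str
    scope: Scope
    statement_kind: StatementKind
    note: str = ""

    def __post_init__(self) -> None:
        if self.criterion_id not in CRITERION_IDS:
            raise ValueError(
                f"statement {self.statement_id}: unknown criterion "
                f"{self.criterion_id!r} (expected one of {CRITERION_IDS})"
            )
        validate_pattern(self.atc_pattern)
        substance = is_substance_code(self.atc_pattern)
        if substance != (self.scope is Scope.SUBSTANCE):
            raise ValueError(
                f"statement {self.statement_id}: scope {self.scope.value} "
                f"inconsistent with pattern {self.atc_pattern!r} "
                "(substance scope iff 7-character code)"
            )


@dataclass(frozen=True)
class DroppedStatement:
    """A statement excluded from screening, with its exclusion reason."""

    statement: PimStatement
    reason: str


@dataclass(frozen=True)
class Criterion:
    """One named set of explicit PIM criteria."""

    criterion_id: str
    full_name: str
    country: str
    age_threshold: int
    statements: tuple[PimStatement, ...]
    pim_section: str = ""

    def __post_init__(self) -> None:
        if self.age_threshold not in (65, 70, 75):
            raise ValueError(
                f"{self.criterion_id}: age threshold {self.age_threshold} "
                "not one of 65/70/75"
            )
        for s in self.statements:
            if s.criterion_id != self.criterion_id:
                raise ValueError(
                    f"statement {s.statement_id} belongs to {s.criterion_id}, "
                    f"not {self.criterion_id}"
                )


@dataclass(frozen=True)
class FormularyEntry:
    """Market availability of one substance code in the study country."""

    atc_code: str
    availability_mode: AvailabilityMode

    def __post_init__(self) -> None:
        if not is_substance_code(self.atc_code):
            raise ValueError(f"formulary code {self.atc_code!r} not substance-level")

    @property
    def available(self) -> bool:
        return self.availability_mode is not AvailabilityMode.NONE


@dataclass
class CriterionSet:
    """A criterion resolved to marketed substance codes, with provenance."""

    criterion_id: str
    resolved_codes: frozenset[str]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations


def filter_statements(
    statements: Sequence[PimStatement],
) -> tuple[list[PimStatement], list[DroppedStatement]]:
    """Partition statements into admissible (plain avoid) and dropped.

    Dropped statements are annotated with the reason their kind cannot be
    evaluated from a prescription-purchase register.
    """
    kept: list[PimStatement] = []
    dropped: list[DroppedStatement] = []
    for s in statements:
        if not isinstance(s.statement_kind, StatementKind):
            raise ValueError(
                f"statement {s.statement_id}: unknown statement kind "
                f"{s.statement_kind!r}"
            )
        if s.statement_kind is StatementKind.PLAIN_AVOID:
            kept.append(s)
        else:
            dropped.append(
                DroppedStatement(s, EXCLUSION_REASONS[s.statement_kind])
            )
    return kept, dropped


def expand_class_statement(
    statement: PimStatement, named_substances: Iterable[str]
) -> frozenset[str]:
    """Expand a class-level statement to named substances under its prefix.

    The expansion universe is the set of substance codes mentioned by name
    anywhere across the harmonized criteria: a class statement such as
    "avoid hypnotics (N05C)" is documented for every individually named
    drug whose code falls under N05C.
    """
    if statement.scope is not Scope.DRUG_CLASS:
        raise ValueError(
            f"statement {statement.statement_id} has substance scope; "
            "only class-scope statements can be expanded"
        )
    return frozenset(
        c for c in named_substances if matches_prefix(c, statement.atc_pattern)
    )


def screen_market(
    codes: Iterable[str], formulary: Iterable[FormularyEntry]
) -> frozenset[str]:
    """Keep only codes marketed nationally.

    A code marketed solely as part of a combination product (codeine in
    analgesic combinations, for example) counts as available.  Codes absent
    from the formulary are treated as not marketed and logged.
    """
    mode_by_code = {e.atc_code: e.availability_mode for e in formulary}
    kept = set()
    for code in codes:
        mode = mode_by_code.get(code)
        if mode is None:
            logger.warning("ATC code %s not in formulary; treated as not marketed", code)
            continue
        if mode is not AvailabilityMode.NONE:
            kept.add(code)
    return frozenset(kept)


def named_substance_universe(criteria: Iterable[Criterion]) -> frozenset[str]:
    """All substance codes named by an admissible statement of any criterion."""
    universe: set[str] = set()
    for crit in criteria:
        kept, _ = filter_statements(crit.statements)
        universe.update(s.atc_pattern for s in kept if s.scope is Scope.SUBSTANCE)
    return frozenset(universe)


def resolve_criterion(
    criterion: Criterion,
    all_criteria: Sequence[Criterion],
    formulary: Iterable[FormularyEntry],
) -> CriterionSet:
    """Resolve one criterion to its marketed substance-code set.

    Pipeline: drop inadmissible statements, expand class statements against
    the cross-criteria named-substance universe, then screen against the
    formulary.  Provenance records which statements contributed each code.
    """
    universe = named_substance_universe(all_criteria)
    kept, _ = filter_statements(criterion.statements)

    contributors: dict[str, list[str]] = defaultdict(list)
    for s in kept:
        if s.scope is Scope.SUBSTANCE:
            contributors[s.atc_pattern].append(s.statement_id)
        else:
            for code in sorted(expand_class_statement(s, universe)):
                contributors[code].append(s.statement_id)

    marketed = screen_market(contributors.keys(), formulary)
    provenance = {
        code: tuple(sorted(contributors[code])) for code in sorted(marketed)
    }
    return CriterionSet(
        criterion_id=criterion.criterion_id,
        resolved_codes=marketed,
        provenance=provenance,
    )


def resolve_all(
    criteria: Sequence[Criterion], formulary: Sequence[FormularyEntry]
) -> dict[str, CriterionSet]:
    """Resolve every criterion; keyed by criterion id, insertion-ordered."""
    return {
        c.criterion_id: resolve_criterion(c, criteria, formulary) for c in criteria
    }


def pre_screen_summary(criteria: Sequence[Criterion]) -> frozenset[str]:
    """Union of substance codes in the harmonized summary before the
    formulary screen (named substances plus class expansions)."""
    universe = named_substance_universe(criteria)
    summary: set[str] = set(universe)
    for crit in criteria:
        kept, _ = filter_statements(crit.statements)
        for s in kept:
            if s.scope is Scope.DRUG_CLASS:
                summary.update(expand_class_statement(s, universe))
    return frozenset(summary)


def consensus_count(code: str, criterion_sets: Iterable[CriterionSet]) -> int:
    """Number of resolved criteria that list *code* as a PIM (0–9)."""
    return sum(1 for cs in criterion_sets if code in cs.resolved_codes)


# ---------------------------------------------------------------------------
# Delimited-text I/O

CRITERIA_COLUMNS = (
    "criterion_id",
    "statement_id",
    "atc_pattern",
    "scope",
    "statement_kind",
    "note",
)


def load_statements_csv(path: str | Path) -> list[PimStatement]:
    """Read a flat criteria table (one row per statement)."""
    out: list[PimStatement] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PimStatement(
                    criterion_id=row["criterion_id"],
                    statement_id=row["statement_id"],
                    atc_pattern=row["atc_pattern"],
                    scope=Scope(row["scope"]),
                    statement_kind=StatementKind(row["statement_kind"]),
                    note=row.get("note", "") or "",
                )
            )
    return out


def write_statements_csv(path: str | Path, criteria: Sequence[Criterion]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CRITERIA_COLUMNS)
        for crit in criteria:
            for s in crit.statements:
                w.writerow(
                    [
                        s.criterion_id,
                        s.statement_id,
                        s.atc_pattern,
                        s.scope.value,
                        s.statement_kind.value,
                        s.note,
                    ]
                )


def load_formulary_csv(path: str | Path) -> list[FormularyEntry]:
    """Read a formulary table (columns: atc_code, availability_mode)."""
    out: list[FormularyEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                FormularyEntry(
                    atc_code=row["atc_code"],
                    availability_mode=AvailabilityMode(row["availability_mode"]),
                )
            )
    return out


def write_formulary_csv(
    path: str | Path, formulary: Sequence[FormularyEntry]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["atc_code", "availability_mode"])
        for e in formulary:
            w.writerow([e.atc_code, e.availability_mode.value])


def group_statements(
    statements: Sequence[PimStatement],
    criterion_meta: Mapping[str, tuple[str, str, int, str]] | None = None,
) -> list[Criterion]:
    """Assemble flat statements into Criterion objects.

    *criterion_meta* maps criterion_id -> (full_name, country, age_threshold,
    pim_section); ids without metadata get placeholder names and the 75-year
    threshold.
    """
    by_crit: dict[str, list[PimStatement]] = defaultdict(list)
    for s in statements:
        by_crit[s.criterion_id].append(s)
    out = []
    for cid in CRITERION_IDS:
        if cid not in by_crit:
            continue
        meta = (criterion_meta or {}).get(cid, (cid, "", 75, ""))
        out.append(
            Criterion(
                criterion_id=cid,
                full_name=meta[0],
                country=meta[1],
                age_threshold=meta[2],
                statements=tuple(by_crit[cid]),
                pim_section=meta[3],
            )
        )
    return out
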