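"""Joining annual cohorts against resolved criterion sets.

A person is a PIM user under a criterion in a given year iff they have at
least one retained purchase of one of the criterion's resolved ATC codes
that year.  Per-person PIM counts are distinct ATC codes pooled over the
whole observation period, regardless of how many times each was purchased.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .criteria import CriterionSet
from .register import AnnualCohort


@dataclass
class ScreenResult:
    """Per-year and pooled PIM exposure facts for one criterion."""

    criterion_id: str
    users_by_year: dict[int, frozenset[str]]
    per_person_codes: dict[str, frozenset[str]]
    per_code_users: dict[str, frozenset[str]]

    @property
    def pooled_users(self) -> frozenset[str]:
        """Persons with >=1 PIM purchase anywhere in the observation period."""
        return frozenset(self.per_person_codes)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format exposure table: year, criterion_id, person_id, atc_code."""
        rows = [
            (year, self.criterion_id, person, code)
            for year, users in sorted(self.users_by_year.items())
            for person in sorted(users)
            for code in sorted(self._codes_in_year.get((year, person), ()))
        ]
        return pd.DataFrame(
            rows, columns=["year", "criterion_id", "person_id", "atc_code"]
        )

    # populated by screen(); maps (year, person) -> codes purchased that year
    _codes_in_year: dict[tuple[int, str], frozenset[str]] = field(
        default_factory=dict, init=False, repr=False, compare=False
    )


def screen(
    cohorts: Mapping[int, AnnualCohort], criterion_set: CriterionSet
) -> ScreenResult:
    """Compute PIM exposure of every cohort under one resolved criterion."""
    resolved = criterion_set.resolved_codes
    users_by_year: dict[int, frozenset[str]] = {}
    person_codes: dict[str, set[str]] = {}
    code_users: dict[str, set[str]] = {}
    codes_in_year: dict[tuple[int, str], frozenset[str]] = {}

    for year in sorted(cohorts):
        recs = cohorts[year].records
        hits = recs[recs["atc_code"].isin(resolved)]
        users_by_year[year] = frozenset(hits["person_id"].unique())
        for (person, code), _ in hits.groupby(["person_id", "atc_code"]):
            person_codes.setdefault(person, set()).add(code)
            code_users.setdefault(code, set()).add(person)
        by_person = hits.groupby("person_id")["atc_code"].apply(frozenset)
        for person, codes in by_person.items():
            codes_in_year[(year, person)] = codes

    result = ScreenResult(
        criterion_id=criterion_set.criterion_id,
        users_by_year=users_by_year,
        per_person_codes={p: frozenset(c) for p, c in sorted(person_codes.items())},
        per_code_users={c: frozenset(p) for c, p in sorted(code_users.items())},
    )
    result._codes_in_year = codes_in_year
    return result


def pims_per_person_distribution(result: ScreenResult) -> dict[str, float | int | None]:
    """Distribution of distinct-PIM counts among PIM users.

    The denominator is persons with at least one PIM purchase under the
    criterion (not the whole population).  Returns min, max, mean, sd,
    median and the share of users with two or more distinct PIMs; all None
    for an empty user set.
    """
    counts = sorted(len(codes) for codes in result.per_person_codes.values())
    if not counts:
        return {
            "n_users": 0, "min": None, "max": None, "mean": None,
            "sd": None, "median": None, "share_two_or_more": None,
        }
    n = len(counts)
    return {
        "n_users": n,
        "min": counts[0],
        "max": counts[-1],
        "mean": statistics.fmean(counts),
        "sd": statistics.stdev(counts) if n > 1 else 0.0,
        "median": statistics.median(counts),
        "share_two_or_more": sum(1 for c in counts if c >= 2) / n,
    }
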