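"""Shared fixtures and the per-person brute-force screening oracle."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pimscreen import reference_criteria, resolve_all

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    """(criteria, formulary, resolved sets) of the packaged synthetic
    nine-criteria summary."""
    criteria, formulary = reference_criteria()
    sets = resolve_all(list(criteria), list(formulary))
    return list(criteria), list(formulary), sets


@pytest.fixture(scope="session")
def pim_universe(reference):
    _, _, sets = reference
    return frozenset().union(*(s.resolved_codes for s in sets.values()))


def brute_force_screen(records: pd.DataFrame, resolved: frozenset):
    """Reference implementation of screening: plain per-row Python loops.

    *records* must already be cohort-eligible rows with parsed dates.
    Returns (users_by_year, per_person_codes, per_code_users) as plain sets.
    """
    users_by_year: dict[int, set] = {}
    per_person: dict[str, set] = {}
    per_code: dict[str, set] = {}
    for row in records.itertuples():
        date = row.purchase_date
        year = date.year if hasattr(date, "year") else int(str(date)[:4])
        if row.atc_code not in resolved:
            continue
        users_by_year.setdefault(year, set()).add(row.person_id)
        per_person.setdefault(row.person_id, set()).add(row.atc_code)
        per_code.setdefault(row.atc_code, set()).add(row.person_id)
    return users_by_year, per_person, per_code


def random_register(
    rng: np.random.Generator,
    n_rows: int,
    codes: list[str],
    n_persons: int = 30,
    years=(2017, 2018, 2019),
) -> pd.DataFrame:
    """A small random register of eligible older persons."""
    persons = [f"R{i:03d}" for i in range(n_persons)]
    births = {
        p: dt.date(1942 - int(rng.integers(0, 20)), 1 + int(rng.integers(0, 12)),
                   1 + int(rng.integers(0, 28)))
        for p in persons
    }
    rows = []
    for _ in range(n_rows):
        p = persons[rng.integers(0, n_persons)]
        year = years[rng.integers(0, len(years))]
        date = dt.date(year, 1 + int(rng.integers(0, 12)), 1 + int(rng.integers(0, 28)))
        rows.append(
            {
                "person_id": p,
                "sex": "F" if rng.random() < 0.6 else "M",
                "birth_date": str(births[p]),
                "purchase_date": str(date),
                "atc_code": codes[rng.integers(0, len(codes))],
                "pharm_form": "tablet",
            }
        )
    return pd.DataFrame(rows, columns=[
        "person_id", "sex", "birth_date", "purchase_date", "atc_code", "pharm_form",
    ])
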