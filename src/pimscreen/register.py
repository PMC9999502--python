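"""Prescription-purchase register I/O and annual cohort construction.

A register extract is a delimited table of dispensing events: pseudonymized
person id, sex, birth date, purchase date, ATC code and pharmaceutical form.
Cohort construction applies the record-level eligibility rules: the person
must be at least ``age_floor`` years old on the purchase date (birthday-exact
completed years), sex must be recorded, the ATC code must belong to the
harmonized PIM summary, and the pharmaceutical form must not be blocklisted
(systemically irrelevant forms such as topical estrogen).  Records are then
split into closed calendar-year cohorts, each carrying the mean-population
census denominator for its year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Default pharmaceutical-form blocklist (case-insensitive exact labels).
DEFAULT_FORM_BLOCKLIST = ("topical estrogen",)

REGISTER_COLUMNS = (
    "person_id",
    "sex",
    "birth_date",
    "purchase_date",
    "atc_code",
    "pharm_form",
)

#: Rejection reasons, in the order filters are applied.
REASON_AGE = "incorrect age"
REASON_SEX = "missing gender"
REASON_ATC = "ATC code not in PIM summary"
REASON_FORM = "invalid pharmaceutical form"
REASON_MALFORMED = "malformed row"


@dataclass
class AnnualCohort:
    """Retained purchase records of one calendar year plus its denominator."""

    year: int
    records: pd.DataFrame
    denominator: float

    @property
    def persons(self) -> frozenset[str]:
        return frozenset(self.records["person_id"].unique())


def age_at(birth_date: dt.date, on_date: dt.date) -> int:
    """Completed years of age on *on_date*, birthday-exact.

    A person turns k on the k-th anniversary of their birth date.
    """
    if on_date < birth_date:
        raise ValueError(f"date {on_date} precedes birth date {birth_date}")
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def load_register(
    path: str | Path,
    form_blocklist: Sequence[str] = DEFAULT_FORM_BLOCKLIST,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a register CSV; return (records, rejection log).

    Structurally malformed rows (unparseable dates, missing sex, blocklisted
    form) are rejected with a reason, never fatal.  The rejection log has the
    original columns plus ``reason``; retained + rejected = input rows.
    """
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, usecols=list(REGISTER_COLUMNS)
    )
    return clean_records(raw, form_blocklist)


def clean_records(
    raw: pd.DataFrame,
    form_blocklist: Sequence[str] = DEFAULT_FORM_BLOCKLIST,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate raw string records; see :func:`load_register`."""
    df = raw.copy()
    birth = pd.to_datetime(df["birth_date"], format="%Y-%m-%d", errors="coerce")
    purchase = pd.to_datetime(df["purchase_date"], format="%Y-%m-%d", errors="coerce")

    reason = pd.Series("", index=df.index, dtype=object)
    malformed = (
        birth.isna()
        | purchase.isna()
        | (purchase < birth)
        | (df["person_id"].str.strip() == "")
        | (df["atc_code"].str.strip() == "")
    )
    reason[malformed] = REASON_MALFORMED

    missing_sex = (~malformed) & (~df["sex"].isin(["F", "M"]))
    reason[missing_sex] = REASON_SEX

    block = {f.lower() for f in form_blocklist}
    bad_form = (reason == "") & df["pharm_form"].str.lower().isin(block)
    reason[bad_form] = REASON_FORM

    rejected = df[reason != ""].assign(reason=reason[reason != ""])
    kept = df[reason == ""].copy()
    kept["birth_date"] = birth[reason == ""].dt.date
    kept["purchase_date"] = purchase[reason == ""].dt.date
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


def load_census(path: str | Path) -> dict[int, float]:
    """Read a census CSV (year, mean_population) into a mapping."""
    df = pd.read_csv(path)
    census = {int(r.year): float(r.mean_population) for r in df.itertuples()}
    if any(v <= 0 for v in census.values()):
        raise ValueError("census mean_population values must be positive")
    return census


def build_cohorts(
    records: pd.DataFrame,
    census: Mapping[int, float],
    pim_universe: Iterable[str],
    age_floor: int = 75,
    form_blocklist: Sequence[str] = DEFAULT_FORM_BLOCKLIST,
) -> tuple[dict[int, AnnualCohort], pd.DataFrame]:
    """Split eligible records into annual cohorts.

    Returns (cohorts keyed by year, rejection log).  Eligibility filters are
    applied in a fixed order so every rejected record carries exactly one
    reason: age at purchase >= *age_floor*, sex recorded, ATC code in the PIM
    summary, pharmaceutical form not blocklisted.  Raises ``KeyError`` naming
    the year if the census does not cover a retained record's year.
    """
    df = records.copy().reset_index(drop=True)
    universe = frozenset(pim_universe)

    birth = pd.to_datetime(df["birth_date"])
    purchase = pd.to_datetime(df["purchase_date"])
    years = purchase.dt.year - birth.dt.year
    before_birthday = (
        purchase.dt.month * 100 + purchase.dt.day
        < birth.dt.month * 100 + birth.dt.day
    )
    age = years - before_birthday.astype(int)

    reason = pd.Series("", index=df.index, dtype=object)
    reason[age < age_floor] = REASON_AGE
    block = {f.lower() for f in form_blocklist}
    sex_missing = (reason == "") & (~df["sex"].isin(["F", "M"]))
    reason[sex_missing] = REASON_SEX
    bad_atc = (reason == "") & (~df["atc_code"].isin(universe))
    reason[bad_atc] = REASON_ATC
    bad_form = (reason == "") & df["pharm_form"].str.lower().isin(block)
    reason[bad_form] = REASON_FORM

    rejected = df[reason != ""].assign(reason=reason[reason != ""])
    kept = df[reason == ""].copy()
    kept["year"] = purchase[reason == ""].dt.year

    cohorts: dict[int, AnnualCohort] = {}
    for year, group in kept.groupby("year", sort=True):
        year = int(year)
        if year not in census:
            raise KeyError(f"census table does not cover year {year}")
        cohorts[year] = AnnualCohort(
            year=year,
            records=group.drop(columns="year").reset_index(drop=True),
            denominator=float(census[year]),
        )
    return cohorts, rejected.reset_index(drop=True)
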