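"""Synthetic prescription-purchase registers with known ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: an older population with a configurable age/sex structure (defaults
match a national 75+ cohort: mean age 82.6, SD 5.7, 61.8% female),
independent per-drug annual use probabilities, a geometric number of
purchases per user-year at uniform dates, and optional noise records
(missing sex, under-age persons, blocklisted pharmaceutical forms) that the
cohort-construction rules must reject.  Every draw is reproducible from the
config seed, and a ground-truth exposure table records exactly which
person-year-drug exposures were generated, so pipeline outputs can be
checked by set equality rather than approximately.

Simplifications relative to real dispensing data: drug use is independent
across drugs and years (no polypharmacy correlation, no persistence), and
purchase dates carry no seasonality.  The counting statistics downstream
are insensitive to both.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .register import age_at


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic register draw.

    ``drug_use_probs`` maps each ATC substance code to the annual
    probability that a person purchases it at least once.  Noise rates are
    fractions: ``underage_rate`` of persons are too young throughout the
    study window; ``missing_sex_rate`` and ``form_noise_rate`` of eligible
    purchase rows are corrupted (blank sex / blocklisted form).
    """

    n_persons: int
    drug_use_probs: Mapping[str, float]
    seed: int
    mean_age: float = 82.6
    sd_age: float = 5.7
    prop_female: float = 0.618
    years: Sequence[int] = (2017, 2018, 2019)
    purchases_per_user_mean: float = 3.0
    form_noise_rate: float = 0.0
    missing_sex_rate: float = 0.0
    underage_rate: float = 0.0
    age_floor: int = 75
    max_age: float = 105.0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        for code, p in self.drug_use_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"use probability for {code} outside [0, 1]")
        for name in ("prop_female", "form_noise_rate", "missing_sex_rate",
                     "underage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.purchases_per_user_mean < 1.0:
            raise ValueError("purchases_per_user_mean must be >= 1")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")


@dataclass
class SimResult:
    """A generated register plus everything needed to verify the pipeline."""

    persons: pd.DataFrame
    records: pd.DataFrame
    truth: pd.DataFrame
    census: dict[int, float]
    noise_counts: dict[str, int]
    config: SimConfig = field(repr=False, default=None)  # type: ignore


def _reference_date(config: SimConfig) -> dt.date:
    return dt.date(config.years[0], 1, 1)


def _calibrated_loc(mean_age: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a [lo, hi]-truncated normal whose mean is
    *mean_age*.  Truncation at the age floor pulls the mean upward, so the
    configured population mean is hit by shifting the parent distribution
    down rather than by quoting a biased mean."""
    from scipy.optimize import brentq

    if not lo + 0.5 < mean_age < hi - 0.5:
        raise ValueError(
            f"mean age {mean_age} not inside truncation window ({lo}, {hi})"
        )

    def realized_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(brentq(lambda L: realized_mean(L) - mean_age,
                        lo - 12 * sd, hi))


def generate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw persons: id, sex, birth date, eligibility flag.

    Eligible persons' ages at the study start follow a normal distribution
    truncated to [age_floor, max_age], so they stay age-eligible for every
    purchase.  Under-age persons (the ``underage_rate`` fraction) are young
    enough to remain below the age floor through the last study year.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_under = int(round(config.underage_rate * config.n_persons))
    n_elig = config.n_persons - n_under

    loc = _calibrated_loc(
        config.mean_age, config.sd_age, config.age_floor, config.max_age
    )
    a = (config.age_floor - loc) / config.sd_age
    b = (config.max_age - loc) / config.sd_age
    ages = sps.truncnorm.rvs(
        a, b, loc=loc, scale=config.sd_age, size=n_elig, random_state=rng,
    )

    span = config.years[-1] - config.years[0] + 1
    under_lo, under_hi = 65, config.age_floor - span - 1
    under_years = rng.integers(under_lo, under_hi + 1, size=n_under)
    under_frac = rng.random(n_under)

    ref = _reference_date(config)
    rows = []
    for i, age in enumerate(ages):
        k, frac = int(age), age - int(age)
        birth = dt.date(ref.year - k, 1, 1) - dt.timedelta(
            days=int(frac * 365)
        )
        rows.append((f"P{i:06d}", birth, True))
    for j in range(n_under):
        k, frac = int(under_years[j]), float(under_frac[j])
        birth = dt.date(ref.year - k, 1, 1) - dt.timedelta(
            days=int(frac * 365)
        )
        rows.append((f"P{n_elig + j:06d}", birth, False))

    sex = np.where(rng.random(config.n_persons) < config.prop_female, "F", "M")
    persons = pd.DataFrame(rows, columns=["person_id", "birth_date", "eligible"])
    persons["sex"] = sex
    return persons[["person_id", "sex", "birth_date", "eligible"]]


def generate_purchases(
    persons: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Draw purchase records and the ground-truth exposure table.

    Per person, year and drug, a Bernoulli draw with the configured annual
    probability decides use; users receive a geometric number (mean
    ``purchases_per_user_mean``) of purchases at uniform dates within the
    year.  Noise corruptions are applied to disjoint row subsets of
    eligible persons' records, so every injected noise row is rejected for
    exactly its own reason downstream.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(persons)
    pid = persons["person_id"].to_numpy()
    sex = persons["sex"].to_numpy()
    birth = persons["birth_date"].to_numpy()
    eligible = persons["eligible"].to_numpy()

    geom_p = 1.0 / config.purchases_per_user_mean
    rec_pid, rec_sex, rec_birth, rec_date, rec_atc = [], [], [], [], []
    truth_rows = []

    for year in config.years:
        start = dt.date(year, 1, 1)
        n_days = (dt.date(year, 12, 31) - start).days + 1
        for code in config.drug_use_probs:
            p = config.drug_use_probs[code]
            users = np.flatnonzero(rng.random(n) < p)
            if users.size == 0:
                continue
            counts = rng.geometric(geom_p, size=users.size)
            day_offsets = rng.integers(0, n_days, size=int(counts.sum()))
            idx = np.repeat(users, counts)
            rec_pid.append(pid[idx])
            rec_sex.append(sex[idx])
            rec_birth.append(birth[idx])
            rec_date.append(
                [str(start + dt.timedelta(days=int(d))) for d in day_offsets]
            )
            rec_atc.append(np.full(idx.size, code))
            truth_rows.extend(
                (pid[u], year, code, bool(eligible[u])) for u in users
            )

    if rec_pid:
        records = pd.DataFrame(
            {
                "person_id": np.concatenate(rec_pid),
                "sex": np.concatenate(rec_sex),
                "birth_date": [str(b) for b in np.concatenate(rec_birth)],
                "purchase_date": np.concatenate(
                    [np.asarray(d) for d in rec_date]
                ),
                "atc_code": np.concatenate(rec_atc),
            }
        )
    else:
        records = pd.DataFrame(
            columns=["person_id", "sex", "birth_date", "purchase_date", "atc_code"]
        )
    records["pharm_form"] = "tablet"

    # deterministic noise injection on disjoint rows of eligible persons
    elig_set = frozenset(pid[eligible])
    elig_rows = records.index[records["person_id"].isin(elig_set)].to_numpy()
    n_sex = int(round(config.missing_sex_rate * len(records)))
    n_form = int(round(config.form_noise_rate * len(records)))
    if n_sex + n_form > len(elig_rows):
        raise ValueError("noise rates too high for the generated register")
    chosen = rng.permutation(elig_rows)[: n_sex + n_form]
    records.loc[chosen[:n_sex], "sex"] = ""
    records.loc[chosen[n_sex:], "pharm_form"] = "topical estrogen"

    n_underage_rows = int((~records["person_id"].isin(elig_set)).sum())
    noise_counts = {
        "missing_sex": n_sex,
        "bad_form": n_form,
        "underage": n_underage_rows,
    }
    truth = pd.DataFrame(
        truth_rows, columns=["person_id", "year", "atc_code", "eligible"]
    )
    records = records.sort_values(
        ["person_id", "purchase_date", "atc_code"], kind="mergesort"
    ).reset_index(drop=True)
    return records, truth, noise_counts


def generate_census(
    persons: pd.DataFrame,
    years: Sequence[int],
    age_floor: int = 75,
    override: Mapping[int, float] | None = None,
) -> dict[int, float]:
    """Mid-year count of persons at or above the age floor, per year.

    *override* substitutes externally supplied denominators (for example
    official mean-population figures) verbatim.
    """
    if override is not None:
        return {int(y): float(override[y]) for y in years}
    census = {}
    for year in years:
        mid = dt.date(year, 7, 1)
        census[year] = float(
            sum(1 for b in persons["birth_date"] if age_at(b, mid) >= age_floor)
        )
    return census


def simulate_register(config: SimConfig) -> SimResult:
    """Generate a complete synthetic study input set from one seed."""
    rng = np.random.default_rng(config.seed)
    persons = generate_population(config, rng)
    records, truth, noise_counts = generate_purchases(persons, config, rng)
    census = generate_census(persons, config.years, config.age_floor)
    return SimResult(
        persons=persons,
        records=records,
        truth=truth,
        census=census,
        noise_counts=noise_counts,
        config=config,
    )
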