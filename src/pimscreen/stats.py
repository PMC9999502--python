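"""Drug-utilization statistics over screened PIM exposure.

Annual prevalence is the number of persons with at least one PIM purchase
in a year divided by that year's mean population (a census figure, possibly
half-integer).  Overlap against a reference criterion is the share of the
other criterion's pooled users also flagged by the reference — an
asymmetric measure.  Class- and substance-level user proportions use a
fixed denominator: the pooled count of persons flagged by ANY criterion
over the whole observation period.  Percentages are computed in full
precision and rendered to one decimal, half-up.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .atc import CANONICAL_LENGTHS, matches_prefix
from .criteria import CriterionSet
from .register import AnnualCohort
from .screening import ScreenResult, screen

logger = logging.getLogger(__name__)


def round_pct(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, as printed in epidemiological tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def annual_prevalence(
    result: ScreenResult, census: Mapping[int, float]
) -> pd.DataFrame:
    """One row per year: numerator, denominator, prevalence percent."""
    rows = []
    for year in sorted(result.users_by_year):
        denom = float(census[year])
        if denom <= 0:
            raise ValueError(f"zero/negative census denominator for {year}")
        num = len(result.users_by_year[year])
        pct = 100.0 * num / denom
        if num > denom:
            logger.warning(
                "%s %d: numerator %d exceeds census denominator %s",
                result.criterion_id, year, num, denom,
            )
        rows.append(
            {
                "criterion_id": result.criterion_id,
                "year": year,
                "numerator": num,
                "denominator": denom,
                "prevalence_pct": round_pct(pct),
            }
        )
    return pd.DataFrame(rows)


def prevalence_table(
    results: Mapping[str, ScreenResult], census: Mapping[int, float]
) -> pd.DataFrame:
    """Stacked annual prevalence for several criteria."""
    frames = [annual_prevalence(r, census) for r in results.values()]
    return pd.concat(frames, ignore_index=True)


def overlap_vs_reference(
    reference_users: Iterable[str], other_users: Iterable[str]
) -> float | None:
    """Share of the other criterion's pooled users also flagged by the
    reference criterion, in percent; None when the other set is empty."""
    other = frozenset(other_users)
    if not other:
        return None
    ref = frozenset(reference_users)
    return round_pct(100.0 * len(ref & other) / len(other))


def overlap_table(
    results: Mapping[str, ScreenResult], reference_id: str
) -> pd.DataFrame:
    """Overlap of every criterion against the reference, pooled over years.

    The reference's own cell is reported as missing, as is conventional.
    """
    ref_users = results[reference_id].pooled_users
    rows = []
    for cid, res in results.items():
        pct = (
            None
            if cid == reference_id
            else overlap_vs_reference(ref_users, res.pooled_users)
        )
        rows.append({"other_criterion_id": cid, "overlap_pct": pct})
    return pd.DataFrame(rows)


def usage_by_group(
    results: Mapping[str, ScreenResult],
    group_level: int,
    denominator: int,
) -> pd.DataFrame:
    """Distinct-user proportions of ATC groups, per criterion and overall.

    *group_level* is the prefix length of one of the five canonical ATC
    levels; substances are grouped by string prefix.  The denominator is
    fixed (the pooled all-criteria PIM-user count), so proportions are
    comparable across criteria.  A criterion with no resolved codes in a
    group contributes no row for it (a blank cell, not 0.0).
    """
    if group_level not in CANONICAL_LENGTHS:
        raise ValueError(f"group level must be one of {CANONICAL_LENGTHS}")
    if denominator <= 0:
        raise ValueError("denominator must be positive")

    rows = []
    union_users: dict[str, set[str]] = {}
    for cid, res in results.items():
        group_users: dict[str, set[str]] = {}
        for code, users in res.per_code_users.items():
            grp = code[:group_level]
            group_users.setdefault(grp, set()).update(users)
            union_users.setdefault(grp, set()).update(users)
        for grp in sorted(group_users):
            rows.append(
                {
                    "group": grp,
                    "criterion_id": cid,
                    "users": len(group_users[grp]),
                    "proportion_pct": round_pct(
                        100.0 * len(group_users[grp]) / denominator
                    ),
                }
            )
    for grp in sorted(union_users):
        rows.append(
            {
                "group": grp,
                "criterion_id": "all",
                "users": len(union_users[grp]),
                "proportion_pct": round_pct(
                    100.0 * len(union_users[grp]) / denominator
                ),
            }
        )
    return pd.DataFrame(rows)


def top_n(
    result: ScreenResult,
    denominator: int,
    n: int = 3,
) -> pd.DataFrame:
    """Top-*n* substances of a criterion by distinct-user count.

    Ties are broken by ascending ATC code; proportions use the fixed
    all-criteria PIM-user denominator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        result.per_code_users.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )[:n]
    return pd.DataFrame(
        [
            {
                "criterion_id": result.criterion_id,
                "rank": i,
                "atc_code": code,
                "users": len(users),
                "proportion_pct": round_pct(100.0 * len(users) / denominator),
            }
            for i, (code, users) in enumerate(ranked, 1)
        ]
    )


def exclude_codes(
    criterion_set: CriterionSet,
    excluded: Iterable[str],
    keep_exceptions: Iterable[str] = (),
) -> CriterionSet:
    """Remove codes under any excluded prefix, honouring keep-exceptions.

    *excluded* entries may be full substance codes or class prefixes.  A
    keep-exception not under any excluded prefix is logged as a warning
    (it has no effect).
    """
    excluded = tuple(excluded)
    keep = frozenset(keep_exceptions)
    for code in keep:
        if not any(matches_prefix(code, pat) for pat in excluded):
            logger.warning(
                "keep-exception %s is not under any excluded prefix", code
            )
    remaining = frozenset(
        code
        for code in criterion_set.resolved_codes
        if code in keep or not any(matches_prefix(code, pat) for pat in excluded)
    )
    return CriterionSet(
        criterion_id=criterion_set.criterion_id,
        resolved_codes=remaining,
        provenance={
            c: criterion_set.provenance.get(c, ()) for c in sorted(remaining)
        },
    )


def sensitivity_prevalence(
    cohorts: Mapping[int, AnnualCohort],
    criterion_set: CriterionSet,
    census: Mapping[int, float],
    excluded: Iterable[str],
    keep_exceptions: Iterable[str] = (),
) -> pd.DataFrame:
    """Annual prevalence with selected codes/classes excluded.

    Re-screens the cohorts under the reduced code set; with nothing
    excluded this reproduces the original prevalence, and excluding codes
    can never increase it.
    """
    reduced = exclude_codes(criterion_set, excluded, keep_exceptions)
    return annual_prevalence(screen(cohorts, reduced), census)
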