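"""Prevalence, overlap, usage-proportion, top-N and sensitivity statistics."""

import numpy as np
import pandas as pd
import pytest

from pimscreen.criteria import CriterionSet
from pimscreen.register import build_cohorts, clean_records
from pimscreen.screening import ScreenResult, screen
from pimscreen.stats import (
    annual_prevalence,
    exclude_codes,
    overlap_vs_reference,
    round_pct,
    sensitivity_prevalence,
    top_n,
    usage_by_group,
)

from conftest import random_register


def result(cid="meds75", users_by_year=None, per_person=None, per_code=None):
    return ScreenResult(
        criterion_id=cid,
        users_by_year=users_by_year or {},
        per_person_codes=per_person or {},
        per_code_users=per_code or {},
    )


def test_rounding_is_half_up_to_one_decimal():
    assert round_pct(12.25) == 12.3  # banker's rounding would give 12.2
    assert round_pct(33.6048) == 33.6
    assert round_pct(99.95) == 100.0


def test_prevalence_arithmetic():
    res = result(users_by_year={2017: frozenset(f"p{i}" for i in range(30))})
    table = annual_prevalence(res, {2017: 100.0})
    assert table.loc[0, "prevalence_pct"] == 30.0


def test_prevalence_with_half_integer_census_denominator():
    # 1,683 users over a mean population of 5,008.205 -> 33.6%
    res = result(users_by_year={2017: frozenset(f"p{i}" for i in range(1683))})
    table = annual_prevalence(res, {2017: 5008.205})
    assert table.loc[0, "prevalence_pct"] == 33.6


def test_prevalence_zero_denominator_fatal():
    res = result(users_by_year={2017: frozenset({"a"})})
    with pytest.raises(ValueError):
        annual_prevalence(res, {2017: 0.0})


def test_overlap_identity_set_arithmetic_and_empty():
    assert overlap_vs_reference({"1", "2"}, {"1", "2"}) == 100.0
    assert overlap_vs_reference({"1", "2"}, {"2", "3", "4"}) == 33.3
    assert overlap_vs_reference({"1", "2"}, set()) is None


def test_overlap_is_asymmetric():
    a, b = {"1", "2"}, {"2", "3", "4"}
    assert overlap_vs_reference(a, b) != overlap_vs_reference(b, a)
    assert overlap_vs_reference(b, a) == 50.0


def test_usage_by_group_counts_distinct_users_over_fixed_denominator():
    res = result(per_code={"N05CD08": frozenset({"u1"})})
    table = usage_by_group({"meds75": res}, group_level=4, denominator=10)
    meds = table[table["criterion_id"] == "meds75"]
    assert list(meds["group"]) == ["N05C"]
    assert list(meds["proportion_pct"]) == [10.0]
    # criterion with no codes in a class contributes no row (blank cell)
    empty = result(cid="laroche")
    table2 = usage_by_group({"meds75": res, "laroche": empty}, 4, 10)
    assert "laroche" not in set(table2["criterion_id"])


def test_usage_by_group_rejects_bad_level():
    with pytest.raises(ValueError):
        usage_by_group({"meds75": result()}, group_level=2, denominator=10)


def test_top_n_ranks_by_users_then_code():
    res = result(per_code={
        "N06AA09": frozenset({"a", "b", "c", "d", "e"}),
        "N05BA01": frozenset({"a", "b", "c", "d", "f"}),  # tie: 5 users each
        "M01AE01": frozenset({"a"}),
    })
    table = top_n(res, denominator=10, n=2)
    assert list(table["atc_code"]) == ["N05BA01", "N06AA09"]  # tie by code
    assert list(table["proportion_pct"]) == [50.0, 50.0]


def test_top_n_single_substance_regardless_of_n():
    res = result(per_code={"N05BA01": frozenset({"a"})})
    assert list(top_n(res, 10, n=3)["atc_code"]) == ["N05BA01"]


# --- sensitivity ------------------------------------------------------------

CENSUS = {2017: 30.0, 2018: 30.0, 2019: 30.0}


def _cohorts(seed=3, codes=("A02BC02", "A02BC01", "N05BA01", "N06AA09")):
    rng = np.random.default_rng(seed)
    reg = random_register(rng, 200, list(codes))
    kept, _ = clean_records(reg)
    return build_cohorts(kept, CENSUS, set(codes))[0]


def test_exclusion_honours_prefixes_and_keep_exceptions(caplog):
    cs = CriterionSet("stopp", frozenset({"C03CA01", "N02AA59", "N02AA05"}))
    reduced = exclude_codes(cs, excluded=["C03C", "N02A"],
                            keep_exceptions=["N02AA59"])
    assert reduced.resolved_codes == {"N02AA59"}
    with caplog.at_level("WARNING"):
        exclude_codes(cs, excluded=["C03C"], keep_exceptions=["N05BA01"])
    assert "N05BA01" in caplog.text


def test_sensitivity_identity_and_total_exclusion():
    cohorts = _cohorts()
    cs = CriterionSet("beers", frozenset({"A02BC02", "A02BC01", "N05BA01"}))
    base = annual_prevalence(screen(cohorts, cs), CENSUS)
    same = sensitivity_prevalence(cohorts, cs, CENSUS, excluded=[])
    pd.testing.assert_frame_equal(base, same)
    zero = sensitivity_prevalence(cohorts, cs, CENSUS,
                                  excluded=sorted(cs.resolved_codes))
    assert (zero["prevalence_pct"] == 0.0).all()


def test_sensitivity_halves_prevalence_on_constructed_register():
    """Half the users use only PPIs; excluding the PPI class halves the
    numerator exactly."""
    rows = []
    for i in range(10):
        code = "A02BC02" if i < 5 else "N05BA01"
        rows.append((f"p{i}", "F", "1938-01-01", "2017-03-01", code, "tablet"))
    df = pd.DataFrame(rows, columns=["person_id", "sex", "birth_date",
                                     "purchase_date", "atc_code", "pharm_form"])
    cohorts, _ = build_cohorts(df, {2017: 20.0}, {"A02BC02", "N05BA01"})
    cs = CriterionSet("beers", frozenset({"A02BC02", "N05BA01"}))
    base = annual_prevalence(screen(cohorts, cs), {2017: 20.0})
    sens = sensitivity_prevalence(cohorts, cs, {2017: 20.0}, excluded=["A02BC"])
    assert base.loc[0, "prevalence_pct"] == 50.0
    assert sens.loc[0, "prevalence_pct"] == 25.0


@pytest.mark.parametrize("seed", range(5))
def test_prevalence_monotone_under_random_exclusions(seed):
    cohorts = _cohorts(seed=seed)
    codes = frozenset({"A02BC02", "A02BC01", "N05BA01", "N06AA09"})
    cs = CriterionSet("beers", codes)
    base = annual_prevalence(screen(cohorts, cs), CENSUS)
    rng = np.random.default_rng(1000 + seed)
    pool = sorted(codes) + ["A02BC", "N05B", "N06AA"]
    for _ in range(10):
        k = int(rng.integers(1, len(pool)))
        excl = list(rng.choice(pool, size=k, replace=False))
        sens = sensitivity_prevalence(cohorts, cs, CENSUS, excluded=excl)
        assert (sens["prevalence_pct"] <= base["prevalence_pct"]).all()


def test_union_prevalence_at_least_max_single(reference):
    _, _, sets = reference
    cohorts = _cohorts(seed=9)
    union = CriterionSet(
        "meds75", frozenset().union(*(s.resolved_codes for s in sets.values()))
    )
    union_prev = annual_prevalence(screen(cohorts, union), CENSUS)
    for cs in sets.values():
        single = annual_prevalence(
            screen(cohorts, CriterionSet("meds75", cs.resolved_codes)), CENSUS
        )
        assert (single["prevalence_pct"] <= union_prev["prevalence_pct"]).all()
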