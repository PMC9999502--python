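"""Criteria harmonization: statement filtering, class expansion, market
screening, resolution and cross-criteria consensus."""

import pytest
from hypothesis import given, settings, strategies as st

from pimscreen.criteria import (
    AvailabilityMode,
    CRITERION_IDS,
    FormularyEntry,
    PimStatement,
    Scope,
    StatementKind,
    consensus_count,
    expand_class_statement,
    filter_statements,
    group_statements,
    load_formulary_csv,
    load_statements_csv,
    resolve_all,
    resolve_criterion,
    screen_market,
    write_formulary_csv,
    write_statements_csv,
)

CODES = ["N05CD08", "N05CF01", "N06AA09", "M01AE01", "A02BC02", "N05BA01"]


def stmt(pattern, kind=StatementKind.PLAIN_AVOID, cid="stopp", sid="s1"):
    scope = Scope.SUBSTANCE if len(pattern) == 7 else Scope.DRUG_CLASS
    return PimStatement(cid, sid, pattern, scope, kind)


# --- statement validation ---------------------------------------------------

def test_statement_scope_must_match_pattern_length():
    with pytest.raises(ValueError):
        PimStatement("stopp", "s1", "N05C", Scope.SUBSTANCE,
                     StatementKind.PLAIN_AVOID)
    with pytest.raises(ValueError):
        PimStatement("stopp", "s1", "N05CD08", Scope.DRUG_CLASS,
                     StatementKind.PLAIN_AVOID)


def test_statement_rejects_unknown_criterion_and_bad_pattern():
    with pytest.raises(ValueError, match="unknown criterion"):
        PimStatement("bogus", "s1", "N05C", Scope.DRUG_CLASS,
                     StatementKind.PLAIN_AVOID)
    with pytest.raises(ValueError):
        stmt("N05CD8")  # non-canonical length rejected at load


# --- filtering --------------------------------------------------------------

def test_filter_drops_each_inadmissible_kind_with_its_reason():
    kinds_reasons = [
        (StatementKind.CONCURRENT_USE, "concurrent use"),
        (StatementKind.CONDITION_SPECIFIC, "condition-specific"),
        (StatementKind.DOSE_OR_DURATION_LIMITED, "dose/duration-limited"),
        (StatementKind.WEAK_EVIDENCE, "weak evidence"),
        (StatementKind.ANTICHOLINERGIC_UNSPECIFIED,
         "anticholinergic without specific substance"),
    ]
    statements = [stmt("N05BA01", sid="keep")]
    statements += [
        stmt("N05C", kind=k, sid=f"drop{i}") for i, (k, _) in enumerate(kinds_reasons)
    ]
    kept, dropped = filter_statements(statements)
    assert [s.statement_id for s in kept] == ["keep"]
    assert [d.reason for d in dropped] == [r for _, r in kinds_reasons]


def test_filter_empty_input():
    assert filter_statements([]) == ([], [])


@given(
    kinds=st.lists(st.sampled_from(list(StatementKind)), max_size=30)
)
def test_filter_partitions_input(kinds):
    statements = [stmt("N05C", kind=k, sid=f"s{i}") for i, k in enumerate(kinds)]
    kept, dropped = filter_statements(statements)
    assert len(kept) + len(dropped) == len(statements)
    recombined = {s.statement_id for s in kept} | {
        d.statement.statement_id for d in dropped
    }
    assert recombined == {s.statement_id for s in statements}
    assert all(s.statement_kind is StatementKind.PLAIN_AVOID for s in kept)


# --- class expansion --------------------------------------------------------

def test_expansion_worked_example_hypnotics():
    s = stmt("N05C", cid="norgep_nh")
    named = {"N05CD08", "N05CF01", "N06AA09"}
    assert expand_class_statement(s, named) == {"N05CD08", "N05CF01"}


def test_expansion_empty_universe_and_deeper_prefix():
    s = stmt("N05C")
    assert expand_class_statement(s, set()) == frozenset()
    s5 = stmt("N05CD")
    assert expand_class_statement(s5, {"N05CD08", "N05CF01"}) == {"N05CD08"}


def test_expansion_rejects_substance_scope():
    with pytest.raises(ValueError, match="substance scope"):
        expand_class_statement(stmt("N05CD08"), {"N05CD08"})


@given(
    universe=st.sets(
        st.from_regex(r"[AN]\d\d[A-C][A-C]\d\d", fullmatch=True), max_size=40
    ),
    pattern=st.sampled_from(["N", "N05", "N05C", "N05CA", "A02", "A02BC"]),
)
def test_expansion_equals_brute_force_prefix_scan(universe, pattern):
    s = stmt(pattern)
    result = expand_class_statement(s, universe)
    brute = {c for c in universe if c.startswith(pattern)}
    assert result == brute
    assert result <= universe


# --- market screening -------------------------------------------------------

FORM = [
    FormularyEntry("N02AA59", AvailabilityMode.COMBINATION_ONLY),
    FormularyEntry("N02AA05", AvailabilityMode.BOTH),
    FormularyEntry("N05BA01", AvailabilityMode.SINGLE_ONLY),
    FormularyEntry("A02BC02", AvailabilityMode.NONE),
]


def test_screen_keeps_combination_only_and_drops_unmarketed():
    kept = screen_market({"N02AA59", "N02AA05", "N05BA01", "A02BC02"}, FORM)
    assert kept == {"N02AA59", "N02AA05", "N05BA01"}


def test_screen_unlisted_code_treated_as_unmarketed(caplog):
    with caplog.at_level("WARNING"):
        assert screen_market({"J01XE01"}, FORM) == frozenset()
    assert "J01XE01" in caplog.text


@given(codes=st.sets(st.sampled_from([e.atc_code for e in FORM] + ["M01AE01"])))
def test_screen_idempotent_and_monotone(codes):
    once = screen_market(codes, FORM)
    assert screen_market(once, FORM) == once
    assert once <= codes
    # screening a subset yields a subset of the screened superset
    sub = set(list(codes)[: len(codes) // 2])
    assert screen_market(sub, FORM) <= once | screen_market(sub, FORM)
    assert screen_market(sub, FORM) <= screen_market(codes, FORM)


# --- resolution on the packaged reference -----------------------------------

def test_resolution_is_deterministic(reference):
    criteria, formulary, sets = reference
    again = resolve_all(criteria, formulary)
    for cid in sets:
        assert sets[cid].resolved_codes == again[cid].resolved_codes
        assert sets[cid].provenance == again[cid].provenance


def test_every_resolved_code_has_plain_avoid_provenance(reference):
    criteria, _, sets = reference
    kinds = {
        s.statement_id: s.statement_kind for c in criteria for s in c.statements
    }
    for cs in sets.values():
        for code in cs.resolved_codes:
            sids = cs.provenance[code]
            assert sids, f"{code} has no contributing statement"
            assert all(kinds[sid] is StatementKind.PLAIN_AVOID for sid in sids)


def test_class_statement_contributes_via_expansion(reference):
    """NORGEP-NH's hypnotics class statement must appear in the provenance
    of hypnotic codes the criterion does not name itself."""
    _, _, sets = reference
    norgep = sets["norgep_nh"]
    via_class = [
        code for code, sids in norgep.provenance.items()
        if code.startswith("N05C") and "norgep_nh-cls1" in sids
    ]
    assert via_class, "class expansion contributed nothing"


def test_criterion_with_only_dropped_statements_resolves_empty():
    s = PimStatement("laroche", "l1", "N", Scope.DRUG_CLASS,
                     StatementKind.ANTICHOLINERGIC_UNSPECIFIED)
    crit = group_statements([s])[0]
    cs = resolve_criterion(crit, [crit], FORM)
    assert cs.resolved_codes == frozenset()


def test_consensus_counts(reference):
    _, _, sets = reference
    assert consensus_count("N06AA09", sets.values()) == 9  # amitriptyline
    assert consensus_count("N05BB01", sets.values()) == 8  # hydroxyzine
    assert consensus_count("M01AB01", sets.values()) == 7  # indomethacin
    assert consensus_count("B01AA03", sets.values()) == 0  # never resolved


# --- CSV round trip ---------------------------------------------------------

def test_criteria_and_formulary_round_trip(tmp_path, reference):
    criteria, formulary, sets = reference
    cpath, fpath = tmp_path / "criteria.csv", tmp_path / "formulary.csv"
    write_statements_csv(cpath, criteria)
    write_formulary_csv(fpath, formulary)
    statements = load_statements_csv(cpath)
    assert statements == [s for c in criteria for s in c.statements]
    reloaded = group_statements(statements)
    sets2 = resolve_all(reloaded, load_formulary_csv(fpath))
    assert {c: s.resolved_codes for c, s in sets.items()} == {
        c: s.resolved_codes for c, s in sets2.items()
    }
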