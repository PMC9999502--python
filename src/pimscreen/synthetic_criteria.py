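"""Synthetic nine-criteria PIM summary and national formulary.

The real harmonized summary of the nine explicit criteria (Meds75+, Beers,
EU(7)-PIM, the Swedish indicators, Laroche, NORGEP-NH, PRISCUS,
Red-Yellow-Green, STOPP) and the Finnish market screen live in
access-restricted source material.  This module constructs a SYNTHETIC
stand-in with the same published structure, so the whole pipeline can be
exercised and its counting logic verified end to end:

* 352 distinct substance codes in the harmonized summary before the market
  screen, 172 after it;
* per-criterion resolved-set sizes 91 (Meds75+), 79 (Beers), 128 (EU(7)),
  28 (Swedish), 38 (Laroche), 29 (NORGEP-NH), 35 (PRISCUS), 38
  (Red-Yellow-Green) and 65 (STOPP);
* exactly three substances (amitriptyline, clomipramine, diazepam) listed
  by all nine criteria; hydroxyzine, levomepromazine and nitrazepam by
  eight; indomethacin, nortriptyline, solifenacin, tolterodine and
  trimipramine by seven; no other substance reaches seven;
* the class-membership pattern of the major PIM classes (PPIs in two
  criteria, loop diuretics only in STOPP, opioids in five, NSAIDs in seven,
  hypnotics/anxiolytics in all nine, antipsychotics in eight);
* one genuine class-level statement — the NORGEP-NH hypnotics statement
  (N05C) — resolved by expansion against substances named in the other
  criteria, plus the inadmissible statement kinds each criterion
  realistically carries (concurrent-use, condition-specific,
  dose/duration-limited, weak-evidence, unspecified-anticholinergic);
* codeine marketed only in combination products, oxycodone both as a
  single substance and in combination.

Anchor substances carry their real ATC codes; memberships the published
tables do not pin down are filled by a deterministic greedy allocator, and
filler substances are synthetic codes inside plausible ATC classes.  The
construction is pure and seedless: repeated calls are identical.
"""

from __future__ import annotations

from functools import lru_cache

from .criteria import (
    AvailabilityMode,
    Criterion,
    CRITERION_IDS,
    FormularyEntry,
    PimStatement,
    Scope,
    StatementKind,
)

ALL = frozenset(CRITERION_IDS)

#: (full name, country, age threshold, section used as PIM)
CRITERIA_META: dict[str, tuple[str, str, int, str]] = {
    "meds75": ("Meds75+ database", "Finland", 75, "category D: avoid use in older persons"),
    "beers": ("Beers criteria", "USA", 65, "potentially inappropriate in most older adults"),
    "eu7": ("EU(7)-PIM list", "seven European countries", 65, "full PIM list"),
    "swedish": (
        "Indicators for Quality of Drug Therapy in the elderly",
        "Sweden", 75, "medicines that should be avoided unless there is a special reason",
    ),
    "laroche": ("Laroche criteria", "France", 75, "full PIM list"),
    "norgep_nh": ("NORGEP-NH", "Norway", 70, "part A: regular use should be avoided"),
    "priscus": ("PRISCUS list", "Germany", 65, "full PIM list"),
    "ryg": ("Red-Yellow-Green list", "Denmark", 65, "red category: should not be used"),
    "stopp": ("STOPP(/START)", "Ireland", 65, "STOPP statements, applied partially"),
}

#: Resolved-set size per criterion after the market screen.
RESOLVED_SIZE_TARGET: dict[str, int] = {
    "meds75": 91,
    "beers": 79,
    "eu7": 128,
    "swedish": 28,
    "laroche": 38,
    "norgep_nh": 29,
    "priscus": 35,
    "ryg": 38,
    "stopp": 65,
}

PRE_SCREEN_TOTAL = 352
POST_SCREEN_TOTAL = 172

#: Substance names for the anchor codes (display only).
SUBSTANCE_NAMES: dict[str, str] = {
    "N06AA09": "amitriptyline",
    "N06AA04": "clomipramine",
    "N05BA01": "diazepam",
    "N05BB01": "hydroxyzine",
    "N05AA02": "levomepromazine",
    "N05CD02": "nitrazepam",
    "M01AB01": "indomethacin",
    "N06AA10": "nortriptyline",
    "G04BD08": "solifenacin",
    "G04BD07": "tolterodine",
    "N06AA06": "trimipramine",
    "A02BC01": "omeprazole",
    "A02BC02": "pantoprazole",
    "A02BC03": "lansoprazole",
    "A02BC04": "rabeprazole",
    "A02BC05": "esomeprazole",
    "C03CA01": "furosemide",
    "C03CA02": "bumetanide",
    "N02AA59": "codeine, combinations",
    "N02AA05": "oxycodone",
    "N02AX02": "tramadol",
    "N02AA01": "morphine",
    "N02AB03": "fentanyl",
    "N02AE01": "buprenorphine",
    "N02AB02": "pethidine",
    "N02AA03": "hydromorphone",
    "M01AE01": "ibuprofen",
    "M01AH05": "etoricoxib",
    "M01AE02": "naproxen",
    "M01AE03": "ketoprofen",
    "M01AB05": "diclofenac",
    "M01AC01": "piroxicam",
    "M01AC06": "meloxicam",
    "M01AH01": "celecoxib",
    "M01AB15": "ketorolac",
    "N05CD07": "temazepam",
    "N05CF01": "zopiclone",
    "N05CF02": "zolpidem",
    "N05CD08": "midazolam",
    "N05CD05": "triazolam",
    "N05CD03": "flunitrazepam",
    "N05CF03": "zaleplon",
    "N05CD01": "flurazepam",
    "N05CD04": "estazolam",
    "N05CM02": "clomethiazole",
    "N05CA01": "pentobarbital",
    "N05BA04": "oxazepam",
    "N05BA06": "lorazepam",
    "N05BA12": "alprazolam",
    "N05BA02": "chlordiazepoxide",
    "N05BA09": "clobazam",
    "N05BA03": "medazepam",
    "N05BE01": "buspirone",
    "N05BC01": "meprobamate",
    "N05AH04": "quetiapine",
    "N05AD01": "haloperidol",
    "N05AH03": "olanzapine",
    "N05AX08": "risperidone",
    "N05AA01": "chlorpromazine",
    "N05AD03": "melperone",
    "N05AF03": "chlorprothixene",
    "N05AA03": "promazine",
    "N05AF01": "flupentixol",
    "N06AA12": "doxepin",
    "N06AA02": "imipramine",
    "N06AA21": "maprotiline",
    "N06AA05": "opipramol",
    "G04BD04": "oxybutynin",
    "G04BD09": "trospium",
    "G04BD10": "darifenacin",
    "G04BD11": "fesoterodine",
    "J01XE01": "nitrofurantoin",
}

_NSAID = ALL - {"laroche", "stopp"}       # M01A blank for Laroche and STOPP
_OPIOID = frozenset({"meds75", "eu7", "swedish", "norgep_nh", "stopp"})  # N02A 5/9
_ANTIPSYCH = ALL - {"swedish"}            # N05A 8/9
_NORGEP = frozenset({"norgep_nh"})

# (code, required memberships, allowed memberships).  Codes where
# required == allowed are fixed; the allocator may top up the rest to at
# most six criteria, so no unnamed substance can reach a 7/9 consensus.
_MARKETED_SPEC: list[tuple[str, frozenset, frozenset]] = [
    # consensus anchors (fixed)
    ("N06AA09", ALL, ALL),
    ("N06AA04", ALL, ALL),
    ("N05BA01", ALL, ALL),
    ("N05BB01", ALL - {"laroche"}, ALL - {"laroche"}),
    ("N05AA02", ALL - {"swedish"}, ALL - {"swedish"}),
    ("N05CD02", ALL - {"beers"}, ALL - {"beers"}),
    ("M01AB01", _NSAID, _NSAID),
    ("N06AA10", ALL - {"swedish", "ryg"}, ALL - {"swedish", "ryg"}),
    ("G04BD08", ALL - {"laroche", "ryg"}, ALL - {"laroche", "ryg"}),
    ("G04BD07", ALL - {"beers", "priscus"}, ALL - {"beers", "priscus"}),
    ("N06AA06", ALL - {"swedish", "priscus"}, ALL - {"swedish", "priscus"}),
    # proton pump inhibitors: a Beers class, one substance also in Meds75+
    ("A02BC01", frozenset({"beers", "meds75"}), frozenset({"beers", "meds75"})),
    ("A02BC02", frozenset({"beers"}), frozenset({"beers"})),
    ("A02BC03", frozenset({"beers"}), frozenset({"beers"})),
    ("A02BC04", frozenset({"beers"}), frozenset({"beers"})),
    ("A02BC05", frozenset({"beers"}), frozenset({"beers"})),
    # loop diuretics: STOPP only
    ("C03CA01", frozenset({"stopp"}), frozenset({"stopp"})),
    ("C03CA02", frozenset({"stopp"}), frozenset({"stopp"})),
    # opioids
    ("N02AA59", _OPIOID, _OPIOID),
    ("N02AA05", frozenset({"stopp"}), _OPIOID),
    ("N02AX02", frozenset({"meds75", "eu7", "swedish"}), _OPIOID),
    ("N02AA01", frozenset(), _OPIOID),
    ("N02AB03", frozenset(), _OPIOID),
    ("N02AE01", frozenset(), _OPIOID),
    ("N02AB02", frozenset(), _OPIOID),
    ("N02AA03", frozenset(), _OPIOID),
    # NSAIDs
    ("M01AE01", frozenset({"beers", "norgep_nh", "ryg"}), _NSAID),
    ("M01AH05", frozenset({"eu7", "priscus", "ryg"}), _NSAID),
    ("M01AE02", frozenset(), _NSAID),
    ("M01AE03", frozenset(), _NSAID),
    ("M01AB05", frozenset(), _NSAID),
    ("M01AC01", frozenset(), _NSAID),
    ("M01AC06", frozenset(), _NSAID),
    ("M01AH01", frozenset(), _NSAID),
    ("M01AB15", frozenset(), _NSAID),
    # hypnotics and sedatives: NORGEP-NH covers the whole class via its
    # class statement, so every marketed N05C code requires norgep_nh
    ("N05CD07", frozenset({"norgep_nh", "eu7", "priscus"}), ALL),
    ("N05CF01", frozenset({"norgep_nh", "stopp"}), ALL),
    ("N05CF02", _NORGEP, ALL),
    ("N05CD08", _NORGEP, ALL),
    ("N05CD05", _NORGEP, ALL),
    ("N05CD03", _NORGEP, ALL),
    ("N05CF03", _NORGEP, ALL),
    ("N05CD01", _NORGEP, ALL),
    ("N05CD04", _NORGEP, ALL),
    ("N05CM02", _NORGEP, ALL),
    ("N05CA01", _NORGEP, ALL),
    # anxiolytics
    ("N05BA04", frozenset({"beers"}), ALL),
    ("N05BA06", frozenset(), ALL),
    ("N05BA12", frozenset(), ALL),
    ("N05BA02", frozenset(), ALL),
    ("N05BA09", frozenset(), ALL),
    ("N05BA03", frozenset(), ALL),
    ("N05BE01", frozenset(), ALL),
    ("N05BC01", frozenset(), ALL),
    # antipsychotics (Swedish criteria carry none)
    ("N05AH04", frozenset({"ryg"}), _ANTIPSYCH),
    ("N05AD01", frozenset(), _ANTIPSYCH),
    ("N05AH03", frozenset(), _ANTIPSYCH),
    ("N05AX08", frozenset(), _ANTIPSYCH),
    ("N05AA01", frozenset(), _ANTIPSYCH),
    ("N05AD03", frozenset(), _ANTIPSYCH),
    ("N05AF03", frozenset(), _ANTIPSYCH),
    ("N05AA03", frozenset(), _ANTIPSYCH),
    ("N05AF01", frozenset(), _ANTIPSYCH),
    # tricyclic antidepressants
    ("N06AA12", frozenset(), ALL),
    ("N06AA02", frozenset(), ALL),
    ("N06AA21", frozenset(), ALL),
    ("N06AA05", frozenset(), ALL),
    # urinary antispasmodics
    ("G04BD04", frozenset(), ALL),
    ("G04BD09", frozenset(), ALL),
    ("G04BD10", frozenset(), ALL),
    ("G04BD11", frozenset(), ALL),
    # nitrofurantoin: a top substance of Meds75+, Laroche and PRISCUS
    ("J01XE01", frozenset({"meds75", "laroche", "priscus"}), ALL),
]

# Synthetic filler substances (class, count).  Classes are plausible PIM
# territory (sedating antihistamines, anticholinergics, muscle relaxants,
# class-Ia antiarrhythmics, sulfonylureas, ...) but deliberately avoid the
# anchor classes above so the published class-membership pattern holds.
_FILLER_CLASSES: list[tuple[str, int]] = [
    ("R06AA", 4), ("R06AB", 4), ("R06AD", 4), ("R06AE", 4),
    ("N04AA", 4), ("A03AB", 4), ("A03BA", 3), ("A03BB", 2),
    ("M03BX", 4), ("M03BA", 3), ("C01BA", 3), ("N02CA", 3),
    ("C04AD", 3), ("C04AE", 3), ("G03CA", 3), ("A10BB", 3),
    ("C02AB", 3), ("C02CA", 3), ("N06AB", 3), ("R03DA", 3),
    ("N03AE", 2), ("R05DA", 3), ("A04AD", 3), ("N07CA", 3),
    ("G04CA", 3), ("C01AA", 2), ("R01BA", 3), ("A06AB", 3),
    ("C03BA", 3), ("M04AA", 3), ("C07AA", 3), ("A07DA", 3),
]

# Substances in the summary but not marketed nationally (screened out).
# Mostly contributed by the large international lists.  Meds75+ contributes
# none: it is built from the national market to begin with.
_UNMARKETED_CLASSES: list[str] = [
    "A02BA", "A03AA", "C01BB", "C02AA", "C04AC", "G03CB", "G04CB",
    "J01XX", "M01AG", "M02AA", "N02AC", "N04BA", "N05AC", "N06AX",
    "N07AA", "R01AB", "R06AX", "S01EA", "A07AA", "D04AA",
]
_UNMARKETED_ASSIGNMENT_CYCLE: list[frozenset] = [
    frozenset({"eu7"}),
    frozenset({"eu7", "priscus"}),
    frozenset({"eu7"}),
    frozenset({"eu7", "beers"}),
    frozenset({"stopp"}),
    frozenset({"eu7", "stopp"}),
    frozenset({"priscus"}),
    frozenset({"eu7"}),
    frozenset({"beers"}),
    frozenset({"eu7", "ryg"}),
    frozenset({"laroche"}),
    frozenset({"eu7"}),
]

_AUGMENT_CAP = 6  # keeps allocator-made memberships below 7/9 consensus


def _filler_codes() -> list[str]:
    return [
        f"{prefix}{i:02d}"
        for prefix, n in _FILLER_CLASSES
        for i in range(1, n + 1)
    ]


def _unmarketed_codes() -> list[str]:
    # three hypnotics named by EU(7) but unmarketed: they enter the
    # NORGEP-NH class expansion and are then screened out
    codes = ["N05CD91", "N05CD92", "N05CD93"]
    per_class, extra = divmod(PRE_SCREEN_TOTAL - POST_SCREEN_TOTAL - len(codes),
                              len(_UNMARKETED_CLASSES))
    for idx, prefix in enumerate(_UNMARKETED_CLASSES):
        n = per_class + (1 if idx < extra else 0)
        codes.extend(f"{prefix}{i + 90:02d}" for i in range(n))
    return codes


def _allocate_memberships() -> dict[str, frozenset]:
    """Fill in marketed-code memberships to hit the per-criterion targets.

    Required memberships are applied first; remaining per-criterion deficits
    are filled greedily (largest deficit first, spreading across codes with
    the fewest memberships), respecting each code's allowed set and the
    six-criteria cap on allocator-made memberships.
    """
    specs = _MARKETED_SPEC + [
        (code, frozenset(), ALL) for code in _filler_codes()
    ]
    members: dict[str, set] = {code: set(req) for code, req, _ in specs}
    allowed: dict[str, frozenset] = {code: alw for code, _, alw in specs}
    fixed = {code for code, req, alw in specs if req == alw}

    deficit = dict(RESOLVED_SIZE_TARGET)
    for code in members:
        for cid in members[code]:
            deficit[cid] -= 1
    if any(v < 0 for v in deficit.values()):
        raise RuntimeError(f"required memberships overshoot targets: {deficit}")

    def cap(code: str) -> int:
        return len(allowed[code]) if code in fixed else min(_AUGMENT_CAP,
                                                            len(allowed[code]))

    # every substance must be listed by at least one criterion
    for code, _, _ in specs:
        if members[code]:
            continue
        options = sorted(
            (c for c in allowed[code] if deficit[c] > 0),
            key=lambda c: (-deficit[c], c),
        )
        if not options:
            raise RuntimeError(f"no criterion left for {code}")
        members[code].add(options[0])
        deficit[options[0]] -= 1

    order = [code for code, _, _ in specs]
    while any(v > 0 for v in deficit.values()):
        cid = max(sorted(deficit), key=lambda c: deficit[c])
        candidates = [
            code for code in order
            if code not in fixed
            and cid in allowed[code]
            and cid not in members[code]
            and len(members[code]) < cap(code)
        ]
        if not candidates:
            raise RuntimeError(f"cannot place remaining {deficit[cid]} codes "
                               f"for criterion {cid}")
        code = min(candidates, key=lambda c: (len(members[c]), c))
        members[code].add(cid)
        deficit[cid] -= 1

    return {code: frozenset(m) for code, m in members.items()}


def _inadmissible_statements() -> list[PimStatement]:
    """Statements each criterion carries that register data cannot evaluate."""
    K = StatementKind
    rows = [
        ("stopp", "B01AA03", Scope.SUBSTANCE, K.CONCURRENT_USE,
         "warfarin combined with NSAIDs"),
        ("laroche", "N", Scope.DRUG_CLASS, K.ANTICHOLINERGIC_UNSPECIFIED,
         "concomitant use of anticholinergic drugs, no substance named"),
        ("beers", "C01AA05", Scope.SUBSTANCE, K.DOSE_OR_DURATION_LIMITED,
         "digoxin above 0.125 mg/day"),
        ("stopp", "A02BC", Scope.DRUG_CLASS, K.DOSE_OR_DURATION_LIMITED,
         "PPI at full dose beyond 8 weeks"),
        ("beers", "C09CA", Scope.DRUG_CLASS, K.CONDITION_SPECIFIC,
         "angiotensin receptor blockers in hyperkalaemia"),
        ("norgep_nh", "N05", Scope.DRUG_CLASS, K.CONCURRENT_USE,
         "three or more concurrent psychotropics"),
        ("ryg", "N03AE92", Scope.SUBSTANCE, K.CONDITION_SPECIFIC,
         "in fall-prone patients only"),
        ("priscus", "N05BA91", Scope.SUBSTANCE, K.DOSE_OR_DURATION_LIMITED,
         "above a daily-dose threshold"),
        ("meds75", "N06AX91", Scope.SUBSTANCE, K.WEAK_EVIDENCE,
         "category B: evidence in older persons is vague"),
    ]
    # seven EU(7) statements misinterpreted as conditional and excluded from
    # data collection; synthetic placeholders, identities not public
    rows += [
        ("eu7", f"V03AB{i:02d}", Scope.SUBSTANCE, K.CONDITION_SPECIFIC,
         "synthetic stand-in: misinterpreted as condition-dependent, "
         "excluded from data collection")
        for i in range(1, 8)
    ]
    return [
        PimStatement(cid, f"{cid}-x{i:02d}", pattern, scope, kind, note)
        for i, (cid, pattern, scope, kind, note) in enumerate(rows, 1)
    ]


@lru_cache(maxsize=1)
def reference_memberships() -> dict[str, frozenset]:
    """Marketed substance code -> criteria listing it (ground truth)."""
    return _allocate_memberships()


@lru_cache(maxsize=1)
def reference_criteria() -> tuple[tuple[Criterion, ...], tuple[FormularyEntry, ...]]:
    """Build the synthetic nine criteria and the national formulary."""
    members = reference_memberships()
    unmarketed = _unmarketed_codes()

    statements: dict[str, list[PimStatement]] = {cid: [] for cid in CRITERION_IDS}

    # NORGEP-NH hypnotics: covered by its class statement; the criterion
    # names an N05C substance itself only when no other criterion does.
    norgep_class = PimStatement(
        "norgep_nh", "norgep_nh-cls1", "N05C", Scope.DRUG_CLASS,
        StatementKind.PLAIN_AVOID, "regular use of hypnotics and sedatives",
    )

    for code in sorted(members):
        for cid in sorted(members[code]):
            if (cid == "norgep_nh" and code.startswith("N05C")
                    and members[code] != frozenset({"norgep_nh"})):
                continue  # reaches NORGEP-NH via the class statement
            statements[cid].append(
                PimStatement(
                    cid, "", code, Scope.SUBSTANCE, StatementKind.PLAIN_AVOID,
                    SUBSTANCE_NAMES.get(code, ""),
                )
            )
    statements["norgep_nh"].append(norgep_class)

    for idx, code in enumerate(unmarketed):
        for cid in sorted(_UNMARKETED_ASSIGNMENT_CYCLE[idx % len(_UNMARKETED_ASSIGNMENT_CYCLE)]):
            statements[cid].append(
                PimStatement(cid, "", code, Scope.SUBSTANCE,
                             StatementKind.PLAIN_AVOID,
                             "not marketed nationally")
            )

    for s in _inadmissible_statements():
        statements[s.criterion_id].append(s)

    criteria = []
    for cid in CRITERION_IDS:
        numbered = tuple(
            PimStatement(
                s.criterion_id,
                s.statement_id or f"{cid}-{i:03d}",
                s.atc_pattern, s.scope, s.statement_kind, s.note,
            )
            for i, s in enumerate(statements[cid], 1)
        )
        name, country, age, section = CRITERIA_META[cid]
        criteria.append(Criterion(cid, name, country, age, numbered, section))

    formulary = [
        FormularyEntry("N02AA59", AvailabilityMode.COMBINATION_ONLY),
        FormularyEntry("N02AA05", AvailabilityMode.BOTH),
    ]
    special = {e.atc_code for e in formulary}
    formulary += [
        FormularyEntry(code, AvailabilityMode.SINGLE_ONLY)
        for code in sorted(members)
        if code not in special
    ]
    formulary += [
        FormularyEntry(code, AvailabilityMode.NONE) for code in unmarketed
    ]
    return tuple(criteria), tuple(formulary)
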