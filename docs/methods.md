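# Methods

## The screening model

`pimscreen` treats PIM screening as three composable maps:

1. **Criteria → code sets.** An explicit criterion is a list of
   avoid-statements, each scoped to an ATC pattern (a full 7-character
   substance code, or a class prefix at one of the canonical lengths 1, 3,
   4, 5). Only *plain avoid* statements are admissible for register-based
   screening; the other five kinds — concurrent use, condition-specific,
   dose/duration-limited, weak evidence, and unnamed anticholinergics —
   require clinical context a dispensing register lacks, and are dropped
   with a recorded reason. Class statements are expanded against the
   *named-substance universe*: all substance codes named by an admissible
   statement of any of the harmonized criteria. (Whether the universe
   should exclude the statement's own criterion is ambiguous; we include
   it, which is harmless because a self-named substance is in the set
   already.) The expanded summary is then screened against a national
   formulary: `single_only`, `combination_only` and `both` availability all
   count as marketed (the codeine rule: a substance marketed only inside
   combination products still counts), `none` is removed, and codes absent
   from the formulary are treated as unmarketed with a warning rather than
   an error — the screen exists precisely to remove such codes.

2. **Register → cohorts.** Records are split into closed calendar years; a
   record is retained iff the person is at least `age_floor` (default 75)
   years old on the purchase date, sex is recorded, the ATC code is in the
   harmonized summary, and the pharmaceutical form is not blocklisted
   (default blocklist: "topical estrogen", matched case-insensitively as an
   exact label). Age is birthday-exact completed years — a person turns
   *k* on the *k*-th anniversary of their birth date; registers carrying
   only a birth year are not supported. Filters are applied in a fixed
   order (age, sex, code, form) so each rejected record carries exactly one
   reason and rejected + retained always equals the input row count.

3. **Cohorts × code set → statistics.** A person is a user of criterion
   *c* in year *y* iff they have ≥ 1 retained purchase of a resolved code
   that year. Annual prevalence divides the user count by the year's mean
   population from the census table (values may be half-integers, means of
   two time points; they are used as-is). Overlap with a reference
   criterion divides the pooled intersection by the other criterion's
   pooled user count — deliberately asymmetric, and reported as missing
   when the other criterion has no users. Distinct-PIM-per-person counts
   pool codes over the whole observation window (matching the single
   "PIMs per person" presentation of multi-year comparisons); annual user
   sets remain available per year. Class-level and top-N proportions use
   one fixed denominator, the pooled all-criteria PIM-user count, so
   percentages are comparable across criteria; a criterion with no
   resolved codes in a class yields no row (a blank, not 0.0). Top-N ties
   are broken by ascending ATC code.

## The synthetic criteria summary

The harmonized summary of nine real criteria lives in access-restricted
source material, so the package constructs a synthetic stand-in
(`pimscreen.synthetic_criteria`) with the same published structure: 352
distinct codes before market screening, 172 after; resolved sizes per
criterion of 91 (Meds75+), 79 (Beers), 128 (EU(7)), 28 (Swedish), 38
(Laroche), 29 (NORGEP-NH), 35 (PRISCUS), 38 (Red-Yellow-Green), 65 (STOPP);
exactly three substances (amitriptyline, clomipramine, diazepam) in all
nine criteria, three at 8/9 and five at 7/9; the class-membership pattern
of the major classes (PPIs in 2/9 criteria, loop diuretics only in STOPP,
opioids in 5/9, NSAIDs in 7/9 excluding Laroche and STOPP, hypnotics and
anxiolytics in 9/9, antipsychotics in 8/9); and one genuine class
statement, NORGEP-NH's hypnotics rule (`N05C`), resolved by expansion.
Anchor substances carry their real ATC codes. Memberships the published
tables do not pin down — including which single criterion omits each 8/9
substance — are filled by a deterministic greedy allocator that caps
allocator-made memberships at six criteria, so no filler substance can
reach a 7/9 consensus. Seven deliberately synthetic EU(7) statements are
flagged condition-specific to reproduce the operational exclusion of
misinterpreted entries. The construction is pure and seedless: repeated
calls are bit-identical. It reproduces the *structure* of the real
summary, not its exact rows; tests passing on it validate the counting
machinery, not the clinical content of any criterion.

## The register generator

`SimConfig` defaults encode a realistic 75+ national cohort: mean age 82.6
years, SD 5.7, 61.8 % female, study years 2017–2019. Ages are drawn from a
normal distribution truncated to [75, 105]; because truncation at the age
floor pulls the mean upward, the location parameter is calibrated (Brent
root-finding) so the *realized* mean equals the configured one — the
configured value is a population mean, not a parent-distribution
parameter. The scale parameter is the pre-truncation SD; the realized SD
is somewhat smaller (≈ 4.8 at the defaults). Birth dates are placed so
that completed-years age at the study start is exact.

Per person, year and drug, a Bernoulli draw with the configured annual
probability decides use; users receive a geometric number of purchases
(mean 3, the scale of repeat dispensings for maintenance medication) at
uniform dates within the year. Drug use is independent across drugs and
years — no polypharmacy correlation, persistence or seasonality. This is a
deliberate simplification: every downstream statistic is a counting
statistic over *distinct* person-year-code facts, insensitive to
correlation structure and within-year timing. Tests passing on synthetic
registers therefore validate cohort construction and counting logic, not
behavioural realism of prescribing.

Noise is injected so that it is exactly accountable: under-age persons
(the `underage_rate` fraction) are young enough to stay below the age floor
through the last study year, and row corruptions (blank sex, blocklisted
form) are applied to disjoint row subsets of eligible persons' records.
Every injected noise row is therefore rejected for exactly its own reason,
and rejection-log totals equal injected counts as an identity, not
approximately. A ground-truth table records every generated
person-year-drug exposure, so noise-free pipeline output can be checked by
set equality. All generation flows from a single `numpy` Generator seeded
by the config; identical configs give bit-identical outputs.

## Numerical and design choices

- Percentages are computed in full precision and rendered to one decimal
  with half-up rounding (`decimal`), matching how epidemiological tables
  are printed; bankers' rounding would differ on exact .x5 boundaries.
- ATC matching is positional string-prefix matching at the five canonical
  lengths only; patterns of other lengths are rejected at load.
- All outputs are sorted by (year, criterion, person/code) so repeated
  runs are byte-identical; screening itself is order-invariant.
- Sensitivity exclusions are prefix-based with keep-exceptions (e.g.
  exclude `N02A`, keep codeine's combination code); a keep-exception not
  under any excluded prefix is a warning, not an error. Exclusion is
  applied to the resolved set, then the cohorts are re-screened, which
  makes prevalence monotone non-increasing under exclusion by
  construction — the property the sensitivity analyses rely on.
- Degenerate inputs: an empty criterion set screens to zero users per year
  rather than erroring; a per-user distribution over zero users returns an
  empty summary; a zero census denominator is fatal; a cohort year missing
  from the census is fatal and names the year.
- The pipeline writes each table as CSV and renders the Markdown report
  from the CSVs alone, so every reported number is traceable to a CSV
  cell.

## Problem sizes

The test suite exercises the oracle-equivalence check on 100 random
registers of ≤ 200 rows against a pure-Python per-person scan, parameter
recovery on 5,000-person registers (10 seeds × 3 probabilities, within 3
binomial standard errors), monotonicity on 50 random exclusion sets, and
determinism byte-for-byte on repeated pipeline runs. The acceptance script
repeats these measurements at the same sizes. These sizes are chosen as the
smallest at which the checks are statistically meaningful; all statistics
scale linearly in register rows.

## Known limitations

- The synthetic criteria summary validates counting machinery only; its
  filler substances and the unpinned membership choices are not clinical
  statements about any real drug.
- Only plain avoid-statements are evaluated; the dropped statement kinds
  (interactions, conditions, dose/duration) genuinely reduce measured
  prevalence for criteria that rely on them heavily.
- No confidence intervals or significance tests are produced, matching the
  descriptive register-study setting the package targets.
- OTC purchases, reimbursement status, institutional care and geographic
  stratification are out of scope.
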