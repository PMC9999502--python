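# pimscreen

Screening prescription-purchase registers for **potentially inappropriate
medications (PIMs)** in older people, against explicit, ATC-coded criteria.

Explicit PIM criteria — national avoid-lists such as the Finnish Meds75+
database (category D), the Beers criteria, STOPP, the Laroche list, the
EU(7)-PIM list, NORGEP-NH, PRISCUS, the Swedish quality indicators and the
Danish Red-Yellow-Green list — name drugs whose risks generally outweigh
their benefits in people aged 65–75 and over. Because each list is written
for its own market and in its own vocabulary, comparing them on register
data requires harmonizing them into a common currency: sets of 7-character
WHO ATC substance codes. `pimscreen` implements that harmonization and the
drug-utilization statistics built on it, for pharmacoepidemiologists who
work with dispensing registers.

## What the package computes

**Harmonization.** Each criterion is a list of avoid-statements. Statements
that cannot be evaluated from dispensing data alone are dropped with a
recorded reason (concurrent-use rules, condition-specific rules,
dose/duration limits, weak-evidence flags, and "anticholinergics" without a
named substance). Class-level statements (e.g. *avoid hypnotics*, ATC
`N05C`) are expanded to the individual substances named anywhere across the
harmonized criteria. Finally the summary is screened against a national
formulary: substances marketed only in combination products (codeine) are
kept, substances not marketed at all are removed. The result per criterion
*c* is a concrete code set **R_c**.

**Screening.** From a register of purchases, annual cohorts retain records
where the person is ≥ 75 years old on the purchase date (birthday-exact),
sex is recorded, the ATC code is in the harmonized summary and the
pharmaceutical form is valid. A person is a *PIM user* under criterion *c*
in year *y* iff they have ≥ 1 retained purchase of a code in R_c during
*y*.

**Statistics.** Annual prevalence is
`100 · |users(c, y)| / N_y`, with `N_y` the mean population of year *y*
from a census table. Overlap of criterion *c* with a reference *r* is
`100 · |U_r ∩ U_c| / |U_c|` on pooled multi-year user sets (asymmetric).
Per-person PIM counts are distinct ATC codes pooled over the observation
period, regardless of purchase multiplicity. Class-level and top-N
substance proportions use one fixed denominator: persons flagged by *any*
criterion. Sensitivity re-analyses re-screen after removing code prefixes
(with keep-exceptions, e.g. *all opioids except codeine*), which can never
increase prevalence.

**Synthetic data.** Real national dispensing registers are
access-restricted, so the package ships (a) a deterministic *synthetic*
nine-criteria summary and formulary with the same published structure as a
real national comparison (352 ATC codes pre-screen, 172 marketed, resolved
sizes 91/79/128/28/38/29/35/38/65, three substances listed by all nine
criteria), and (b) a register generator with configurable age/sex structure
(defaults: mean age 82.6 ± 5.7 years, 61.8 % female), per-drug annual use
probabilities, and noise records with exact ground truth.

## Worked example

```sh
python examples/03_screen_and_prevalence.py
```

simulates 3,000 persons over 2017–2019 with realistic use probabilities for
eight common PIMs, screens them against all nine criteria and prints:

```
criterion   prev2017  prev2018  prev2019  overlap_vs_meds75
meds75         27.2      27.8      27.6      -
beers          40.7      41.5      40.6   62.6
eu7            23.2      24.2      24.4  100.0
swedish        30.2      31.5      31.7   85.4
laroche         8.9       8.3       8.1  100.0
norgep_nh      34.6      36.2      36.4   73.8
priscus         8.9       8.3       8.1  100.0
ryg            15.6      15.7      15.9   69.2
stopp          44.7      44.9      46.3   67.8

persons with >=1 PIM under any criterion: 2907
meds75 distinct PIMs per user: 1-4 (median 1, 30.4% with >=2)

top 3 PIMs under the STOPP criteria (share of all PIM users):
criterion_id  rank atc_code  users  proportion_pct
       stopp     1  C03CA01   1758            60.5
       stopp     2  N02AA59   1194            41.1
       stopp     3  N05CF01    783            26.9
```

Each row is one criterion's annual prevalence of PIM use (% of the census
population with ≥ 1 PIM purchase that year) and, for the comparators, the
share of their PIM users also flagged by the national reference criterion.
Prevalence varies several-fold across criteria because each emphasizes
different drug classes — here STOPP is driven by furosemide (`C03CA01`),
which no other criterion lists. The other examples cover criteria
harmonization (`01`), register simulation and noise accounting (`02`) and
sensitivity re-analysis with drug classes excluded (`04`).

A command-line interface mirrors the pipeline stages:

```sh
pimscreen simulate --config sim.yaml --out data/
pimscreen resolve-criteria --out resolved/
pimscreen run --config run.yaml     # register -> tables -> report.md
```

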