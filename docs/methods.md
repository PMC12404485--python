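# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports in the FAERS
quarterly ASCII dialect: one `$`-delimited file per table with a header
row, dates as `YYYYMMDD` integers possibly truncated to `YYYYMM`/`YYYY`.
A report (`CaseReport`) carries demographics (sex, age in years, country,
reporter type), an FDA receipt date, one event date, a list of drug
entries with FAERS role codes (PS/SS/C/I) and per-drug start dates (from
`THER`), and a set of MedDRA preferred terms (PTs). PT→SOC coding is a
user-supplied two-column table standing in for the licensed MedDRA
dictionary; PTs without a mapping are reported and excluded from
SOC-level analysis only.

## Cleaning and deduplication

Reports with no PT, no drug entry, or age > 150 years are dropped;
missing sex/age/country are retained as their own category, since
spontaneous-reporting analyses tabulate missingness. Ages are normalized
from FAERS unit codes (YR, DEC, MON, WK, DY, HR) to years; unparseable
values become missing, never errors.

Deduplication is two-step, each step independently switchable:

1. **Case-version rule** — per case id, keep the version with the latest
   FDA receipt date (ties: largest primary id).
2. **Field-identity rule** — among survivors, reports identical on
   (sex, age, country, event date, sorted PT set) are treated as duplicate
   submissions; the one with the smallest primary id is kept.

The field-identity rule intentionally collapses coincidental matches as
well (e.g. two age-missing, date-missing reports with the same single PT);
this mirrors how such rules behave on real data, and the test suite checks
the retained count against an independent brute-force key count rather
than assuming only verbatim copies are removed. The operation is
idempotent and order-deterministic.

Target flagging: a report is a target report iff at least one
**primary-suspect** entry matches a drug-name pattern, case-insensitively;
substring matching is the default because FAERS drug names carry
dose/formulation suffixes (exact mode is available). All other reports
form the "all other drugs" comparator, so two drugs analysed in the same
database automatically exclude each other's reports from their own
background.

## Disproportionality

Contingency tables are built report-level (a report counts once per
distinct term) at PT or SOC level, one table per term with at least one
target report. `a ≥ 3` is the default eligibility threshold: the printed
criterion "N ≥ 3" is ambiguous between the co-occurrence count and the
table total, and the co-occurrence reading is both the pharmacovigilance
convention and consistent with the smallest published row count being 3.
If b, c or d is zero, 0.5 is added to all four cells for estimation
(Haldane–Anscombe) and the result flagged; classification still uses the
raw `a`.

The four algorithms use the point-estimate forms: ROR with a 1.96 normal
CI on the log scale; PRR with the uncorrected Pearson χ² (exactly the
printed formula — no Yates correction) and its one-degree-of-freedom
upper-tail p; the BCPNN information component `IC = log₂(aN/((a+c)(a+b)))`
with lower credibility bound `IC − 2·√(1/(a+1))/ln 2`; and MGPS
`EBGM = aN/((a+c)(a+b))` with `EBGM05 = EBGM·exp(−1.645·s)`. Two
deliberate choices here:

- **EBGM05 multiplier 1.645, not 1.96.** The source table's formula text
  prints 1.96, but its published EBGM05 values are only consistent with a
  one-sided 5th percentile (hypokalaemia: 16.04 with 1.645 vs 15.28 with
  1.96 against a printed 16.05). The multiplier is a function argument.
- **IC025 credibility form.** No variance formula is printed for IC; the
  implemented bound reproduces every published IC025 across report counts
  3–2,105 to ±0.02. It is exposed as a plain function (`ic025_lower`) so
  an alternative posterior could be substituted.

Since both Bayesian statistics use their point-estimate forms,
`IC = log₂(EBGM)` holds identically, and ROR, PRR, EBGM are ordered by
distance from independence (`sign(ROR−PRR) = sign(PRR−EBGM) =
sign(ROR−1)`); both identities are enforced as property tests. The full
Bayesian machinery (DuMouchel's EM hyperprior fit, the exact BCPNN
posterior) is out of scope by design; the interval hooks leave room for
it.

The joint rule requires all four criteria simultaneously (ROR ≥ 2 with CI
lower bound > 1 and a ≥ 3 — the CI requirement is the conventional ROR
rule and can be disabled; PRR ≥ 2 with χ² ≥ 4 and a ≥ 3; IC025 > 0;
EBGM05 > 2). Benjamini–Hochberg adjustment (statsmodels) is applied over
the joint-positive candidate set — matching the source workflow, where 19
candidates reduced to 18 after one q-value of 0.052 — with an `all`
scope option; significance is q < α = 0.05, two-tailed.

## Time to onset

Onset is computed per (target report, PT) as event date minus the
primary-suspect drug's start date, requiring both at full `YYYYMMDD`
precision; partial dates and negative intervals are excluded and counted
in an exclusion log. Day 0 is valid and falls in the first bin. The six
bins 0–30/31–60/61–90/91–180/181–360/>360 days are closed integer
intervals; the median is taken on raw days. Cumulative incidence curves
are empirical CDFs per PT for the top-k PTs by record count. The
late-onset screen keeps target reports with onset ≥ 365 days (cutoff ≤ 0
is a no-op restriction keeping all target reports, including those with
unevaluable onsets), rebuilds PT tables against the unchanged comparator,
and flags PTs with EBGM05 ≥ 2 or IC025 ≥ 0. Note the source analysis's
printed bin percentages for 31–60 and 181–360 days (12.8%, 14.89%) are
inconsistent with its own printed counts (31/246 = 12.60%,
36/246 = 14.63%); this package always reports exact proportions.

## Subgroups and two-drug comparison

Stratified screens restrict both target and comparator reports to one
stratum and re-run the full PT screen. Age bins are [0, 65), [65, 85],
(85, ∞); missing ages and unknown sex belong to no stratum, so the
male/female/missing tables sum cell-wise to the unstratified table (a
tested invariant).

Two drugs are compared per shared significant PT by
`Δln ROR = ln ROR_A − ln ROR_B` with `SE = √(SE_A² + SE_B²)`, each SE
recovered from the drug's ROR CI as `ln(hi/lo)/(2·1.96)`; the 95% CI is
`Δ ± 1.96·SE` and p is two-tailed normal. The independent log-normal
approximation is justified because the two report sets are disjoint after
primary-suspect assignment. Applied to the published rows this reproduces
the printed comparisons to input-rounding accuracy (congestive heart
failure Δ = 0.864 vs printed 0.87, CI 0.457–1.271 vs 0.46–1.27;
constipation −1.230 vs −1.24); for hard faeces the printed p of 0.16 is
not reproducible from the printed CIs (which imply p ≈ 0.11–0.12), so
tests assert only the reproducible facts (CI spanning zero,
non-significance).

## Recovering 2×2 cells from printed rows

Published signal tables print `(a, ROR, PRR, χ²)` but not the cells. The
three equations determine (b, c, d): algebra gives the target margin
`a + b = a(ROR−1)/(ROR−PRR)` exactly; the χ² equation then determines the
comparator total by Brent root-finding; a multi-start bounded
trust-region least-squares on log-cells (cells confined to [1, 10⁹])
refines the solution. The refinement matters because printed rounding
makes some rows exactly infeasible — several published rows have
ROR = PRR at two decimals, which would algebraically force ROR = 1 — and
the optimizer then finds the nearest table within half-ulp of print. A
row is flagged infeasible when the best relative residual exceeds 10⁻³;
cells are reported as positive reals, since integer cells generally
cannot reproduce rounded statistics. Across all 40 bundled published rows
the recovered cells reproduce every printed statistic at printed
precision (IC within ±0.01, EBGM within 1%).

## The synthetic generator

The generator emulates the structure the statistics assume, not FAERS
epidemiology. Reports are independent; each drug is included with its
marginal probability (first listed drug present becomes the primary
suspect, the rest secondary; drug-free reports receive a filler
comparator drug); each PT occurs with its background probability,
independently across PTs. An injected association (drug D, event E,
target odds ratio θ) tilts the event probability for reports with PS = D
to `qθ/(1−q+qθ)`, which yields population odds ratio exactly θ against
background rate q. Duplicates are verbatim re-emissions of the full
record with the same case id, so the deduplication rule can be tested
directly. Onset days are lognormal (per-PT override available) for
target-drug reports and uniform 0–360 otherwise; partial dates truncate
the day or month component.

Default conditions, chosen once to mirror the source cohort's reported
structure: 20,000 reports; target-drug marginal 0.02; 22 PTs across seven
SOCs with background rates 0.0005–0.15; missing sex 21.4% and missing age
65.9% (the published table's rates); male fraction 0.62 among known
(≈ the published 767:462); half of start/event dates missing or partial
(the published onset analysis retained 246 of 1,564 reports); 5%
duplicates; onset median 92 days (the published median) with log-sd 1.2.
Simulation-recovery checks run at n = 50,000 where the published
effect-size regime (odds ratio 10) is detected with high margin; the
realized-odds-ratio accuracy check is made on a high-frequency PT where
the expected co-occurrence count (~390) keeps Monte-Carlo error well
inside its 20% band.

What the generator does *not* model — reporting biases, drug
co-prescription structure, event correlations within reports, secular
trends — bounds what passing tests show: they validate the statistical
machinery and its decision rules on data satisfying the methods'
independence assumptions, not the epidemiological fidelity of any real
signal.

Reports that draw no event are emitted but removed by the cleaning rule
(as real no-PT cases are); ground truth therefore tabulates event-bearing
unique reports, keeping generator truth and pipeline counts comparable.
Conditioning on at least one event leaves null pairs at odds ratio
exactly 1 and perturbs injected pairs negligibly at the default rates.

## Numerical and degenerate-input conventions

Zero cells: Haldane–Anscombe 0.5 correction for estimation, flagged.
Empty inputs return empty tables with warnings rather than raising, except
where a precondition is violated (empty pattern list, empty report list
for the writer, top_k < 1, non-positive CI bounds, p-values outside
[0, 1]). Determinism: every simulation is driven by one integer seed
through `numpy.random.default_rng`; repeated runs are byte-identical, and
all orderings (dedup survivors, table rows, partitions) are explicitly
sorted. All thresholds (min co-occurrence count, α, interval multipliers,
onset cutoff, FDR scope, match mode) are function arguments with the
defaults above; nothing is hard-coded.

## Known limitations

- The reference tables transcribe published rows as printed, including
  two rows sharing the truncated name "Blood potassium"; recovery is
  row-wise, so the duplication is harmless.
- SOC-level counting is report-level by default; an event-level counter
  would differ where one report has several PTs in one SOC.
- The comparative analysis assumes each drug's screen used the same
  database snapshot; it does not model overlap if a report names both
  drugs as primary suspect in different case versions.
- The cell-recovery system is near-degenerate for rows with
  ROR ≈ PRR; recovered (c, d) are then poorly identified individually
  even though every derived statistic is stable, so recovered cells
  should be used for statistic regression, not as report counts.
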