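# Methods

## Three-valued criteria evaluation

Every leaf criterion is a `≥` comparison on a numeric field or a boolean
flag; a missing field makes the leaf UNKNOWN. Composites use strong Kleene
connectives, and the k-of-n operator returns TRUE when the TRUE count
already reaches k, FALSE when even counting every UNKNOWN as TRUE cannot
reach k, and UNKNOWN otherwise. All connectives therefore satisfy the
*completion contract*: the engine's verdict equals the three-way summary of
evaluating every boolean completion of the missing leaves (TRUE iff all
completions are true, FALSE iff none is). The test suite enforces this
against a brute-force enumerator for both bundled rule sets and for deeper
synthetic trees with up to ten leaves, along with information
monotonicity: filling in a missing field can only refine a verdict, never
flip a determinate one.

A patient is *evaluable* for a criterion iff its verdict is determinate.
All reported proportions use determinate-case denominators. This is the
only convention consistent with a composite's denominator exceeding a
component's (an OR over history can be settled for a patient whose
corticosteroid count is missing but who reports prior surgery), which is
exactly the pattern the published indication tables show. Whether the
original analysis used determinate-case or complete-case counting cannot
be verified without patient-level data; the per-criterion denominators of
the published tables are therefore not reproduction targets, only their
closed-form percentage arithmetic is.

Operationalization choices baked into the bundled rule sets:

* The 2021 "≥ 1 SCS course in the past 2 years" is evaluated on the
  past-year count — the only window the underlying registry captured.
* "Previous sinonasal surgery" and "history of endoscopic sinus surgery"
  are one field, `n_ess ≥ 1`.
* Anosmia is proxied by VAS loss-of-smell ≥ 52 mm (the adapted cutoff, not
  50) in both rule sets.
* The asthma leaf uses the reported asthma diagnosis; inhaled
  corticosteroid use is carried in the data model but not consulted by any
  rule.
* Banded history answers (">3" surgeries or courses) are stored as the
  integer 4; every rule threshold on those fields is ≤ 2, so any value ≥ 4
  is rule-equivalent.

Rule trees are data, not code: they serialize to JSON
(`data/ruleset_schema.json`), so stricter national variants (NPS ≥ 5,
SNOT-22 ≥ 50, ...) can be expressed by users; only the two international
sets ship.

## Statistical kernel

`fisher_exact_two_sided` enumerates the full conditional support of the
top-left cell, accumulating hypergeometric log-probabilities via `lgamma`
(no overflow at registry-scale counts), and sums the probabilities of all
tables no more probable than the observed one — the probability-mass
two-sided convention, with a relative tie tolerance of 1e-7. This is the
dominant convention in mainstream statistical software, but not the only
one; published values computed under another convention (e.g. a "p > 0.99"
style doubling rule) need not agree, and one such printed value indeed
does not reproduce under any standard convention we tried. The kernel is
cross-checked in the tests against an exact integer-arithmetic factorial
oracle (exhaustively for all tables with N ≤ 40) and against an
independent library implementation at larger counts.

Percentages are rounded half-up to one decimal (`28.65 → 28.7`), matching
how the cohort tables are printed; every percentage in every emitted
report is recomputed from the numerator and denominator printed beside it,
and the report writer asserts that internally. Median/IQR summaries use
linear interpolation between order statistics (quantile positions
`p·(n−1)+1`, the common "type 7" default; no convention was stated for the
published tables).

## Synthetic cohort generator

The generator emulates the published cohort's *marginals* only: the joint
distribution of a real CRSwNP population is not identifiable from
published summaries, and no attempt is made to reproduce composite counts.
Families per field:

| field(s) | family | calibration target |
|---|---|---|
| age, BMI | truncated normal | printed mean ± SD (bounds 18–90 yr, 14–60 kg/m²) |
| BEC, IgE, disease duration | log-normal | printed median (IQR) |
| SNOT-22, Lund-Mackay, VAS ×3 | scaled beta on the score range | printed median (IQR) |
| sex, smoking | categorical | printed percentages |
| surgeries, SCS courses, NPS | integer bands, uniform within band | printed band percentages |
| comorbidities, treatment flags | Bernoulli | printed percentages |

**Median-anchored calibration.** The published quartiles are asymmetric
around the median on every scale, so a symmetric least-squares fit of all
three quantiles biases the fitted median by several percent (≈ −5% for the
eosinophil count). Since the sample median is the statistic downstream
checks target, calibration instead matches the family median exactly — in
closed form for the log-normal (`µ = ln median`,
`σ = (ln q3 − ln q1)/2z₀.₇₅` as the quartile least-squares solution) and
via a root-finding constraint for the scaled beta (spread parameter
searched with tolerance 1e-6) — leaving the residual error on the
quartiles (up to ~9% where the asymmetry is strongest). Disordered or
out-of-range targets raise a calibration error.

**Dependence.** Sampling is Gaussian-copula style: one shared
standard-normal severity factor per patient, combined with an
idiosyncratic normal per field through the field's loading, then mapped
through the marginal quantile function. The default loading is 0
everywhere (independent fields): the published margins alone cannot
identify loadings, and the near-multiplicative combination of the two
type-2 components in the published data (81.7% and 44.3% combining to
≈ 90.3%) is consistent with independence. Users studying
severity-clustering effects can set loadings per field.

**Missingness** is missing-completely-at-random with per-field rates
derived from the printed denominators (e.g. nasal polyp score observed in
158 of 206 patients → rate 1 − 158/206). The published data imply one
inconsistency here — the corticosteroid-count leaf is reported with
denominator 188 in one table and 182 in the other for the same field —
which cannot be represented with a single per-field rate; the 188/206 rate
is used. No published information supports an informative-missingness
mechanism, so none is modelled.

**Value discretization.** SNOT-22 and Lund-Mackay are rounded to integers,
VAS and laboratory values to one decimal. Integer rounding means an
integer sample median cannot sit on a half-integer published target
(Lund-Mackay 14.5); the in-suite recovery checks widen the 3% relative
tolerance by the rounding unit for those two fields.

**What passing tests show — and don't.** Marginal-recovery tests at
n = 20000 demonstrate that the generator reproduces the published
marginals and missingness rates within sampling noise, and
pipeline-closure tests show the full generate → mask → evaluate → report
chain is total, deterministic per seed, and responds in the right
direction to threshold changes. None of this validates the *joint*
structure of real CRSwNP data: composite indication fractions computed on
synthetic cohorts (e.g. ~28% under the 2021 rule, ~40% under the 2023 rule
at default settings) are products of the independence assumption, not
predictions about any real population, and the per-criterion evaluable
counts will not match a real registry's.

## Reporting conventions

Cross-tabs, treatment gaps and concordance use determinate-case inclusion:
patients with an UNKNOWN composite verdict, or missing treatment status,
are excluded from those tables, with exclusion counts logged and recorded
in the run manifest. Percentages are blank (None/empty cell) on zero
denominators rather than 0. The `report.json` document contains no
timestamps, so identical configurations produce byte-identical reports;
the manifest carries the timestamp, seed, input hashes and package
version needed to re-run a bundle bit-identically.

## Problem sizes

The default synthetic cohort is n = 206 (the published cohort size).
Calibration checks use n = 20000, where binomial noise on a prevalence is
≈ 0.35 percentage points and median noise on the eosinophil count is
≈ 0.7% — comfortably inside the 1-point and 3% bands they are held to.
Property suites run the completion oracle on cohorts of 60 patients
(every record exercises up to 2^u completions, u ≤ 10 per rule tree) and
the Fisher oracle exhaustively over all 135k+ tables with N ≤ 40.

## Known limitations

* Index-date snapshots only; no longitudinal diary data model.
* No EPOS 2020 rule set (tissue eosinophilia per high-power field is not
  in the data model) and no national reimbursement rule sets, though the
  JSON tree format can express threshold-style variants.
* MCAR missingness and a single-factor copula are the simplest mechanisms
  consistent with the published summaries, not estimates of the real ones.
* The odds ratio reported with Fisher results is the unconditional sample
  ratio `ad/bc` (blank when undefined); no confidence intervals or
  conditional-MLE estimate, and no multiplicity adjustment anywhere.
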