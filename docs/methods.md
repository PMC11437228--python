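# Methods

## The decision algorithm

The engine (`preopcard.aep`) evaluates a fixed gate sequence per patient
and stops at the first gate that fires; the result carries the end-point
id, the recommendation, the possible/no-clear indication dichotomy, and an
ordered trace of every predicate evaluated. Fields are demanded lazily —
only the gates actually reached need their inputs — so a record that stops
at gate 1 never requires a MICA risk. The mapping from proceed branches to
end-point numbers (5 = low-risk surgery, 6 = RCRI gate, 7 = risk < 1%,
8 = adequate capacity) lives in a single table so renumbering cannot alter
routing. Patients with elevated risk, poor functional capacity, and no
prospect that testing would change management proceed to surgery; they are
recorded under end point 8 with a distinct trace marker (`8*`) rather than
a tenth id, sharing its proceed recommendation and no-clear-indication
class. The mutual order of the four screening gates (active condition,
unclear status, ischemia concern, ECG) can change which of end points 1–4
a multi-flag patient receives, but never the possible/no-clear dichotomy —
all four map to "possible indication" — which the test suite verifies by
enumeration.

Threshold comparisons are strict as worded: risk < 1%, METS < 4,
age < 65. An externally supplied NSQIP-style risk percent, when present,
substitutes for the MICA value at gate 7; it is never computed internally.
The shipped MICA coefficient file is synthetic (clearly labelled) — the
model class is a generic logistic, and users wanting the published
regression load their own coefficient file.

## Calendar windows

All dates are timezone-free calendar days. A visit strictly before the
cutover (default 2022-07-01) is *pre*; the cutover day itself opens the
*post* period. A service event is preoperative iff
`0 ≤ surgery_date − event_date ≤ 60` days — closed at both ends, so a
same-day service counts and so does one exactly 60 days out. Outcomes
count in `1 ≤ event_date − surgery_date ≤ 30`. The source material does
not state its boundary conventions; these closed conventions were fixed
once for determinism and are configurable (`StudyConfig`).

Duplicate visits (same patient and surgery date) keep the chronologically
first visit, ties broken by ingestion order. "Missing risk scores" means
any absent field among the six RCRI components, the MICA percent, the METS
class, or the ASA class. Duplicates are removed before the missing-score
scan so the accounting identity is exact.

## Synthetic cohorts

The generator (`preopcard.simulate`) emulates the *margins* of a matched
two-arm preoperative cohort: per-period covariate prevalences, a
piecewise-linear inverse-CDF age distribution hitting the configured
median and IQR (default median 64, IQR 53–72, range 18–95), a lognormal
MICA percent (median 0.27%, σ = 0.8, giving ~5% above the 1% threshold),
iid RCRI components (p = 0.066 per component, giving ~5.5% with score ≥ 2
under independence), and per-period service and outcome event rates with
dates placed uniformly inside the relevant windows (plus a 1% sprinkle of
out-of-window service events that linkage must ignore).

Confounding is injected by re-assigning period labels with
exponential tilting: each record's odds of the post arm are multiplied by
`exp(strength)` per positive tilt covariate (default: the six
comorbidities plus poor functional capacity), realized by Gumbel top-k
weighted sampling without replacement so arm sizes stay exact and the
draw is reproducible. With strength 0 the configured per-period
prevalences are realized exactly in expectation; with nonzero strength
the per-period margins shift slightly toward the pooled values, which is
acceptable for the intended "mild confounding" regimes.

What the generator does **not** emulate: covariate correlation (fields are
drawn marginally; a real cohort's comorbidities co-occur), any dependence
of service or outcome rates on covariates beyond period (configurable
conditioning was considered and left out of the default spec), seasonal or
secular utilization trends within a period, and repeat visits. Passing
pipeline tests therefore demonstrate statistical correctness of the
machinery under the reported margins, not fidelity to any real EMR joint
distribution.

`data/table1_matched.yaml` encodes the matched-cohort margins (11,645 per
arm) with confounding strength 0.05 — mild enough that ≥ 90% of records
survive caliper matching, the regime the pipeline was designed for.

## Propensity matching

The score is an unpenalized logistic regression of period on the baseline
covariate set (age, sex, race, ethnicity, six comorbidities, METS class,
ASA band 3–4, RCRI band ≥ 2, MICA band ≥ 1%, surgical risk level), fitted
by Newton's method with an L-BFGS fallback. Complete separation (no score
overlap between arms) is an error; quasi-separation on rare covariate
levels merely clips the affected scores to keep logits finite.

Matching is greedy 1:1 nearest-neighbor without replacement on the logit
of the score: the smaller arm is processed in a seeded random order, each
record paired with the nearest unmatched record of the other arm, subject
to a caliper of 0.2 × SD of the logit scores (sample SD, ddof = 1).
Distance ties break toward the earlier-ingested record. The implementation
uses path-compressed nearest-unused pointers over the sorted controls, so
cohort-scale matching is near-linear; the test suite checks it pair-for-pair
against a quadratic re-simulation of the same policy. Documented guarantees
rather than optimality: the greedy total distance is bounded below by the
exhaustive-assignment optimum, every pair respects the caliper, and since
an unmatched treated record implies no unused control within the caliper,
the matching is maximal on the caliper graph and retains at least half the
optimal pair count. The algorithm's order, caliper and replacement policy
are stated choices (standard practice), not reconstructions of any
particular statistical package's internals.

Balance is reported as standardized mean differences (binary:
`(p₁−p₂)/sqrt((p₁(1−p₁)+p₂(1−p₂))/2)`; continuous: pooled-SD
standardization; categorical: the largest absolute per-level SMD) alongside
the pre-match hypothesis tests, because p-value-only balance assessment is
sample-size dependent. Under any multiplicity-aware reading, a fraction of
per-covariate post-match p-values near the nominal α is the expected
behavior of a well-matched cohort; the tests assert that, not "all p > .05".

## Contingency analysis and E-values

Pearson chi-square without continuity correction is the default; a 2×2
table with any expected cell below 5 switches to the Fisher exact test.
For variables with more than two levels and omnibus p < .05, pairwise 2×2
comparisons are Bonferroni-adjusted by the number of pairs; post hoc
results are never produced without a significant omnibus test. Mann-Whitney
U (for age) uses the exact distribution for small tie-free samples and the
tie-corrected normal approximation otherwise; degenerate comparisons with
zero rank variance report p = 1.

Odds ratios are cross-products with the Haldane–Anscombe 0.5 correction on
any zero cell. The E-value uses `E = RR + sqrt(RR·(RR−1))` after
converting OR to an approximate RR — square root for common outcomes,
identity for rare ones — with the common/rare switch at 15% pooled
prevalence. That cutoff is the unique simple convention under which all
four published E-values in the motivating tables follow from their own
printed counts (consultation ≈ 20.5% pooled is converted by square root;
echocardiogram 6%, stress 1.6% and catheterization 0.4% are treated as
rare); it is configurable. RRs below 1 are inverted before the formula, so
E-values are direction-invariant, with floor 1 at the null.

Report percentages round half-up to one decimal, matching the convention
of the tables the pipeline emulates.

## Problem sizes used in the validation suite

The package's own validation uses: 20 seeds at full matched-cohort scale
(23,290 records) for the matched-fraction property; 200 replicates of
2,000-record null cohorts for the type-I-error check (rejection rate at
most twice nominal α = .05); 100 replicates of 2,000-record cohorts with
an injected consultation odds shift of 0.72 for CI-coverage of the
recovered odds ratio (≥ 90%); exhaustive enumeration (1,536 combinations)
for the decision engine; and brute-force oracles for matching (n ≤ 8) and
Mann-Whitney (group sizes ≤ 8). These sizes give stable verdicts for the
properties tested while keeping the suite quick to run.

## Known limitations

- The algorithm engine assumes upstream completeness; it raises on missing
  fields rather than imputing.
- Greedy matching is order-dependent by construction; different seeds give
  slightly different (equally valid) matched sets.
- The E-value is a point sensitivity measure; no E-value for the CI bound
  is computed.
- The monthly utilization series is structural (counts and rates per
  month); no trend model or plot is fitted to it.
- No time-to-event analysis: outcomes are binary 30-day windows.
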