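# Methods

## Data model and temporal conventions

The pipeline consumes three delimited UTF-8 tables (patient, therapy,
clinical) with documented headers; no proprietary export format is read.
All dates are ISO-8601 calendar days and every interval is half-open,
`[start, end)`, which makes day arithmetic and overlap logic unambiguous.
Age is computed from birth year only, evaluated at the window start, as is
usual for research databases that do not release full birth dates. The
study window defaults to the calendar year 2007 with a 90-day lead-in:
patients enter the cohort if they are at least 70 at the window start and
registered no later than 90 days before it. Patients who transfer out
mid-window are retained (registration must cover the window start, not the
whole window); how mid-window transfers should be handled is genuinely
open, and this choice maximises comparability of the denominator.

A prescription's coverage is `[issue_date, issue_date + duration_days)`
with `duration_days = ceil(quantity / daily_units)` when not given
explicitly. Real dosing directions are often missing; the reader keeps the
derivation explicit and overridable per row rather than imputing silently.

## Drug eras and dose normalisation

Per patient and drug class (or drug code, for duplication), consecutive
prescriptions whose coverage intervals are separated by at most
`max_gap_days` (default 30, the typical repeat-prescription cadence) merge
into one **era**. Era-average dose is

    avg_ddd_per_day = (Σ strength · quantity / ddd_amount) / era_days

and analogously for raw mass. Dose rules compare this era average to their
threshold: strictly above for "dose > X" rules (digoxin > 125 mcg/day,
aspirin > 150 mg/day) and at-or-above 2.0 DDD/day for "maximum therapeutic
dosage" (the PPI rule) — the cutoff is not standardised anywhere, so it
lives in the rule file, configurable per rule, not in code.

A consequence of era-average dosing worth knowing: appending a low-dose
prescription extends the era and can dilute the average below a dose
threshold, so event sets are not monotone under added prescriptions for
dose rules. They are monotone for all other predicate types, except the
intended suppression by protective co-drugs; both behaviours are tested.

## Criterion semantics

Each criterion is a conjunction evaluated per calendar day; the engine's
interval algebra is an exact closed form of a literal day-by-day scan (the
test suite carries an independent naive scanner and asserts event-for-event
agreement, trigger dates included). Conventions:

* required conditions count if coded on or before the day; chronic
  concepts (gout, COPD, glaucoma, dementia, ...) have unlimited lookback,
  acute flags are windowed per rule (falls: 90 days, "a fall in the past
  three months"). Conditions coded only after the exposure never trigger —
  condition-before-trigger is required throughout.
* absence-of-indication rules (aspirin with no vascular indication) use an
  explicit excluded-concept list in the rule pack.
* co-prescription means calendar-day overlap of eras (≥ 1 day); protective
  co-prescription suppresses the rule on overlapping days only.
* duration thresholds use week-based constants (>1 week = 7, >1 month =
  28, >8 weeks = 56, >3 months = 84 days) because calendar-month
  arithmetic is ill-defined; cumulative qualifying era days are counted
  over lead-in + window and the rule fires strictly above the threshold.
* therapeutic duplication requires two eras of *different* drug codes in
  the same duplication group overlapping ≥ 28 days inside the window; the
  floor operationalises "concurrent" and avoids counting within-group
  switches, a known over-count source in record databases.
* one event at most per (patient, criterion), dated at the first day the
  predicate holds — prevalence tables count patients, not episodes.
* the long-term urinary catheter item is represented as a standing coded
  concept in the vocabulary; persistence beyond two months is part of the
  concept's definition rather than re-derived from repeat codes.

The bundled comprehensive pack encodes the 50 criterion rows of the
emulated study's indicator table over a synthetic vocabulary. The
`subset28` flags mark the 28 criteria evaluable from prescription data
alone (drug-only, dose, duration, co-prescription, duplication, and
drug-proxy drug-disease rules); the exact membership used by earlier
claims-only studies is not published, so the flag set is this package's
own reconstruction, chosen so that the subset's leading issues (PPI at
maximum dose > 8 weeks, NSAID > 3 months, long-term neuroleptics) are
evaluable within it. The criteria the original study could not apply to
its database are not encoded at all.

## Vocabulary and Charlson index

The shipped codebook is a self-consistent synthetic stand-in for Multilex/
Read dictionaries and the WHO DDD index, which cannot be redistributed;
the schema accepts real vocabularies with the same columns. Charlson
scoring uses the classic 17-category weights (1/2/3/6), summing each
distinct category once, with no age points — age is modelled as its own
covariate. Raw scores are banded 0–1 → "1", 2 → "2", ≥ 3 → "3" for the
tables and the regression, matching the three-band presentation of the
emulated study's tables; its methods text mentions a five-level
categorisation, an ambiguity resolved here in favour of the tables, and
the banding is configurable.

## Covariates and statistics

A repeat medication is a drug class with ≥ 3 prescriptions issued inside
the window; polypharmacy is ≥ 4 repeat classes. Derivation is
window-local: lead-in prescriptions never affect repeat counts.

Prevalence CIs default to the Wilson score interval — the method used by
the emulated study is unstated, Wald agrees at large n but misbehaves at
the small n of synthetic test cohorts — and the method is recorded in the
output. 2×2 odds ratios use the cross-product with Woolf log-scale CIs;
the Haldane–Anscombe 0.5 correction is available behind a flag because
small synthetic cohorts hit zero cells. The adjusted model is a binomial
GLM with logit link fitted by IRLS (statsmodels), categorical covariates
dummy-coded against declared references (no polypharmacy, age 70–74,
male, Charlson band 1); "missing" sex is a retained level with its own
coefficient. Constant outcomes, detected separation (|β| > 30 or a
standard error > 50) and rank-deficient designs raise explicit errors
rather than returning numbers. Wald p-values are emitted but no claim is
made of matching any unpublished values. Reported rounding follows the
emulated tables: one-decimal percentages and odds ratios.

## Synthetic cohort generator

The generator defines the study conditions for all tests: age-band weights
(0.215 / 0.242 / 0.185 / 0.358 for 70–74 / 75–80 / 81–85 / >85) and sex
weights (41% male / 58% female / 1% missing) follow the emulated cohort's
marginals; chronic-condition prevalences follow its characteristics table
where reported (COPD 3.4%, peptic ulcer 6.8%, diabetes 16.5%, dementia
2.4%, hypertension 34.7%, osteoarthritis 19.7%, heart failure 1.1%,
parkinsonism 1.9%) and plausible registry values elsewhere. Background
therapy draws only on classes no criterion references, so unplanted
patients cannot fire rules. Default planting rates make duplication
(0.10), unindicated aspirin (0.08) and the PPI rule (0.03) the most common
issues, mirroring the emulated ranking, with a 0.005 base rate elsewhere.

Planting is constructive: rows are built to satisfy the predicate (dose
rules exceed thresholds by a sampled 25–75% margin, or sit exactly at an
at-or-above boundary; duration rules exceed by ≥ 7 days; conditions are
coded before the era; protective drugs are withheld), then verified by
evaluating the actual engine on the assembled record — generation fails
loudly if a planted rule does not fire. Criteria whose predicates conflict
with already-present facts (a required condition another planted rule
excludes, a protective class already on board) are skipped for that
patient rather than planted inconsistently. Truth labels record both the
planted set and the full engine-expected set (planted drugs can
legitimately fire additional criteria, e.g. a planted aspirin+warfarin
pair also firing the no-indication rule when no vascular code is present);
exact-recovery tests assert against the expected set and containment of
the planted set. Near-miss injection (optional) places just-below-
threshold exposure — 21-day overlaps, 21-day benzodiazepine eras, digoxin
at exactly 125 mcg/day — to stress boundaries; these must fire nothing.

In outcome-linked mode the generator assigns polypharmacy, Charlson band,
age and sex first, draws the PIP outcome from stated log-odds
(defaults: polypharmacy ln 18.2, age >85 ln 0.4, female ln 0.9, missing
ln 1.5, CCI-2 ln 1.51, CCI-3 ln 0.9, intercept −1.8), and plants one
criterion from a restricted list whose drugs and conditions touch neither
the Charlson categories nor each other — so the derived covariates equal
the intended ones exactly and the fitted model has known truth. A single
integer seed drives one `numpy` generator stream; identical configurations
produce byte-identical output files.

What the generator does **not** emulate: inter-practice heterogeneity,
realistic UK drug-utilisation rates, coding noise/ambiguity in diagnosis
vocabularies, mid-stream dose titration, or correlated multimorbidity.
Passing tests therefore demonstrate the correctness of the screening
logic, covariate derivation and estimation under known truth — not that
real-database prevalence would be reproduced.

## Problem sizes and numerical choices

Tests run the oracle-equivalence check on 50-patient cohorts, exact
planted recovery on 500-patient cohorts over five seeds, binomial
rate-recovery at n=500, and logistic parameter recovery over 200
replicates at n=2,000 (coverage of each true coefficient by its Wald 95%
CI must be ≥ 90%). The acceptance script uses n=2,000 for its synthetic
metrics. GLM convergence uses IRLS defaults (tolerance 1e-8, 100
iterations). Ties in duplication triggers resolve to the earliest
qualifying day; evaluation order is deterministic (sorted patients,
rule-pack order), so re-runs are bit-for-bit identical.

## Known limitations

* Era-average dose dilution (above) — a per-day dose model would be
  monotone but would depart from the strength×quantity/DDD exposure
  computation this pipeline reproduces.
* The synthetic vocabulary is a functional stand-in; mapping quality of
  real Read/Multilex code lists is out of scope.
* The subset-28 membership is a reconstruction (see above), so subset
  prevalences are comparable in structure, not in code-for-code content,
  with claims-only studies.
* No practice-level clustering, survival modelling, or missing-data
  imputation; the emulated study's model has none either.
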