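# Methods

This note documents the models and procedures clifkit implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## The data model and validation

CLIF organises ICU EHR data into longitudinal tables linked by
`patient_id` and `hospitalization_id`. The registry ships 22 unique
tables; the eight the analyses read (patient, hospitalization, adt,
vitals, labs, respiratory_support, medication_admin_continuous, scores)
carry fully specified columns, the rest carry minimal schemas (keys, a
timestamp, a `_name`/`_category` pair) and are extensible — their full
column lists are site configuration, not something this package should
invent. Category strings are lower_snake_case and compared
case-insensitively; all datetimes are stored timezone-aware in UTC and
converted on load; Parquet is the canonical format, with RFC 4180 UTF-8
CSV (ISO-8601 datetimes) as the text alternative.

Validation is rule-based and total: required tables, required columns,
declared dtypes, category membership in the controlled vocabulary, key
uniqueness and non-nullness, referential integrity against patient and
hospitalization, and declared datetime orderings (ADT out ≥ in, discharge
≥ admission). Violations are returned as data with row locators, never as
exceptions, so a site can triage its ETL output. The mapping operation
(`apply_category_mapping`) populates `_category` from `_name` via a
case-insensitive site dictionary, leaves unmapped names null (counted),
never alters `_name`, and is idempotent.

## Cohort discovery

An encounter qualifies if age at admission ≥ 18 years, the first ICU ADT
segment begins ≤ 48 h after the hospital admission datetime, the
contiguous ICU time from that first entry is ≥ 24 h, and the admission
date falls inside the study window (2020-01-01 to 2021-12-31 by default).
All boundaries are inclusive, matching the "within" / "at least"
phrasing of the criteria. Three choices were genuinely open and are fixed
here:

- *ICU-stay accounting.* "Staying at least 24 hours" is interpreted as
  the contiguous ICU block from first entry, merging back-to-back ICU
  segments separated by < 1 h (transfer artifacts). Later, separate ICU
  visits within the same hospitalization do not count toward the first
  block.
- *Offset anchor.* The 48-hour offset is measured from the
  hospitalization admission datetime (not ED arrival, which CLIF
  represents as an ADT segment of its own).
- *Window membership* is by hospital admission date, not ICU entry.

Outlier handling uses a per-(stream, category) plausibility-range table.
Values strictly outside [min, max] are set to missing; rows are never
deleted, so record counts and timestamps are preserved and the operation
is idempotent. The shipped ranges are artifact defaults (e.g. heart rate
20–300 bpm, temperature 32–44 °C) and fully overridable — a consortium's
own range table is configuration.

## Synthetic data generator

The generator emulates the structure of a multi-site ICU cohort at desk
scale so that every downstream operation has an exact oracle. Defaults
follow the reported consortium marginals: age ~ Normal(60.6, 17.2)
truncated at 18; 45% female; race mix 3.6/29.6/58.7/8.1% for
asian/black/white/other; 7.1% Hispanic; hospital mortality calibrated to
9.5% and mechanical ventilation to 38%; 0.07% of encounters with no
recorded temperature. Subphenotype mixture weights (NT 0.567, HT 0.240,
HFR 0.072, HSR 0.121) are renormalised midpoints of the reported per-site
prevalence ranges — an arbitrary but fixed choice, since only ranges are
published.

Structure per encounter: admission uniform over the window; ICU entry
offset ~ Exponential(mean 12 h); ICU length of stay ~ LogNormal(median
72 h, log-SD 0.8, floor 1 h); ADT segments ED/ward → ICU → ward;
timestamps floored to the minute. Temperatures are the encounter's true
reference curve plus i.i.d. N(0, 0.3²) noise, charted on the hour for
hours 0..min(72, stay), with a configurable fraction (default 30%)
recorded in Fahrenheit; other vitals are hourly Gaussians clipped
strictly inside the plausibility ranges; labs are Poisson-thinned
(default 1.5/day per analyte) around per-encounter latent levels.

Outcomes are drawn from a true logistic model on age, subphenotype
indicators and a latent albumin level (defaults: OR 2.0 for HT, 1.6 for
HFR, 2.0 for HSR vs NT; −0.4 per g/dL albumin; 1.35 per decade of age).
The intercept is solved numerically (Brent) so the realised cohort's
expected prevalence equals the configured target — effect sizes and
marginal rates stay independently configurable, and adjusted-OR recovery
is well-posed because the only omitted covariate (albumin) is
independent of subphenotype and small enough that non-collapsibility
attenuation is negligible (< 1% of the coefficient at the defaults).

Injected data-entry errors replace a configurable fraction (default
0.001) of vitals/labs values with values strictly above the plausible
maximum, and every injection is logged (table, row, category, old/new
value), which makes outlier cleaning exactly testable. All randomness
flows from one `numpy` generator seeded by the config; the same config
and seed reproduce every table byte-for-byte.

What the generator does **not** emulate: inter-site coding idiosyncrasies
and style differences, informative missingness, carry-forward charting,
treatment feedback (e.g. antipyretics truncating fever), correlated vital
streams, or realistic pharmacology. Passing tests therefore demonstrate
the correctness of the pipeline's logic and estimators under known
generating conditions — not that any particular clinical effect size in
real data is reproduced.

## Reference trajectories and classification

The four reference curves are parameterised exponential-approach shapes
`plateau + (start − plateau)·2^(−t/half-life)`: NT flat at 37.0 °C; HT
starting 36.2 °C approaching 36.5 °C (half-life 36 h, below NT
throughout); HFR starting 38.6 °C resolving to 37.0 °C with a 6 h
half-life (resolved within ~a day); HSR the same onset with a 30 h
half-life (resolving over ~three days). These are synthetic stand-ins
with the qualitative shapes the labels imply, **not** the published
group-based-trajectory-model curves, which are not printed anywhere this
package could cite; externally estimated curves load from CSV and drop in
everywhere.

Temperature standardization bins readings in [ICU entry, entry + 72 h]
to integer hours since entry by within-hour mean, converting
Fahrenheit-labelled values first (C = (F − 32)·5/9). Encounters with zero
temperature observations are excluded with the reason recorded; the
minimum-observation threshold is 1, matching an exclusion rule of "no
recorded temperatures" rather than a density requirement.

Classification minimises the **mean** squared error over observed hours
— "sum of the mean squared errors" is ambiguous between a sum and a
mean across hours; dividing by the observed-hour count makes sparse and
dense series comparable, so missingness is not itself penalised. Ties
break in the fixed order NT < HT < HFR < HSR. Whether the original
validation matched on raw hours or on polynomial evaluations of the GBTM
is unstated; hourly-grid matching is the documented choice here.

## Outcome models

Adjusted associations are logistic regressions of in-hospital mortality
or mechanical ventilation on subphenotype indicators (NT reference) plus
age (continuous, years), sex (reference female), race (four categories,
reference white) and ethnicity (Hispanic vs not), the only categorisation
the consortium tables print. Fitting is IRLS (binomial GLM) to gradient
tolerance 1e-8, maximum 200 iterations; perfect separation,
non-convergence, or absurd coefficients (|β| > 30) raise a fit-failure
error rather than returning silently unstable estimates. The odds-ratio
table reports OR = exp(β) with Wald 95% CIs exp(β ± 1.96·SE).

## Evaluation metrics

- **AUC** is the midrank (Mann-Whitney) estimator; ties contribute ½.
- **DeLong CI**: placement-value variance `S₁₀/m + S₀₁/n`, Wald interval
  truncated to [0, 1]. A degenerate (zero) variance — e.g. perfect
  separation — cannot support a Wald interval; the widest valid interval
  [0, 1] is returned with a warning. A seeded bootstrap is available as
  an option through resampling the inputs; DeLong is the default because
  it is analytic and deterministic.
- **Brier** is the mean squared error of the predicted probability.
- **Calibration** uses equal-count bins (deciles by default) of the
  sorted predictions, reporting mean predicted vs observed event rate per
  bin; with fewer subjects than bins, the bin count shrinks with a
  warning.
- **Decision curves**: `score ≥ p_t` counts as treated (closed on the
  left — a fixed convention); NB_model = TP/N − (FP/N)·p_t/(1−p_t);
  treat-all = π − (1−π)·p_t/(1−p_t); treat-none ≡ 0. The site evaluation
  grid always includes the 0.3 high-risk threshold.

## Model harness

The mortality model is a LightGBM binary classifier chosen for native
missing-value routing: first-24-h aggregates stay missing, never imputed.
Hyperparameters are selected by grid search with stratified 5-fold CV
scored by the package's own AUC; folds, the booster
(`deterministic=true`, single-threaded) and tie-breaking (first grid
point in sorted-key iteration order) are all seed-reproducible. Models
serialise to LightGBM's portable text format for cross-site exchange.
Reproducing any real site's coefficients or AUCs requires real EHR data
and is out of scope; the harness is validated by parameter- and
signal-recovery on synthetic data.

## Federated aggregation

Sites exchange `SiteSummary` objects (counts plus age mean/SD). Combining
sums counts and recomputes percentages from the combined
numerator/denominator. The combined age mean and SD are recovered by
converting each site's (n, mean, SD) back to first and second moments and
pooling — exact and associative up to float rounding when the inputs are
exact, approximate when site moments were themselves rounded for
publication. Table cells format as "n (pct%)" with one decimal below 10%
(two significant figures) and whole percent otherwise, and "mean (SD)" to
one decimal.

## Problem sizes used in the test suite

Checks run at desk scale chosen to make each assertion a ≥ 2–3 SE
statement: 200-encounter sites for pipeline equalities against ground
truth; 1,000 encounters for subphenotype recovery at noise SD 0.2 °C
(observed recovery ≈ 100%; the pass bar is 95%); 5,000 encounters for
prevalence calibration (3 binomial SE); 20,000 encounters with an
enriched HSR arm (weight 0.3) and 15% mortality for odds-ratio recovery
within [1.8, 2.2]; 500 simulations for DeLong CI coverage (95% ± 3%);
100 seeded replicates for null-association CI coverage (≥ 90%).
Recovery experiments deliberately use more informative designs than the
default marginals where the default design would make the stated band a
< 2 SE statement.

## Known limitations

- Default reference trajectories are stand-ins; substantive subphenotype
  conclusions require the externally estimated curves.
- The cohort definition relies on ADT location codes and inherits their
  selection biases (left-censoring, procedural stays mislabelled ICU).
- The generator's independence assumptions (noise i.i.d., streams
  independent given the encounter) understate real EHR correlation; test
  power computed under them does not transfer to real data.
- Combined-summary age SD is a pooled approximation whenever site SDs
  are rounded; only counts and recomputed percentages are exact.
- No recalibration or model-updating methods, no secure multiparty
  computation — "federated" here means file-based exchange of summary
  objects.
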