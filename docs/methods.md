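# Methods

## Problem and model

`bgdecomp` predicts inpatient blood-glucose decompensation as a 5-class
problem (nondecompensated, hypoglycemia, mild/moderate/severe
hyperglycemia; boundaries 3.9 / 10 / 13.9 / 16.7 mmol/L, boundary-exact as
in the README table). The design is built around three ideas:

1. **Event-anchored derived variables.** Inpatient laboratory data has no
   fixed sampling grid, so raw series are replaced by per-analyte summary
   statistics over a look-back window that ends strictly before the first
   decompensation event of the target category (or spans the full stay for
   controls). This mimics a clinician scanning a chart — averages, spread,
   trend, latest and most extreme values — rather than aligning time
   points. Only the first event per (case, category) is modeled; an event
   that coincides with the case's very first measurement is voided for that
   category, because no prior information exists to predict it from.
2. **A library of binary one-vs-rest-style models over category
   *combinations*.** Each binary XGBoost model detects a clinically
   meaningful positive set (e.g. "any hyperglycemia" = {2,3,4}); every case
   without a category in the positive set is a control — including
   decompensated cases of other categories. Sparsity-aware split finding
   consumes missing analytes natively; no imputation anywhere.
3. **Error-correcting output-code (ECOC) decoding.** The binary votes form
   a bit string compared against class codewords by Hamming distance;
   redundant models beyond the minimum ⌈log₂5⌉ = 3 provide error
   correction. Ties resolve by clinical severity with mild hyperglycemia
   deliberately last (fewer false alarms). The composition of the ensemble
   is chosen by a genetic algorithm.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| category thresholds | 3.9, 10, 13.9, 16.7 mmol/L | clinical guideline boundaries; level-2 hypoglycemia (<3.0) is merged into category 1 |
| demographic limits | age 18–130 y, height 100–250 cm, weight 25–400 kg | out-of-range → missing, other fields of the patient retained |
| hard lab limits | chloride 65–138, pH 6.8–7.8, potassium 1.3–9.0, sodium 100–191 | values incompatible with life → row removed; negatives removed except base excess |
| isolation-forest contamination | 0.01 | conservative flagging; flags are extra predictors, never filters |
| recent trend | OLS slope over last min(3, n) points, units/h | the most literal "recent trend"; missing below 2 points |
| most extreme value | argmax |x − window mean|, ties → later | self-contained, needs no reference ranges |
| row hash | 64-bit BLAKE2b of the canonicalised feature string | stable dedup of identical derived rows |
| split | 70/30 by case (round-half-up), optional by patient | patient-level split avoids leakage across repeat admissions |
| class weights | inverse class frequency, normalised to mean 1 | counters imbalance without resampling |
| search budget | 100 combinations/model (examples and the acceptance script use 8–50) | desk-scale; the search space covers depth, learning rate, trees, subsampling, column sampling, min child weight, L2 and γ |
| selection metric | AUC ROC (precision, sensitivity, informedness recorded) | a single retained-model criterion is needed; the alternative metrics are kept for inspection and are configurable |
| vote threshold | 0.5 on predicted probability | configurable per model |
| tie-break priority | (1, 4, 3, 0, 2) | severity order, mild hyperglycemia last |
| GA | population 50, 30 generations, uniform crossover 0.5, mutation 1/L, tournament 3, elitism 2 | standard settings; fitness = macro per-class precision of decoded predictions (classes never predicted score 0); a PR-curve-area fitness is available as the alternative reading of "average precision" |

Fold aggregation in `cross_validate` is per-fold-then-average (mean and
SD across folds). Display rounding is half-up at the report's precision;
raw values are kept internally.

## The synthetic cohort: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:
per-admission event prevalences 12.8 / 42.1 / 16.4 / 13.3 % for categories
1–4, ~1.66 admissions per patient, a 52-analyte panel with per-case
inclusion probability 0.6, daytime-peaked inhomogeneous-Poisson sampling
times, glucose as an Ornstein–Uhlenbeck process around a per-case
set-point, and a small rate of deliberately implausible entries to
exercise the cleaning stage. Six designated signal analytes shift linearly
over the 12 h before an injected event by `signal_strength` (default
1.5 SD) with category-specific sign patterns, and glucose drifts toward
the relevant band edge; with `signal_strength = 0` the cohort is an exact
null.

Two structural choices were made so that the null is *exactly* null —
i.e. that nothing but the injected signal distinguishes positives from
controls:

* **Decompensation ends a latent baseline course and extends the stay.**
  Pre-event window length is drawn from the same distribution as control
  stay length, so analysis counts and window duration carry no label
  information, while reproducing the qualitative observation that
  decompensated stays are longer. Event times are consequently later in
  the stay than the real-data medians (tens of hours post admission).
* **Single decompensation episode per case by default.** With co-occurring
  categories, the look-back window of a later event contains the
  decompensated BG measurements of an earlier one, making labels partially
  recoverable from features by construction. Multi-category cohorts are
  available (`allow_multi_category=True`) and the labeling/feature/ensemble
  stages fully support multi-category instances; only the generator's
  default avoids them.

Not emulated: pharmacokinetics and dosing, clinically calibrated analyte
correlations (reference means/SDs are invented), fasting/OGTT measurement
contexts (the inclusion-rule checker supports them if present), and
real-data event-time marginals. Passing tests on synthetic cohorts
therefore demonstrate *mechanical correctness and signal recovery under
the stated generative assumptions*, not clinical performance; real-data
metrics depend on cohort composition and are expected to differ.

The dysglycemia-risk cohort inclusion rules (diabetes-spectrum ICD-10
codes, ATC A10 exposure, extreme glucose-related results) are implemented
and tested but not applied to synthetic cohorts by default: the generator
emulates the post-inclusion at-risk population directly, and filtering
synthetic controls on diagnosis/drug markers would induce spurious
feature–label association in null cohorts.

## Numerical and degenerate-input behaviour

* `categorize_bg` is total on positive values and boundary-exact; zero or
  negative BG raises.
* Statistics with undefined denominators are missing, never 0: SD/IQR/
  range/trend need ≥ 2 points, trend also needs distinct times; precision
  with no positive predictions is missing (it scores 0 only inside the GA
  fitness, where "never predicts a class" must be penalised).
* Isolation forests run per analyte on (value, hours-since-admission) and
  are fitted only on look-back rows, so post-event data cannot influence
  any feature bit; analytes with < 20 fit rows are never flagged.
* Codeword collisions raise with the colliding classes named; infeasible
  GA masks get −∞ fitness; the GA memoises masks and is deterministic for
  a fixed seed.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); XGBoost runs single-threaded `hist` for
  reproducibility.

## Known limitations

* Control windows span the full stay while event windows end at the event;
  on real data (where decompensation timing correlates with stay length)
  duration-derived features may pick up structural signal. The synthetic
  design neutralises this; analyses of real extracts should consider a
  matched-censoring scheme.
* The GA guarantees only fitness ≥ every visited mask; equality with the
  exhaustive optimum is verified in tests up to the 9-candidate library
  (511 masks) but is not a mathematical guarantee at much larger library
  sizes.
* Retained binary-model metrics come from the same withheld 30% used for
  candidate selection and are therefore optimistically biased (winner's
  curse); the outer pipeline evaluation uses cases untouched by selection.
* Probability calibration of the binary models is out of scope; votes use
  a fixed threshold.
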