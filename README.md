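# bgdecomp

Multiclass prediction of inpatient blood-glucose (BG) decompensation —
hypoglycemia and three grades of hyperglycemia — from routine,
irregularly-sampled electronic-health-record data.

Acute BG decompensations are frequent in hospitalised adults and worsen
outcomes. `bgdecomp` is for biostatisticians and clinical data scientists
who want a tested, reusable implementation of an event-anchored,
ensemble-of-binary-classifiers approach to this prediction problem, with a
synthetic cohort generator (ground-truth events at known times) standing in
for protected hospital data.

## The method

BG values (mmol/L) are categorised as

| interval           | category | type                   |
|--------------------|----------|------------------------|
| ≥ 3.9 to ≤ 10      | 0        | nondecompensated       |
| < 3.9              | 1        | hypoglycemia           |
| > 10 to ≤ 13.9     | 2        | mild hyperglycemia     |
| > 13.9 to ≤ 16.7   | 3        | moderate hyperglycemia |
| > 16.7             | 4        | severe hyperglycemia   |

For each admission ("case") the first event per category is detected; all
data strictly before it (the *look-back window*) is summarised into derived
variables — per analyte the mean, SD, IQR, total range, recent trend
(OLS slope over the last ≤3 points, units/h), most extreme and most recent
value, and analysis count — combined with demographics, antidiabetic-drug
history (ATC A10), previous decompensations, diagnosis history (ICD-10) and
ICU stay. The time from the last datum in the window to the event is the
*prediction horizon*. Cases without an event contribute their full stay as
controls.

Binary XGBoost classifiers are trained for clinically relevant
positive-class sets (A = {1,2,3,4}, B = {1}, …, G = {1,4}, H = {2,3,4},
I = {3,4}), with inverse-class-frequency weights, a case-level 70/30 split
and a stochastic hyperparameter search scored on the withheld 30%. Missing
values are handled natively by sparsity-aware split finding.

The second level is an error-correcting output code: an ordered ensemble of
L binary models gives each class k a codeword C[k] ∈ {0,1}^L (C[k][j] = 1
iff k is in model j's positive set; at least ⌈log₂ 5⌉ = 3 distinct-codeword
models are required). A case's votes decode to
`argmin_k Hamming(votes, C[k])`, ties broken by clinical severity
(hypo > severe hyper > moderate hyper > nondecompensated > mild hyper).
The ensemble composition is selected by a seeded genetic algorithm
maximising macro-averaged per-class precision on validation data.

## Worked example

```bash
python examples/05_full_pipeline.py
```

prints (≈400-patient synthetic cohort, search budget 8 per model):

```
GA-selected ensemble: ['A', 'B', 'C', 'D', 'E', 'F', 'G', 'H'] (fitness 0.824)
member withheld-split AUCs: {'A': 0.863, 'B': 0.897, 'C': 0.676, 'D': 0.744,
                             'E': 0.529, 'F': 0.657, 'G': 0.757, 'H': 0.875}

3-class confusion matrix (rows = true):
predicted   0   1    2
true
0          18  11   12
1           0  20    4
2          12  16  112
control        sensitivity  43.9%  specificity  92.7%  precision  60.0%
hypoglycemia   sensitivity  83.3%  specificity  85.1%  precision  42.6%
hyperglycemia  sensitivity  80.0%  specificity  75.4%  precision  87.5%

binary reduction (any decompensation): sensitivity 92.7%,
specificity 43.9%, precision 86.9%
```

The GA fitness is the macro-averaged per-class precision of the decoded
multiclass predictions; the per-class rows are one-vs-rest percentages on
the withheld 30% of cases after grouping predictions to
control/hypo/hyper; the binary reduction collapses all decompensation
classes into one. The other examples (`examples/01…04`) walk through
cohort generation, cleaning/labeling, a single binary model with its
feature-importance ranking, and codeword decoding with the severity
tie-break.

A thin CLI mirrors the stages: `bgdecomp --seed 1 --outdir out run-all`
(also `simulate`, `preprocess`, `label`, `featurize`, `train`, `assemble`,
`evaluate`, `init-config`; configuration via `--config file.yaml`).

## Layout

- `src/bgdecomp/synthetic_cohort.py` — cohort generator + ground truth
- `src/bgdecomp/preprocessing.py` — plausibility limits, isolation-forest flags
- `src/bgdecomp/labeling.py` — categories, first events, windows, horizons,
  cohort inclusion rules
- `src/bgdecomp/features.py` — derived variables, hashing, dedup
- `src/bgdecomp/binary_models.py` — XGBoost library, weights, split, search
- `src/bgdecomp/ecoc.py` — codewords, Hamming decoding, GA composition
- `src/bgdecomp/evaluation.py` — confusion matrices, metrics, CV, reports
- `docs/methods.md` — model assumptions, parameter choices, limitations
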