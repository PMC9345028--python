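"""Generate a synthetic inpatient cohort with injected BG decompensations.

The generator emulates the data a hospital EHR extract would provide:
irregular, daytime-biased lab sampling over a 52-analyte panel, sparse
per-case panels, and decompensation events (categories 1-4) injected at
known ground-truth times with per-admission prevalences of
12.8/42.1/16.4/13.3%.
"""

from bgdecomp import CohortConfig, generate_cohort

config = CohortConfig(n_patients=300, seed=1)
cohort = generate_cohort(config)

n_cases = len(cohort.admissions)
print(f"patients: {len(cohort.demographics)}, admissions: {n_cases}")
print(f"lab measurements: {len(cohort.lab)} across "
      f"{cohort.lab['analyte'].nunique()} analytes")

prev = cohort.ground_truth.groupby("category").size() / n_cases
print("\nper-admission event prevalence (fraction of cases):")
for cat, name in [(1, "hypoglycemia"), (2, "mild hyper"),
                  (3, "moderate hyper"), (4, "severe hyper")]:
    print(f"  category {cat} ({name:14s}): {prev.get(cat, 0.0):.3f}")
# These fractions track the configured prevalences up to binomial noise;
# every event has a ground-truth time and a matching BG measurement.
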