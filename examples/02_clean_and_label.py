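"""Plausibility cleaning, first-event detection and look-back windows.

Demographics outside physiological limits become missing; implausible lab
rows are dropped; each case's first decompensation event per category is
detected from its glucose series (events at the very first measurement are
voided — there is nothing before them to predict from), and every modeling
instance gets a look-back window and a prediction horizon.
"""

from bgdecomp import (CohortConfig, apply_lab_limits, build_windows_manifest,
                      categorize_bg, detect_events_cohort, generate_cohort,
                      horizon_summary)

print("category boundaries (mmol/L):",
      {v: categorize_bg(v) for v in (3.89, 3.9, 10.0, 10.01, 16.7, 16.71)})

cohort = generate_cohort(CohortConfig(n_patients=300, seed=1))
lab = apply_lab_limits(cohort.lab)
print(f"lab rows: {len(cohort.lab)} raw -> {len(lab)} after limits")

events = detect_events_cohort(lab, cohort.admissions)
manifest = build_windows_manifest(lab, cohort.admissions, events)
print(f"events detected: {len(events)}; "
      f"instances (events + controls): {len(manifest)}")

summary = horizon_summary(manifest)
print("\nper-category look-back and prediction horizon:")
print(summary.round(2).to_string(index=False))
# The horizon is the lead time an alert would give: hours between the last
# datum in the look-back window and the decompensation event.
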