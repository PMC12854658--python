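"""Classify stays with the structured-data rule engine.

Generates a 500-stay cohort in memory, applies the Boolean rule cascade
(hemoglobin drop within 48 h, stay nadir, transfusions > 5 units,
antihemorrhagic prescriptions, diagnosis-code lists) and prints the
prevalence table and per-source contributions.
"""

from bleedwatch import CohortConfig, generate_structured
from bleedwatch.evaluation import source_contribution
from bleedwatch.sda import classify_cohort, cohort_prevalence

bundles, truth = generate_structured(CohortConfig(n_stays=500, seed=42))
calls = classify_cohort(bundles)

prev = cohort_prevalence(calls)
print("prevalence (count, % of", prev.denominator, "stays):")
for key, count in prev.counts.items():
    print(f"  {key:13s} {count:4d}  {prev.percentages[key]:6.2f}%")

agree = sum(c.label == truth.label(c.stay_id) for c in calls)
print(f"agreement with generator truth: {agree}/{len(calls)}")
print("-> every injected event satisfies exactly one rule, so the engine")
print("   recovers the truth perfectly on this synthetic cohort.")

mb = source_contribution(calls, "MB")
print("\nMB detection by source (shares can exceed 100% where sources overlap):")
for src, rec in mb["per_source"].items():
    print(f"  {src:12s} {rec['count']:3d}  {rec['pct']:6.2f}%")
print("stays found by exactly m sources:", mb["overlap_histogram"])
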