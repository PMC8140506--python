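"""Data-driven age categorization by AUC maximization.

On a fixture whose disease prevalence drops at ages 27 and 35, the
cut-point search should recover those boundaries; on the calibrated
cohort it finds boundaries near the late-20s / mid-30s, mirroring the
age structure of the AMH-PCOS relationship.
"""

from amhcut import (
    AgeStepGenParams,
    CohortGenParams,
    generate_age_step_outcome,
    generate_cohort,
    optimal_cutpoints,
)

fixture = generate_age_step_outcome(
    AgeStepGenParams(cutpoints=(27.0, 35.0), prevalences=(0.8, 0.5, 0.1),
                     n=6000, seed=3)
)
part = optimal_cutpoints(fixture.rename(columns={"d": "label"}), k=2)
print(f"step fixture: recovered cut-points {part.cutpoints}, AUC {part.auc:.3f}")

cohort = generate_cohort(CohortGenParams(n_case=2000, n_control=2000, seed=1))
cohort["label"] = (cohort.group == "case").astype(int)
part2 = optimal_cutpoints(cohort, k=2)
print(f"synthetic cohort: cut-points {part2.cutpoints}, AUC {part2.auc:.3f}")
print(f"age bands: {part2.intervals}")
print("Bands are left-closed/right-open except the last; each band gets "
      "its own AMH cut-off downstream.")
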