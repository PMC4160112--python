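"""Generate a synthetic 10-colony study and run the QAP test battery.

The generator plants a differential-strength coupling of 0.36 on nF-F
trails; the pipeline should recover a positive observed correlation,
with significance assessed by within-colony node-label permutation.
"""

import polydomy as pm

report = pm.run_analysis(
    pm.GeneratorConfig(seed=1, rho_target=0.36),
    pm.AnalysisConfig(seed=1, n_permutations=500),
)

print("colony summaries:")
print(report.colony_summaries.to_string(index=False))

headline = [
    "strength_by_trail_type",
    "differential_vs_strength_nF-F",
    "differential_vs_strength_F-F",
    "length_by_trail_type",
    "population_by_foraging_status",
]
print("\nheadline QAP tests:")
print(
    report.tests.set_index("test")
    .loc[headline, ["observed", "p_value", "n"]]
    .to_string(float_format=lambda x: f"{x:.4f}")
)

assort = report.assortativity
degree = assort[assort["attribute"] == "weighted_degree"]
print("\nper-colony weighted degree correlation (Bonferroni-adjusted):")
print(degree[["colony_id", "r", "p_adjusted", "significant_05"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# The nF-F differential-strength correlation should be positive (the
# planted coupling); trail-type vs strength has no planted effect, so
# its p-value is usually unremarkable. Each p traces to 500 within-colony
# node-label permutations with the run seed recorded in the report.
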