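"""Developmental-trajectory analysis: mixed models, BIC, LRTs, FDR.

Fits constant/linear/quadratic random-intercept models per (tract, metric),
selects the order by BIC, tests the group offset and the group-by-age
interaction by likelihood ratio, and FDR-corrects across the 72 measures.
The synthetic cohort plants group offsets (FA up, diffusivities down in the
deletion group) and no interaction, so group effects should be widely
significant and interaction discoveries should stay at the false-positive
level.
"""

from longdti import SimulationConfig, generate_cohort, run_trajectory_analysis

table, _, _ = generate_cohort(SimulationConfig(seed=7))
res = run_trajectory_analysis(table, alpha=0.05)

print(f"models fitted: {len(res)} (18 tracts x 4 metrics)")
print(f"group effects at q<0.05:       {int(res.significant_group.sum())}")
print(f"interaction effects at q<0.05: {int(res.significant_interaction.sum())}")
print("\nselected polynomial orders by metric (counts):")
print(res.groupby("metric")["selected_order"].value_counts().to_string())
print("\nstrongest group effects (per metric):")
cols = ["tract", "metric", "selected_order", "coef_group", "q_group", "group_direction"]
best = res.loc[res.groupby("metric")["q_group"].idxmin(), cols]
print(best.to_string(index=False))
print("\nA positive group_direction for FA and negative for AD/RD/MD mirrors")
print("the planted deletion-group pattern; q-values are Benjamini-Hochberg")
print("corrected across all 72 measures within each effect family.")
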