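"""Generate a synthetic longitudinal DTI cohort and summarize its design.

The generator emulates a two-group accelerated-longitudinal study: controls
and 22q11.2-deletion carriers, ages 5-35 at entry, 1-3 visits each, per-scan
tract-average FA/AD/RD/MD over 18 tracts, five dichotomous clinical risk
factors per subject, and a planted rank-1 latent component linking risk
factors to subject-level metric deviations.
"""

from longdti import SimulationConfig, generate_cohort

cfg = SimulationConfig(seed=42)
table, risk, truth = generate_cohort(cfg)

n_subj = table["subject_id"].nunique()
scans = table.drop_duplicates(["subject_id", "visit_index"])
print(f"subjects: {n_subj} ({cfg.n_per_group} per group)")
print(f"scans: {len(scans)} (mean {len(scans) / n_subj:.2f} per subject)")
print(f"age range: {scans['age'].min():.1f}-{scans['age'].max():.1f} years")
print(f"rows: {len(table)} = scans x 18 tracts x 4 metrics")
print("\nrisk-factor prevalences (planted vs empirical):")
for rf, p in zip(risk.columns[1:], cfg.risk_prevalence):
    print(f"  {rf:18s} {p:.2f} vs {risk[rf].mean():.2f}")
fa = table[table.metric == "FA"]["value"]
print(f"\nFA range across tracts/ages: {fa.min():.3f}-{fa.max():.3f}")
print("Each subject also carries a latent score (risk factors projected on")
print("the planted behavior weights) that shifts all of their scans along")
print("the planted brain-weight pattern - the signal the PLS must recover.")
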