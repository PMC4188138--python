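"""Volume-cognition regressions and the across-diagnosis ANOVA.

Does the choice of normalization change how well hippocampal volume explains
a memory score, and do the diagnostic groups separate regardless of mode?
"""

import icvnorm as iv

cohort = iv.generate_cohort(iv.adni_like_spec(seed=6))
model = iv.fit_reference_model(cohort, "CTL")
adjusted = {m: iv.adjust(cohort, m, model=model) for m in ("raw", "proportion", "residual")}

print("ADAS word recall ~ hippocampus, R^2 by mode:")
for mode, adj in adjusted.items():
    fit = iv.fit_score_model(adj, "adas_word_recall", "hippocampus")
    print(f"  {mode:>10}: R^2 = {fit.r_squared:.3f}")
inter = iv.fit_score_model(adjusted["raw"], "adas_word_recall", "hippocampus", with_interaction=True)
print(f"  raw + ICV + hippocampus:ICV interaction: R^2 = {inter.r_squared:.3f}")

print("\nhippocampus ~ ICV + age within each diagnosis:")
for dx in cohort.diagnoses:
    fit = iv.fit_voi_on_icv_age(cohort, "hippocampus", group=dx)
    print(f"  {dx}: beta_ICV = {fit.params['icv']:.3e}, R^2 = {fit.r_squared:.2f}")

anova = iv.anova_tukey(adjusted["residual"], "hippocampus")
print(f"\nANOVA across CTL/MCI/AD (residual volumes): F = {anova.f:.1f}, p = {anova.p:.2g}")
print(anova.pairwise.to_string(index=False))
# All three pairwise Tukey HSD contrasts separate: atrophy dominates the
# group structure whatever the head-size treatment.
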