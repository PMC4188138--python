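"""ICV-matched subsampling: remove head-size variability by design.

Instead of adjusting volumes, select 21 males and 21 females whose ICVs are
nearly identical (relative SD < 1% within each group), then compare with a
Mann-Whitney U-test and calibrate the Welch t against a bootstrap null.
"""

import icvnorm as iv

cohort = iv.generate_cohort(iv.pivus_like_spec(seed=5))
sub = iv.match_by_icv(cohort, "gender", k=21, rel_sd_max=0.01)
print(sub.stats.to_string(index=False, float_format=lambda v: f"{v:,.5g}"))
# Both groups now share essentially one head size, so any remaining volume
# difference cannot be ICV-mediated.

df = cohort.data.set_index("subject_id")
for region in ("hippocampus", "third_ventricle"):
    xf = df.loc[sub.ids["F"], region]
    xm = df.loc[sub.ids["M"], region]
    mw = iv.mann_whitney(xf, xm)
    boot = iv.bootstrap_t(sub, cohort, region, n_boot=5000, seed=5)
    print(f"{region:>16}: U = {mw.u:.0f} (p {mw.p:.3f}), "
          f"Welch t = {boot.t_observed:+.2f}, bootstrap p = {boot.p_sim:.3f}")
# In this generator gender effects beyond ICV are small, so matched-group
# p-values are usually unremarkable -- the analysis quantifies exactly that.
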