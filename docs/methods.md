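# Methods

## Model

Every analysis in this package assumes the linear head-size model for a
regional volume V in subject i:

    V_i = a + β · ICV_i + g(sex_i) + s · age_i + d(dx_i) + ε_i,   ε ~ N(0, σ²)

with region-specific intercept a (mm³), ICV slope β (dimensionless), an
additive male offset g, an optional age slope s (mm³/year), additive
diagnosis (atrophy) offsets d, and Gaussian noise. The intercept is the
scientifically load-bearing term: with a > 0, the fraction V/ICV ≈
β + (a+ε)/ICV decreases in ICV, so division by head size over-corrects and
reverses the sign of the volume–ICV correlation. Residual adjustment,
V − β̂(ICV − ICV̄) with β̂ fit by OLS in a reference group, is exactly
orthogonal to ICV within that group (a property of least squares, not of the
data) and preserves the group mean; applied to other groups it is unbiased
but only zero-correlation in expectation.

### Reference-group convention

When a cohort contains several diagnosis strata, the residual slope is fit
on the designated reference (control) stratum and applied to all strata: the
control slope is taken to represent the premorbid volume–head-size
relationship, which pathology may distort. `fit_reference_model` refuses to
pool strata silently when no reference is named. An `include_age` flag adds
age as a second regressor (the stored β is then the partial ICV slope);
default off.

## Synthetic cohorts

The generator's default catalog carries 51 hemisphere-averaged regions
(17 subcortical, 34 cortical) with normative per-gender means and SDs for a
population of cognitively normal 75-year-olds, and gender-specific ICV
distributions (F: 1,440,320 ± 121,240 mm³; M: 1,638,419 ± 140,237 mm³).
Calibration, chosen once:

* β is set for a volume–ICV correlation of 0.5 (the middle of observed
  mean correlations in large elderly cohorts), computed from the female SD:
  β = 0.5·σ_region/σ_ICV.
* For non-ventricular regions β is capped at 0.75·mean_F/ICV̄_F so the
  intercept stays ≥ 25% of the female mean. This guarantees the positive
  intercept that real gray- and white-matter volumes show; for the affected
  small regions (e.g. transverse temporal, frontal pole) it lowers the
  implied correlation to ~0.3–0.45, a realistic spread.
* Ventricular/CSF regions (lateral, inferior lateral, third and fourth
  ventricles, CSF) have SD/mean ratios large enough that the same rule
  yields negative intercepts, so their fractions keep a positive ICV
  correlation. Known departure from real data: in large cohorts the
  fourth-ventricle and CSF fraction–ICV correlations are near zero rather
  than positive; the catalog does not reproduce that detail.
* The male offset g = (mean_M − mean_F) − β(ICV̄_M − ICV̄_F) reproduces male
  cell means exactly; noise σ² = SD_F² − β²σ_ICV² (floored at (0.2·SD_F)²)
  approximates female SDs exactly and male SDs roughly. Calibration is
  documented as approximate, not a fit.
* The three-stratum cohort adds atrophy offsets as fractions of the female
  mean — gray matter −5% (MCI) and −12% (AD), medial-temporal regions
  (hippocampus, amygdala, entorhinal) −10%/−20%, ventricles +15%/+35%,
  white matter 0 — plus a gray-matter age slope of −0.3%/year (intercepts
  re-anchored at age 75). Values are standard magnitudes for these
  populations, chosen once.
* Cognitive scores are linear in the hippocampal volume with Gaussian noise
  and floor/ceiling clipping (MMSE 0–30, ADAS word recall 0–10). In the
  three-stratum cohort, per-diagnosis offsets make cell score means land on
  their normative targets (ADAS 2.9/4.5/6.1; MMSE 29.1/27.1/23.3): the score
  gap between strata is deliberately only partly hippocampus-mediated, as in
  real data. The ADAS slope (−1.5e-3 points/mm³, noise 1.2) keeps
  within-group score SDs near the normative ~1.1–1.4.
* ICV is drawn independently of age (no association is observed in elderly
  cohorts) and volumes are floored at 1 mm³ with a logged count; the spec
  validator warns at construction time when parameters make truncation
  likely (routinely true for ventricles, whose real distributions are
  right-skewed while the generator is Gaussian).

What a green test on this generator establishes: the *algebraic* behavior of
the normalization modes (orthogonality, mean preservation, sign reversal,
gender-difference elimination when differences are ICV-mediated) and the
calibration of the inferential machinery. What it cannot establish:
real-data effect sizes (published R², mean correlations, AUC values), which
depend on restricted cohorts; the pipeline reports these quantities in the
published table shapes but asserts nothing about their values.

## Statistical procedures

* **Welch t everywhere.** Normative tables of t-statistics computed from
  per-gender summary statistics match the unequal-variance form, not the
  pooled form, so Welch with Satterthwaite df is the only two-sample t path.
  Sign convention: positive when the second group exceeds the first.
* **Bonferroni families** default to the report table the region belongs to
  (17 subcortical, 34 cortical); p_adj = min(1, p_raw × family size);
  direction calls {A>B, B>A, none} are made on p_adj at α = 0.05.
* **Age gate.** Partial correlation (residualize-then-correlate, p from t on
  n − 3 df) replaces plain Pearson only where corr(age, VOI) is significant
  at uncorrected two-sided α = 0.05, evaluated per region. Uncorrected is a
  deliberate choice (the gate is a screening device, not an inference) and
  is recorded in the run manifest.
* **ICV matching.** Both groups are sorted by ICV; among all contiguous
  k-windows whose within-group relative SD is below the bound (default 1%),
  the window pair with the smallest mean gap is selected. Deterministic for
  a fixed input order; infeasibility reports the best achievable SDs. The
  criterion (bound + close means) is the specification; the window search is
  this package's algorithmic choice.
* **Mann–Whitney U** is reported for the first sample; exact enumeration
  when n_x·n_y ≤ 400 and no ties are present, tie-corrected normal
  approximation otherwise (exact enumeration does not handle ties).
* **Bootstrap t.** Within-group resampling with replacement, Welch t per
  replicate, null constructed by centering replicates at the observed t
  (made explicit in the manifest because the null construction is a free
  choice); simulation p = (exceedances + 1)/(n_boot + 1), so p > 0 always.
  Degenerate zero-variance replicates are redrawn and counted. Type-I error
  at α = 0.05 calibrates to ~0.03–0.05 in the test suite.
* **ANOVA/Tukey** use scipy's F test and statsmodels' studentized-range HSD.
* **ROC/AUC** uses the rank formulation with half-credit ties, making AUC
  exactly U/(n₁n₀) with the package's own Mann–Whitney convention (asserted
  as a cross-module identity). CIs and the paired two-marker test use DeLong
  placement values; the paired test addresses correlated AUCs measured on
  the same subjects. DeLong rather than bootstrap CIs is a choice, logged.
  Orientation: markers where disease lowers the score (atrophy) are negated
  once per contrast so reported AUCs are ≥ 0.5, with the flip recorded.

## Numerical choices

* OLS slopes use the centered closed form (cross-products of deviations);
  with mm³-scale ICVs this keeps residual–ICV correlations below 1e-10 in
  float64, which the acceptance suite asserts for all 51 regions.
* Rounding for printed report tables is half-away-from-zero (1 decimal for
  t, 2 for adjusted p), matching how such tables are conventionally typeset;
  internal values are never rounded.
* Proportions are kept as fractions in (0, 1), never rescaled to percent.
* Gender is encoded as the strings F/M; files are UTF-8 comma-separated with
  "." decimals regardless of locale.

## Limitations

* The generator is Gaussian per cell; real ventricular volumes are
  right-skewed. Matched-subsample non-normality is therefore milder in the
  synthetic world than in practice, which weakens the motivation for the
  Mann–Whitney path there (it is retained regardless).
* The "ICV as covariate in the group model" strategy is intentionally not an
  output mode; only the three treatments above are compared.
* FreeSurfer stats files are not parsed; input is a pre-extracted CSV table
  (a `lh_`/`rh_` hemisphere-averaging helper is included).
* Longitudinal change, non-Gaussian ICV models and image-level simulation
  are out of scope.
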