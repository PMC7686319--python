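# Methods

## Model and estimation

Every tract–metric measure is analyzed with a linear mixed model containing a
single random effect, a per-subject intercept. Estimation is always maximum
likelihood, never REML, because the analysis compares models with different
fixed-effect structures via likelihood-ratio tests (LRTs), which is invalid
under REML. The fitter (`longdti.mixedlm`) exploits the random-intercept
structure directly: given the variance ratio ρ = σ_b²/σ_e², the GLS solution
is an OLS fit of within-subject partially demeaned data (shrinkage
`c_i = 1 − 1/√(1 + n_i ρ)` for a subject with `n_i` scans), so the likelihood
profiles to a one-dimensional function of log ρ that is maximized by bounded
Brent search (absolute tolerance 1e-8, ρ ∈ [e⁻¹⁸, e¹²], with an explicit
boundary comparison at ρ ≈ 0). This makes a fit cost ~1–2 ms, which is what
allows 72-measure model selection and the Monte-Carlo calibration studies to
run routinely. The fitter is cross-validated in the test suite against
statsmodels `MixedLM(reml=False)` on shared data (log-likelihood,
coefficients, and both variance components agree to ≤1e-5).

Numerical details:

* Age is centered at the pooled sample mean before fitting (conditioning of
  the age² term); coefficients are reported on the centered scale. BIC is
  invariant to this choice.
* BIC = −2·logLik + k·ln(N_obs), with N_obs the number of scans and k the
  number of fixed effects plus two variance components. Ties in BIC break
  toward the lower polynomial order.
* On interpolating (noise-free) data the residual sum of squares is floored
  at 1e-30 to keep the log-likelihood finite; coefficients are unaffected.
* Degenerate design columns (single observed sex, scanner or group level)
  are dropped with a logged warning instead of producing a singular design.
* Exact per-scan duplication is **not** an invariance of ML estimation:
  identical scans collapse the residual-variance estimate and hence reweight
  subjects. The exact invariance is subject-level duplication (the likelihood
  doubles, leaving the maximizer unchanged), which is what the tests assert.

## Trajectory testing

The polynomial order (0/1/2) is selected by BIC on the *full* model (group +
interactions + covariates); the same order is then used for both LRTs, which
avoids comparing models of different orders. The interaction LRT drops
group×age (and group×age² when the order is 2; df = 2) from the full model;
the group LRT then drops the group main effect from the interaction-free
model (df = 1). Both statistics are referenced to χ² asymptotics; the null
calibration of this choice is verified empirically (rejection rate at
α = 0.05 within [0.02, 0.09] over 200 replicates). FDR correction uses
Benjamini–Hochberg step-up (via statsmodels `multipletests`), applied across
all 72 measures separately for the group family and the interaction family —
the most conservative reading when the correction family is not dictated by
the design.

## Deviation scores (brain matrix)

Age models for the PLS stage are fitted on exactly the subset that enters the
PLS (single group, typically patients with ≥2 scans), with BIC order
selection among 0–2 and sex/scanner covariates, reusing the trajectory-stage
conventions. Residuals are taken against the **fixed-effects-only**
prediction — including the estimated random intercept would absorb precisely
the subject-level deviation the matrix is meant to carry — and averaged per
subject. Averaging per-scan residuals is algebraically identical to
residualizing the per-subject mean at the mean age for linear curves and
remains well defined for quadratic ones; the mean-age variant is available as
`method="mean_age"`. Subjects missing a measure at every scan are excluded
with a warning.

## PLS correlation

R = YzᵀXz/(n−1) so that entries are Pearson correlations; this scaling leaves
saliences, permutation p-values and bootstrap scores unchanged relative to an
unscaled cross-product and only rescales singular values by a constant.
Dimensional convention: U is 5×5 (behavior saliences in columns), V is 5×72
(brain saliences in rows), L_X = XzVᵀ, L_Y = YzU. Dichotomous risk-factor
columns are z-scored exactly like continuous ones.

* **Sign convention**: each component is flipped so its largest-magnitude
  behavior salience is positive; applied before any bootstrap alignment.
* **Permutation test** (1000 draws by default): rows of Yz are permuted —
  permuting one block is sufficient to break the subject pairing — and the
  k-th largest permuted singular value is compared with the k-th observed
  (rank matching, no Procrustes rotation; adequate when one dominant
  component exists). p = (1 + #{s_perm ≥ s_obs})/(1 + n_perm), so p is never
  below 1/(n_perm+1).
* **Bootstrap** (500 resamples by default): subjects are drawn with
  replacement, both blocks re-standardized, R and its SVD recomputed, and
  each component sign-aligned to the full-sample reference by the dot
  product of its stacked behavior+brain saliences. Resamples in which any
  column is constant (rare risk factors) cannot be standardized and are
  redrawn and counted. Constancy is detected by an exact peak-to-peak test,
  since the floating-point SD of identical values can round to a tiny
  nonzero number.
* Permutation and bootstrap use independent substreams spawned from the run
  seed, so changing n_boot does not perturb the permutation stream.

## Synthetic cohort generator

The generator emulates the accelerated-longitudinal design the analyses
assume; defaults are fixed once and are not tuned per experiment:

* two groups of 100 subjects, first-visit age uniform on 5–35 y; visit count
  1/2/3 with probabilities 0.55/0.40/0.05 (mean 1.5 scans/subject, matching
  ~300 scans from ~200 subjects); intervals Normal(3, 1) y truncated at
  >0.5 y, with visits beyond the age ceiling dropped;
* metric templates near published tract-average magnitudes, with
  diffusivities in μm²/ms so every metric is O(1): FA rises and saturates
  (quadratic), AD/RD fall linearly, MD falls with curvature; per-tract
  intercepts spread ±5% so tracts are distinguishable;
* deletion-group offsets: FA +0.012, AD/RD/MD −0.020 (the
  increased-FA/decreased-diffusivity phenotype direction), no group×age
  interaction;
* subject-level SDs 0.020–0.030 and scan-level SDs 0.012–0.020 per metric;
  sex/scanner shifts of a few thousandths; scanner assigned per scan with
  P(B) = 0.37;
* risk-factor prevalences (UHR 0.26, preterm 0.31, low IQ 0.33, decline
  0.41, anxiety 0.54) matching the subgroup proportions of a ~39-patient
  deletion cohort, drawn as independent Bernoulli (complete data; no
  inter-factor dependence is imposed);
* the latent component: risk factors are z-coded against their prevalences
  and projected on unit behavior weights (default pattern: strong +UHR,
  −preterm, −low IQ, near-zero decline/anxiety) to give each subject a
  latent score; the subject's every scan is shifted by
  `latent_effect · σ_b(metric) · score · w_brain[measure]` with unit-norm
  brain weights (default: +FA, −diffusivities, uniform across tracts).
  `latent_effect` is therefore in units of the subject-level SD, and the
  injection is a subject-level constant so residualize-then-average recovers
  it. Default `latent_effect` = 1.

What the generator does **not** emulate: image/tractography artifacts, head
motion, realistic inter-tract covariance beyond the planted rank-1
structure, missing data, or scanner effects beyond an additive shift.
Passing tests therefore demonstrate the statistical machinery is correct and
calibrated under the assumed model, not that real acquisitions satisfy those
assumptions.

## Validation studies and problem sizes

The end-to-end statistical tests use problem sizes chosen as a compromise
between Monte-Carlo resolution and routine runtimes: permutation-test
calibration uses 200 cohorts of 200 patients with 200 permutations each;
planted-component recovery 100 cohorts at `latent_effect` = 1.5; LRT
calibration 200 null replicates (plus 20 power replicates at an offset of 3
residual SDs); BIC recovery 100 replicates across the three generating
orders. The Monte-Carlo studies run on a 6-tract list (24 measures) — the
calibration properties do not depend on the measure count, and the
72-measure bookkeeping is asserted separately at full width.

One caveat quantified by the recovery tests: the population correlation
between the projected deviations `X·w_brain` and the planted subject scores
is `d/√(d² + σ_eff²)` with σ_eff ≈ 1.2 (deviation noise per column relative
to the injection unit), so per-subject score recovery exceeds 0.9 only for
strong effects (`latent_effect` ≳ 2.5), whereas salience-vector recovery
(which averages noise across subjects) reaches |r| ≥ 0.9 already at 1.5
SDs. In-sample latent correlations `r_k` are optimistically biased at small
n with 72 measures — the same caveat that applies to the real-data analyses
this package models.

## Known limitations

* Random slopes, spline trajectories and scanner harmonization beyond a
  fixed-effect covariate are out of scope.
* χ² reference distributions for the LRTs are asymptotic; no
  parametric-bootstrap alternative is implemented.
* The permutation statistic is the raw singular value; alternatives
  (explained fraction, Procrustes-aligned values) would differ marginally
  when one component dominates.
* Residualization is in-sample (the same subjects fit the age curves and
  enter the PLS), mirroring the analysis design the package reproduces; no
  cross-validated variant is provided.
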