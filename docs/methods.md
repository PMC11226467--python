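# Methods

## The voxelwise model

Tissue outcome is modelled per voxel: for each voxel *v* inside the GLM
mask, a logistic regression is fitted over the patients whose perfusion
coverage includes *v*, with the follow-up infarct label at *v* as outcome.
Spatial information is therefore encoded implicitly — each voxel has its
own coefficient vector — rather than through explicit spatial features, at
the cost of fitting tens of thousands of small regressions. The predictors
are the smoothed imaging values at the voxel (NCCT, CT-A source, CBV, CBF,
Tmax), scalar clinical covariates (age, sex, NIHSS, onset-to-imaging time),
recanalization success (mTICI > 2a), and recanalization × {CBV, CBF, Tmax}
interactions; 14 columns in the full model. Smoothing applies to predictors
only, never to outcome labels.

**Eligibility (GLM mask).** A voxel is fitted only if it is covered by at
least 10 × (number of model parameters) patients and lesioned in at least
5% of the covered patients. The mask is rebuilt whenever the parameter
count or the training split changes, because the rule depends on both.
Voxels in a patient's exclusion mask (old territorial lesions) are removed
from that patient's coverage before any counting.

**Fitting.** Maximum likelihood via IRLS with deviance-guarded step
halving, convergence at |Δdeviance| < 1e-8, at most 100 iterations, and an
optional ridge stabilizer (default 0). Separation is detected when a
coefficient reaches |β| = 25 on the standardized scale; such voxels keep
their clipped estimates but carry a cleared convergence flag — they are
flagged, never silently dropped. A vectorized implementation fits all mask
voxels simultaneously (batched Newton steps with per-voxel step halving and
an active set); a scalar reference implementation is kept and the test
suite pins the two against each other and against independent generic
optimizers.

**Standardization and interactions.** Continuous design columns are
standardized with training-cohort mean/SD per voxel, which conditions IRLS
and provably leaves t-values, pseudo-R² and predicted probabilities
unchanged. Interaction columns are formed as products of the *transformed*
parent columns (binary recanalization × centered/scaled map value). With a
raw-product parametrization the interaction column is almost collinear with
the recanalization main effect whenever one recanalization arm dominates
(correlation ≈ √recan-fraction ≈ 0.91 at 83% recanalized), which inflates
standard errors and makes per-voxel coefficients uninterpretable; centering
the parent removes this while spanning the same model space. The
standardization constants are stored per voxel in the fitted model, so
predictions are exact and true generating coefficients can be mapped into
the fitted basis exactly (`raw_to_standardized_beta`).

**Dual prediction.** For any patient the fitted model evaluates the linear
predictor twice — recanalization forced to 1 and to 0 — giving a
success-scenario and a failure-scenario infarction-probability map on
coverage ∩ GLM mask minus exclusions. The patient's actual recanalization
status is never used at prediction time. The predicted core is the
binarized success map; the penumbra ("thrombectomy mismatch") is
`failure AND NOT success` after binarization.

## Model selection

Step-down elimination starts from the full 14-parameter model. At each
step, the model is fitted in every cross-validation fold at the
intermediate smoothing level (FWHM 9 mm) and the candidate with the lowest
mean pseudo-R² — averaged without weights over mask voxels and folds — is
removed. The pseudo-R² of a coefficient is t²/(t² + dfe), the standard
partial variance-explained transform of its t-value; it is bounded in
[0, 1], monotone in |t|, and isolated in one function so an alternative
definition can be swapped in. Two constraints shape the order: the
parameters of the thresholding baseline (intercept, CBF, Tmax,
recanalization) are protected and never removed, and an interaction must
leave before either of its main effects. Ties break by the canonical
predictor order and are logged. At every model size the current model is
cross-validated at each smoothing level in the sweep (default 0/5/9/13 mm)
with out-of-fold predictions binarized at the fold-training in-sample
cutoff; the final (model, FWHM) choice minimizes the cross-validated mean
absolute volume difference, and a whole-training in-sample cutoff is then
calibrated for it (per-step whole-training cutoffs can be recorded on
request).

**Cutoff calibration.** The binarization cutoff minimizes the mean over
patients of |predicted volume − true volume| in ml, scanned exhaustively
over all observed in-sample risk values plus {0, 1}; ties resolve to the
smallest cutoff. Predicted volume is a non-increasing step function of the
cutoff, so the scan over breakpoints is exact.

## Thresholding baseline

The clinical single-parameter rules — ischemic core where relative CBF
falls below a threshold (literature default 30% of the unaffected
hemisphere), hypoperfused tissue where Tmax exceeds a threshold (default
6 s) — define the baseline's form; the actual thresholds and its smoothing
level are calibrated by the same cross-validated volume-error objective as
the logistic cutoff, scanning observed map values. Both rules use strict
inequalities. Calibration is stratified by actual recanalization status:
the CBF_rel rule (a core surrogate) is trained on patients with successful
recanalization, whose final lesion approximates the core, and the Tmax
rule on patients without recanalization. CBF_rel is CBF divided by the
mean CBF over covered voxels of the unaffected hemisphere (mirror half of
the grid); the mean (rather than median or a vendor definition) is a
choice isolated behind one function. For ROC analysis the baseline's
continuous score is the parameter map itself (−CBF_rel under the success
scenario, Tmax under failure).

## Evaluation

Per patient, restricted to coverage ∩ GLM mask minus exclusions, under the
patient's *actual* recanalization scenario: absolute volume difference
(ml, the primary metric), ROC AUC of the risk map against the lesion mask
(Mann-Whitney formulation, ties counted ½ — per-patient, threshold-free),
and Dice overlap of the binarized prediction (both-empty defined as 1 and
flagged). Methods are compared with two-sided Wilcoxon signed-rank tests;
cohort tables report mean and normal-approximation 95% CIs (mean ±
1.96 SE). Mismatch analysis computes, per patient, compartment and method,
the tissue-to-infarct conversion rate |compartment ∩ lesion| /
|compartment| (undefined for empty compartments; such patients are
excluded listwise from the ANOVA, with a logged count), and feeds the
2 (compartment) × 2 (method) × 2 (recanalization, between-patients) mixed
ANOVA. With all factors at two levels every effect reduces to a test on
per-subject contrast scores; between-group imbalance is handled with
unweighted (Type-III-style) means, sphericity is moot for 2-level within
factors, and the implementation is verified against a closed-form balanced
cell-means decomposition and against pingouin on the collapsed
1-within × 1-between sub-design.

**Statistical tests.** Wilcoxon signed-rank: exact two-sided p by
enumeration of sign assignments when ≤ 12 nonzero differences (valid with
midranks), otherwise tie-corrected normal approximation with continuity
correction; all-zero differences give p = 1, flagged. Rank-sum: exact
enumeration of rank assignments for ≤ 12 pooled observations, otherwise
tie-corrected normal approximation. Fisher's exact: two-sided p as the sum
of hypergeometric point probabilities ≤ the observed one (1e-12 relative
slack); zero margins give p = 1, flagged.

## Phantom cohorts

Because the underlying patient data cannot be shared, validation rests on
synthetic cohorts with a known generative model. Each phantom patient has
a spherical core-plus-penumbra deficit with smooth logistic radial
transitions (2 mm transition width) in the affected hemisphere; Tmax rises
and CBF/CBV fall from background plateaus (Tmax 0.5 → 8 → 12 s; CBF 100 →
45 → 25%; CBV 100 → 90 → 40% of contralateral), NCCT/CT-A show a small
core hypodensity. Per-case heterogeneity emulates real cohorts: lesion
radii scale by U(0.8, 1.25), deficit depth by a shared severity factor
U(0.75, 1.25) with an extra independent U(0.8, 1.2) factor per perfusion
map (the maps co-vary but are not copies of each other, keeping the
per-voxel design identifiable), centers jitter by ±2 mm, and the NCCT/CT-A
hypodensity depth is drawn independently of the perfusion severity, so the
nuisance maps are weakly informative marginally but carry no information
conditional on the perfusion maps. Noise is a spatially smooth Gaussian
random field (FWHM 6 mm, exact marginal SD), matching the smooth error
structure of deconvolved perfusion maps; white noise would be annihilated
by the 9-mm analysis smoothing and would artificially break the link
between generated and analysed maps. Coverage is the lesion ball plus an
8-mm margin together with its mirror ball (the contralateral reference for
CBF_rel). Infarct labels are Bernoulli draws from the logistic model
applied to the *realized* (noisy) maps, so refitting the generating
predictor set is a correctly specified estimation problem.

Default true coefficients (raw scales; log-odds units):
intercept 2.0, CBV −0.03 /%, CBF −0.025 /%, Tmax 0.2 /s,
recanalization +1.0, recan×CBV −0.06, recan×CBF +0.04. These give
clinically shaped probabilities — core ≈ 0.93 (no recanalization) and
≈ 0.90 (with), penumbra ≈ 0.44 vs ≈ 0.06, background ≈ 0.03 — while
keeping every informative predictor's per-voxel standardized effect in
roughly [0.4, 2.2], the regime where maximum likelihood at 200-patient
cohorts is close to its asymptotics; this balance is what makes the
phantoms usable both for coefficient-recovery and for selection-recovery
studies. Covariate distributions follow typical thrombectomy cohorts (age
74 ± 12, 57% female, NIHSS 2-30, onset-to-imaging 45-480 min,
recanalization fraction 0.83). Clinical covariates and the
recan × Tmax interaction have zero generating weight.

**What the phantoms do not emulate:** CT physics and reconstruction
artifacts, anatomy (no tissue classes, vascular territories, or realistic
lesion shapes), registration error, delineation noise in the ground truth,
and between-site acquisition differences. Passing recovery tests therefore
demonstrates correctness of the estimation and selection machinery under
the assumed generative model, not clinical performance on real data.

## Validation-study design and problem sizes

- *Coefficient recovery*: one default cohort of n = 200 on the 32³ grid,
  fitted with the generating 7-predictor set at FWHM 0. Median
  standardized bias per coefficient stays below half a standard error.
  Pooled 95% Wald-interval coverage across mask voxels sits near 0.97:
  collinearity among the perfusion maps and the 83/17 recanalization
  imbalance inflate observed-information standard errors mildly, a
  finite-sample property of Wald intervals at such designs (confirmed by a
  fixed-design Monte Carlo against an independent optimizer), not an
  estimator defect.
- *Step-down recovery*: ten replicate cohorts of n = 180 on a 16³ grid
  (radii 5/10 mm) with a balanced recanalization arm (fraction 0.5).
  Balance is deliberate: it is the designed condition for validating the
  selection algorithm, since the interaction t-values that drive
  elimination lose most of their power under heavy arm imbalance. The
  success criterion is that all seven conditionally-null predictors leave
  before any informative one.
- *Threshold recovery*: 24 noiseless phantoms whose lesions follow the
  deterministic rules CBF_rel < 35% (recanalized) and Tmax > 6 s
  (otherwise); calibration must recover both values to within one observed
  map-value step.
- *End-to-end evaluation*: train n = 120 / test n = 40 on a 24³ grid,
  logistic model at FWHM 5 vs the calibrated baseline.

These sizes are the package's chosen desk-scale study conditions; all
randomness is seeded and every study is reproduced by
`scripts/acceptance.py`.

## Numerical and convention choices

- Kernel truncation at 4σ; mask-aware (renormalized) smoothing so values
  outside coverage never bleed in; FWHM 0 is the identity.
- Hemispheres split at the mid-sagittal plane of the grid (axis 0);
  occlusion side comes from the manifest.
- Masks are uint8 {0, 1}; volumes float32; voxel volume in ml is the
  product of voxel sizes in mm³ / 1000.
- Lesion voxels outside coverage are dropped at load time with a logged
  count; lesion ⊆ coverage afterwards.
- mTICI grades 2b/2c/3 count as successful recanalization.
- Per-case RNG streams derive from (seed, case index), so cohorts are
  order-independent.
- Out-of-fold integrity is enforced by training-set fingerprints; scoring
  a training patient requires an explicit in-sample flag.

## Known limitations

- Wald-based pseudo-R² loses power under strong predictor collinearity
  and near-separation; at desk scale this makes elimination margins thin
  (see the balanced-arm design above). The original selection procedure
  shares this property.
- Whether the historical cutoff used for cross-validated metrics was
  fold-specific or whole-training is ambiguous; both are computed and the
  fold-training cutoff is used for out-of-fold metrics.
- The contralateral CBF reference uses the hemisphere mean; vendor
  definitions differ.
- No spatial regularization across voxels; neighbouring fits share data
  but not parameters.
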