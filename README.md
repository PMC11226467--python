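# voxlogit

Voxelwise logistic tissue-outcome prediction for acute ischemic stroke
patients undergoing mechanical thrombectomy.

Given co-registered multimodal CT of a patient with a proximal
anterior-circulation vessel occlusion — non-contrast CT, CT-angiography
source images and the perfusion parameter maps CBV, CBF and Tmax — plus
basic clinical covariates, the package predicts which brain tissue will be
infarcted on follow-up imaging. It is aimed at researchers working on
perfusion-based patient selection who want a transparent, fully inspectable
alternative to vendor black boxes, with a matched single-parameter
thresholding baseline and a complete evaluation suite.

## The model

One independent ("mass-univariate") logistic regression is fitted at every
eligible voxel *v* over the training patients *i* whose perfusion coverage
includes that voxel:

```
logit P(infarct_iv = 1) = β0v + Σk βkv · x_ikv
```

The full predictor set has 14 terms: intercept; the five smoothed imaging
values at the voxel (NCCT, CT-A, CBV, CBF, Tmax); age, sex, NIHSS,
onset-to-imaging time; recanalization success (mTICI > 2a); and the
interactions of recanalization with CBV, CBF and Tmax. Because
recanalization is a *training input*, a fitted model predicts **two** risk
maps for a new patient — one assuming successful and one assuming failed
recanalization. Binarizing both at a cutoff calibrated to minimize the mean
absolute volume error yields the predicted ischemic core (success map) and,
as `failure AND NOT success`, the "thrombectomy mismatch" — the
operational penumbra.

Around the estimator the package provides:

- **`phantom`** — synthetic patient cohorts with a known generative
  voxelwise logistic model (spherical core/penumbra perfusion deficits,
  smooth noise fields, clinical covariates), so every downstream stage is
  testable without patient data;
- **`imaging`** — NIfTI I/O, mask-aware Gaussian smoothing at configurable
  FWHM, relative CBF (% of the unaffected hemisphere), mask bookkeeping;
- **`glm`** — the per-voxel IRLS logistic fitter (vectorized across
  voxels), GLM eligibility mask (coverage ≥ 10× parameters, lesion rate
  ≥ 5%), t-values, pseudo-R², dual risk-map prediction;
- **`selection`** — cross-validated step-down elimination by mean
  pseudo-R² with a protected core (intercept, CBF, Tmax, recanalization),
  a smoothing sweep (0/5/9/13 mm), and cutoff calibration;
- **`baseline`** — the clinical thresholding predictor (core: CBF_rel < θ;
  hypoperfusion: Tmax > θ) with cross-validated thresholds;
- **`metrics`** — absolute volume difference, per-patient ROC AUC, Dice,
  mismatch compartments, tissue-to-infarct conversion rates, Wilcoxon
  signed-rank/rank-sum, Fisher's exact test, and the mixed
  compartment × method × recanalization ANOVA.

## Worked example

```python
from voxlogit import (PhantomParams, generate_case, PredictorSet,
                      fit_voxelwise, predict_risk_maps, calibrate_cutoff,
                      eval_mask, make_folds, calibrate_thresholds,
                      evaluate_cohort)
from voxlogit.phantom import DEFAULT_TRUE_BETA

params = PhantomParams(shape=(24, 24, 24), core_radius_mm=7, penumbra_radius_mm=12,
                       coverage_margin_mm=6, recan_fraction=0.6, seed=3)
train = [generate_case(params, i) for i in range(120)]
test  = [generate_case(params, 1000 + i) for i in range(40)]

model = fit_voxelwise(train, PredictorSet(tuple(DEFAULT_TRUE_BETA), fwhm=5.0))
risks, truths = [], []
for case in train:
    support = eval_mask(case, model.glm_mask)
    pair = predict_risk_maps(model, case)
    risks.append(pair.scenario(case.recanalization)[support])
    truths.append(case.lesion.astype(bool)[support])
cutoff = calibrate_cutoff(risks, truths, voxel_vol=0.008)
thresholds, _ = calibrate_thresholds(train, make_folds(len(train), 5, seed=1),
                                     fwhm_list=[0.0, 5.0], glm_mask=model.glm_mask)
result = evaluate_cohort(model, cutoff, thresholds, test)
print(f"cutoff = {cutoff.value:.3f}")
print(result["summary"].round(2).to_string(index=False))
```

prints (summary values in ml for volume error, % for AUC and Dice):

```
cutoff = 0.366
      method           metric  mean ci_low ci_high p_vs_other
    logistic  abs_vol_diff_ml  0.38   0.28    0.48       0.00
thresholding  abs_vol_diff_ml  1.20   0.94    1.46       0.00
    logistic              auc 83.47  82.27   84.68       0.00
thresholding              auc 84.94  83.75   86.13       0.00
    logistic             dice 52.22  48.58   55.85       0.65
thresholding             dice 47.91  41.72   54.11       0.65
```

The binarization cutoff lands well below the naive 0.5 (0.37 here) because
infarcted voxels are the minority class; the logistic model beats the
calibrated thresholding baseline on volumetric error, while topographic and
spatial accuracy are comparable at this phantom scale. `result["anova"]`
holds the conversion-rate ANOVA (compartment × method × recanalization),
and `result["mismatch"]` the per-patient core/penumbra volumes and
conversion rates.

A command-line interface mirrors the pipeline
(`voxlogit simulate|fit|select|calibrate|predict|evaluate`); every command
writes its resolved configuration and hash next to the outputs so runs are
reproducible.

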