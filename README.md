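# mpmri

Multiparametric MRI analysis for predicting pathological complete response
(pCR) to neoadjuvant chemotherapy in breast cancer — a tested, reusable
implementation of the full study pipeline, exercised end-to-end on
synthetic cohorts with known ground truth.

Only 10–30% of breast-cancer patients achieve pCR after neoadjuvant
chemotherapy, and pCR is a strong surrogate for survival, so predicting it
from *pre-treatment* imaging matters clinically. The pipeline implemented
here asks whether imaging features — semi-quantitative DCE perfusion
biomarkers, IVIM diffusion parameters and IBSI-style radiomics — improve
pCR prediction over clinical variables alone, and whether any single
biomarker separates responders from non-responders.

## What it computes

**Perfusion (DCE).** Per voxel in the tumour mask, from the relative-
enhancement concentration proxy c(t) = (S(t) − S0)/S0:
iAUC60 = ∫₀⁶⁰ c(t) dt (trapezoid, interpolated endpoints), initial slope
max Δc/Δt up to the peak, peak = max c, and time-to-peak (TTP), all
referenced to injection start.

**Diffusion (DWI).** ADC from the log-linear fit of S(b) = S0·e^(−b·ADC)
over b = 0, 150, 400, 1000 s/mm², and the IVIM bi-exponential
S(b) = S0·[f·e^(−b·D*) + (1 − f)·e^(−b·D)] via the segmented fit
(D and intercept from b ≥ 200; f from the intercept; D* by bounded 1-D
least squares, D* ≥ D).

**Radiomics.** 251 imaging features per patient: 8 biomarkers × 5 ROI
statistics, plus first-order, intensity-histogram, GLCM, GLRLM, GLSZM and
NGTDM features on the ADC and iAUC60 maps (fixed-bin-number
discretisation, Ng = 32). Every texture feature is verified against an
exhaustive-enumeration oracle.

**Statistics and models.** Two-step feature selection (variance ≤ 0.1
dropped, then |r| > 0.8 pairs resolved to the higher-variance member);
pooled-variance t-tests per feature; class balancing (all 12 responders +
12 random non-responders); leave-one-out cross-validation of ten
classifier families (K-NN, DT, RF, AdaBoost, GBoost, GNB, LDA, QDA, MLP,
LR) on imaging, clinical and combined feature sets, reported as confusion
matrices with accuracy / sensitivity / specificity / error rate.

The synthetic generator (`mpmri.synthetic`) draws two-group cohorts whose
ground-truth parameters follow the reported responder/non-responder
shifts: shorter TTP (187.47 ± 51.27 s vs 237.67 ± 79.20 s), smaller
voxel-wise D* dispersion (0.006 vs 0.007 mm²/s) and smoother ADC texture
in responders. See `docs/methods.md` for models, assumptions and design
choices.

## Worked example

The numbered drivers under `analysis/` run the study on a simulated
58-patient cohort (12 pCR / 46 non-pCR) and write tables to `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_extract_features.py --seed 0
python analysis/03_group_statistics.py
python analysis/04_select_features.py --seed 0
python analysis/05_compare_models.py --seed 0
```

At seed 0 this prints, among others:

```
simulated 58 patients (12 pCR / 46 non-pCR)
extracted 251 imaging + 4 clinical features for 58 patients in 30 s
88 of 251 imaging features differ between groups at p < 0.05 (no multiple-testing adjustment)
balanced cohort: 24 patients (12 per class)
selection (min-max scaled variance): 251 -> 4 features (241 low-variance, 6 correlated removed)
selection (raw-units variance):      251 -> 28 features
best classifier per configuration:
  imaging: gnb accuracy 95.8%  (FN 1, FP 0)
  clinical: lda accuracy 58.3%  (FN 5, FP 5)
  combined: gnb accuracy 95.8%  (FN 1, FP 0)
```

Reading this: the generator plants genuine group differences in TTP, D*
dispersion and ADC texture, and the pipeline finds them — TTP and
ADC-texture features dominate the significant set; the weakly informative
clinical flags alone predict little better than chance on 24 patients,
while configurations that include imaging recover the signal almost
perfectly. The two selection counts show how strongly the (unstated in
the source study) variance-threshold scaling drives the retained-feature
count. Accuracies are LOOCV estimates on one balancing draw;
`05_compare_models.py --n-seeds 25` reports their dispersion across
draws.

A thin CLI mirrors the drivers for single studies:
`mpmri simulate`, `mpmri extract perfusion|diffusion`, `mpmri compare`
(see `--help`).

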