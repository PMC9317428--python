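# Methods

This package re-implements, as a tested pipeline over synthetic data, a
multiparametric-MRI analysis for predicting pathological complete response
(pCR) to neoadjuvant chemotherapy in breast cancer: voxel-wise
perfusion/diffusion biomarker extraction, IBSI-style radiomics, two-step
feature selection, per-feature group statistics, and a balanced
leave-one-out comparison of ten classifier families over imaging, clinical
and combined feature sets. The original cohort is private, so a synthetic
generator with known ground truth stands in for the data; every claim the
test suite makes is a property of the methods, not a reproduction of the
clinical numbers.

## Synthetic cohort generator

Each patient comprises a 4D DCE series, DWI volumes at b = 0, 150, 400,
1000 s/mm², a spherical tumour mask (digital sphere, default radius 4
voxels ≈ 257 voxels, 1.2 mm isotropic spacing), four binary clinical
covariates and a pCR label. Group-valued parameters are `(responders,
non-responders)` pairs.

**DCE forward model.** Voxel concentration follows a piecewise-linear
uptake curve: zero until contrast onset `t0` (drawn U(5, 15) s), a linear
rise, a *symmetric* triangular apex of half-width 40 s centred at
(TTP, peak), then a washout 4× slower than the apex slope — the rapid rise
with delayed washout typical of malignant lesions. The apex is symmetric
over exactly one temporal-resolution unit on purpose: it guarantees that
the argmax of the noiselessly sampled curve is the grid point nearest the
true peak, so time-to-peak is recovered to within half the 40 s temporal
resolution for *every* sampling phase. A gamma-variate (also provided,
and used as the smooth-curve oracle in tests) cannot give that guarantee:
its near-peak skew shifts the sampled argmax by ≈ 133/width s beyond the
half-resolution bound in a narrow phase window, however wide the curve.
Signal is S(t) = S0·(1 + c(t)) with additive Gaussian noise (default SD
2 intensity units on a baseline of 100).

**Acquisition window.** The emulated protocol keeps the clinical 40 s
temporal resolution with injection starting 20 s after the first dynamic
ends. The default is 14 dynamics rather than 6: the calibrated TTP
distributions (below) extend far beyond a 6 × 40 s window, and the quoted
total sequence duration (7 min 42 s) likewise implies longer effective
coverage. A strict 6-dynamic protocol is available via `n_dynamics=6`.

**DWI forward model.** The IVIM bi-exponential
S(b) = S0·[f·e^(−b·D*) + (1 − f)·e^(−b·D)] with Rician noise of scale
S0/SNR (magnitude MRI), default SNR 50. Voxel D* is floored at
0.015 mm²/s (centre 0.03 ± 0.003): pseudo-diffusion slower than that
leaves the perfusion compartment undecayed at b ≥ 400 and would bias any
segmented fit; reported breast-tumour D* values sit in the 0.01–0.1 mm²/s
range.

**Group calibration.** Responders draw a patient-level TTP centre from
N(187.47, 51.27²) s and non-responders from N(237.67, 79.20²) s (clipped
to the acquisition window), with symmetric within-patient voxel jitter
(SD 15 s); voxel-wise D* dispersion is N(0.006, 0.002²) vs
N(0.007, 0.002²) mm²/s. ADC-map texture is controlled by a homogeneity
parameter in [0, 1] (default 0.7 vs 0.35): a spatially correlated field
plus a low-ADC component whose depth scales with (1 − homogeneity),
producing the negatively skewed maps — and more negative GLCM cluster
shade — of heterogeneous tumours. Pure diffusion D (1.0 ± 0.1 × 10⁻³
mm²/s), perfusion fraction f (8 ± 2%) and peak enhancement (1.0 ± 0.2 mM)
carry no group shift, as no group difference is reported for them.
Clinical flags are Bernoulli draws with mild group-conditional imbalance
(stage III: 0.35 vs 0.55; grade III: 0.60 vs 0.40; premenopausal 0.45 vs
0.40; age > 40: 0.80 both), making the clinical-only model weakly
informative by design.

**What the generator does not emulate:** scanner physics, partial-volume
and motion effects, arterial input variability, irregular tumour shapes,
correlated multi-focal lesions, and any coupling between clinical
covariates and imaging parameters. Passing tests therefore demonstrate
correctness of the extraction/selection/validation machinery and
calibration of its statistics under the stated models — not clinical
performance on real data.

## Perfusion biomarkers

Concentration proxy: c(t) = scale·(S(t) − S0)/S0 with S0 the mean of
pre-injection dynamics and scale a configurable constant (default 1) —
no T1-mapping conversion is attempted; TTP, slope ratios and all texture
features are invariant to the scale. Biomarkers per masked voxel:

- **peak** — maximum over post-injection samples [mM];
- **TTP** — time of the *first* sample attaining that maximum, from
  injection start (first attainment breaks plateau ties) [s];
- **iAUC60** — trapezoidal integral over [injection, injection + 60 s],
  linearly interpolating both endpoints, reported in mM·s (a
  concentration–time integral carries mM·s even where tables print mM);
- **initial slope** — maximum forward difference between consecutive
  samples from contrast onset (first sample above 5% of peak,
  configurable) through the peak sample [mM/s].

At the clinical 40 s sampling, the trapezoid over the 2–3 early samples
differs from the continuous-truth integral by 10–25% for any
implementation (sparse convex rise); the forward–inverse acceptance check
therefore verifies the ≤ 1% agreement on a densely sampled (2 s) series,
where trapezoid error is discretisation-limited, and verifies TTP
recovery at the 40 s protocol.

## Diffusion model fitting

ADC is the least-squares slope of −ln S(b) vs b over all four b-values
(deterministic, closed-form; perfusion contamination makes ADC ≥ D).
IVIM uses the community-standard segmented fit with b_threshold =
200 s/mm²: D and intercept from the log-linear fit over b ∈ {400, 1000};
f = 1 − intercept/S(0) (clipped to [0, 1], reported in %); D* by bounded
scalar least squares on the full curve with D, f fixed, constrained to
[D, 0.5] mm²/s. A full 4-parameter nonlinear fit is ill-posed at four
b-values. With only two high-b points, per-voxel dispersion of D̂ at
SNR 50 is irreducibly ≈ 11% SD (first-order propagation); accuracy claims
are therefore stated as bias bounds — the median of 500 voxel estimates
recovers D within 5% and f within 20% — and D* accuracy is deliberately
not asserted (it is the least reproducible IVIM parameter). Voxels with
non-positive signals or non-convergent fits are excluded and tallied by
cause.

## Radiomics

Fixed-bin-number discretisation (Ng = 32 by default) between the masked
minimum and maximum makes all texture features invariant to affine
intensity rescaling, which the oracle tests exploit. Families, computed
per IBSI-style definitions on the ADC and iAUC60 maps:

- **GLCM** (25 features): pair counts at distance 1 pooled over the 13
  unique 3D directions, symmetrised, then normalised ("merged"
  aggregation — one value per feature);
- **GLRLM** (16): maximal equal-level runs pooled over the same 13
  directions; run percentage divides by 13 × n_voxels since each
  direction's runs partition the mask;
- **GLSZM** (16): 26-connected equal-level zones;
- **NGTDM** (5): 26-neighbourhood mean absolute gray-tone differences;
- **first-order** (20, + total energy on ADC) on raw values and
  **intensity-histogram** (23) on discretised levels.

Entropies use log₂ with 0·log 0 = 0. Degenerate fallbacks are explicit:
single-level correlation and information correlations are 0, inverse
variance sums over i ≠ j only, NGTDM coarseness is capped at 10⁶ when all
neighbourhood differences vanish, contrast/busyness/strength are 0 when
their denominators vanish, and skewness/kurtosis of a constant region are
0. Cluster shade is stored signed (level reflection i → Ng+1−i flips its
sign exactly); study-table-style reports print its absolute value.

The per-patient imaging feature count is fixed at 251 = 40 ROI statistics
(8 biomarkers × {mean, median, SD, p25, p75}) + 211 radiomics. The exact
panel membership is package configuration (105 features per map, plus
total energy on ADC only); 211 being odd, the two map panels cannot be
identical, and the asymmetry is a bookkeeping choice. Every feature is
checked against an independent exhaustive-enumeration oracle written as
plain loops.

## Feature selection and group statistics

Two steps, applied to the imaging block of the balanced cohort:

1. **Variance filter:** drop columns with sample variance ≤ 0.1
   (inclusive). A raw-units threshold is meaningless across features
   spanning mm²/s (~10⁻³) and seconds (~10²), so columns are min–max
   scaled to [0, 1] first; this is the single most consequential unstated
   choice, so it is a config switch (`minmax` | `raw`), and the analysis
   driver reports the retained count under both (e.g. 251 → 4 vs
   251 → 28 at the default seed).
2. **Correlation filter:** among each pair with |Pearson r| > 0.8, drop
   the lower-variance column, processing pairs in descending |r| (ties:
   name order) — deterministic and idempotent. The keep rule compares
   *raw* variance: proportional duplicates (Y = kX) must resolve to the
   larger-scaled copy, which any scale-invariant variance measure would
   leave tied.

Group comparison is the two-sample pooled-variance Student t-test,
two-sided, per feature, with no multiple-testing adjustment (the reports
flag this); group means are reported with sample SDs. Percentiles
throughout use linear interpolation between order statistics.

## Classifier comparison

Balancing keeps every responder plus an equal-size uniform random subset
of non-responders (12 + 12 by default). Leave-one-out cross-validation
runs n folds of test size 1; any standardisation is fitted on the n − 1
training rows only (fold hygiene is instrumented and tested). The ten
families use fixed, seeded small-sample defaults — K-NN (k = 5), decision
tree (depth 3), random forest (30 × depth 3), AdaBoost (30), gradient
boosting (30 × depth 2), Gaussian naive Bayes, LDA (lsqr solver with
automatic shrinkage — plain LDA is undefined with more features than the
~12 samples per class), shrinkage QDA (Σ_c = (1−α)S_c + α(tr S_c/p)I,
α = 0.5, implemented here because an unshrunk QDA is singular at this
sample shape), MLP (one hidden layer of 8), logistic regression. Scale-
sensitive learners (K-NN, MLP, LR, LDA, QDA) get per-fold z-scoring; tree
ensembles run unscaled. No hyperparameter tuning is performed: the
package's claims are ordering properties between configurations, not
absolute accuracies. Metrics use pCR as the positive class: accuracy,
sensitivity, specificity, error rate (= 100 − accuracy), with
zero-denominator ratios reported as unavailable rather than 0. Best
classifier per configuration is chosen by accuracy, ties broken by fewer
false negatives, then name.

Because one draw of 12 from 46 is high-variance, a single balancing draw
(the study's protocol) is the default and a multi-seed mode reports
dispersion across draws. Note that feature selection runs once on the
balanced cohort before cross-validation — the study's protocol, retained
deliberately; fold-internal selection would be the leakage-free variant.

**Null behaviour of LOOCV.** On balanced sets, removing the held-out case
leaves its class in the training minority, biasing prediction *against*
it; mean LOOCV accuracy under label permutation therefore sits slightly
below 50% (measured ≈ 46–50% depending on the learner). The leakage guard
is accordingly one-sided: no classifier's permutation-mean accuracy may
exceed chance by more than sampling error.

## Problem sizes and numerics

Test and acceptance runs use the study-scale cohorts directly (58
patients for extraction and statistics; 24 for the balanced grid; 500
voxels for noise-recovery medians; 200 cohort seeds for the detection-
rate check; 1000 simulated features for type-I calibration; 50 balancing
seeds for the configuration-ordering check). D* optimisation uses
bounded Brent with 10⁻⁹ tolerance; GLCM normalisation is validated to
10⁻⁸; oracle equivalence is asserted to 10⁻¹⁰ relative. All randomness
flows from explicit seeds through `numpy.random.SeedSequence`, making
cohorts bit-reproducible.

## Known limitations

- Synthetic geometry (spherical masks, uniform background) is far simpler
  than segmented tumours; texture features on real lesions have shape-
  coupled behaviour the tests do not probe.
- The concentration proxy is relative enhancement, not quantitative
  gadolinium concentration; iAUC60 and peak are therefore in proxy units.
- D* estimates at four b-values are usable only distributionally; their
  voxel-wise dispersion feature inherits fitting noise.
- The 251-feature panel membership and the variance-filter scaling are
  documented assumptions, not established facts about the original
  analysis.
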