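# Methods

`plaque_radiomics` reimplements a radiomic workflow for discriminating
acute/sub-acute symptomatic from asymptomatic basilar-artery plaque on
high-resolution vessel-wall MRI (HR-MRI), together with a synthetic cohort
generator that makes the whole pipeline exercisable end-to-end without
patient data. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Conventional plaque metrics

All conventional measurements operate on a single analysed 2D cross-section
per patient (the slice with maximal plaque area in the clinical protocol):

* **Plaque burden** `(1 − lumen area / outer-wall area) × 100 %`.
* **Minimal luminal area (MLA)**, mm². The source table labels the column
  mm³; it is an area and is treated as such.
* **Degree of stenosis**, WASID-style on circle-equivalent diameters:
  `(1 − √(A_sten/A_ref)) × 100 %`, with the reference lumen area supplied by
  the caller (the generator simulates a proximal normal segment).
* **Intraplaque haemorrhage (IPH)**: positive when the plaque contains an
  8-connected component of ≥ 3 pixels, all brighter than 150 % of the
  reference-muscle ROI mean on pre-contrast T1. The clinical rule does not
  state an aggregation; a ≥3-pixel component (parameterised) was chosen for
  robustness to single-pixel noise. The rule is monotone in intensity.
* **Enhancement ratio**
  `((plaque_post/GM_post)/(plaque_pre/GM_pre) − 1) × 100 %`, grey-matter
  (GM) normalised. The normalisation cancels per-scan receive gain — this is
  load-bearing for the combined model (below).

Areas are pixel counts × pixel area; no sub-pixel fitting, matching manual
raster segmentation.

## Radiomic feature engine

A from-scratch 2D engine produces a fixed 98-name catalogue per sequence
(T1, T2, CE-T1): 14 first-order intensity statistics, 18 histogram/percentile
auxiliaries, 10 shape descriptors, 24 grey-level co-occurrence (GLCM),
16 run-length (GLRLM) and 16 size-zone (GLSZM) features. Conventions:

* **Discretisation**: equal-width bins over the in-mask intensity range,
  default `n_bins = 32`; the maximum maps into the top bin; a constant ROI
  maps to bin 1. Discretisation makes all texture features invariant to
  affine intensity changes.
* **GLCM/GLRLM**: distance 1, four directions (0°, 45°, 90°, 135°),
  symmetric matrices, per-direction normalisation, features averaged over
  directions with non-empty matrices; pairs and runs crossing the mask
  boundary are discarded. Grey-level indices are 1-based bin labels, logs are
  base 2, `0·log 0 ≡ 0`. A ROI with no valid pair in any direction raises.
* **GLSZM**: zones are 8-connected components of equal level. Note that a
  two-level checkerboard therefore merges diagonally — singleton zones
  require pairwise-distinct levels.
* **Shape**: the slice is treated as a one-voxel-thick volume
  (`Volume = area × thickness`; `SurfaceArea = 2·area + perimeter·thickness`);
  in-plane maximum diameter is the largest pixel-centre distance, and the 3D
  variant adds the slice thickness in quadrature. Shape features depend only
  on the mask and are computed once per study, replicated across sequences.

Every matrix family is validated against independent brute-force pair/run/
zone enumerators (explicit Python loops) to 1e-10 on hundreds of random
small ROIs.

## Statistical machinery

* Univariate screening: two-sided Student (pooled) t-tests for continuous
  variables (Welch switchable), Pearson chi-squared without continuity
  correction for 2×2 tables (correction switchable). The epoch-typical SPSS
  defaults motivate both choices; the source's exact chi-squared variant is
  not recoverable from its printed counts.
* AUC: Mann–Whitney pairwise concordance with ties counted ½ (midranks).
* Operating point: Youden's J maximum; ties resolve to the higher-specificity
  threshold (within a 1e-12 floating tolerance); accuracy, LR+ = sens/(1−spec)
  and 1/LR− = spec/(1−sens) are reported at that threshold.
* Stepwise logistic regression: forward entry by likelihood-ratio test
  (p < 0.10) with backward pruning (removal at p > 0.05), an SPSS-style
  forward-LR emulation; maximum-likelihood fits delegate to statsmodels;
  Wald 95 % CIs `exp(β ± 1.96·SE)`. Separation or non-convergence is flagged,
  never silent: failed candidate fits are skipped, a failed final fit returns
  a flagged result.
* Radiomic feature selection: per sequence, keep features with t-test
  p < 0.05 AND symmetrised univariate AUC `max(AUC, 1−AUC) > 0.65`. No
  multiple-testing correction by default (Benjamini–Hochberg available),
  matching the emulated workflow.
* DeLong: placement-value (midrank) formulation; the paired variance uses the
  structural components S₁₀ and S₀₁; degenerate variance returns z = 0,
  p = 1. The single-model variance agrees with a patient-resampling bootstrap
  within 10 % at n = 100.

## Random forest

Ten bootstrap-sampled binary trees of maximum depth 3 (up to 8 leaves),
Gini-impurity splits, candidate-feature subsets of size ⌈√d⌉ per node,
minimum leaf size 2, class-1 leaf probabilities averaged across trees (hard
voting available). Split ties break to the lowest feature index, then the
lowest threshold (midpoint between adjacent sorted values).

Feature subsets are drawn by hashing `(seed, tree index, node path, feature
name)` into priorities and taking the k smallest. This is uniform
pseudorandom subsampling, bit-reproducible across platforms, and — because a
shared feature keeps the same priority in any model that contains it — two
models differing only in their feature lists (the radiomic and combined
tiers) share bootstrap draws and most split decisions. Model comparisons
then reflect the feature sets rather than subsampling noise, a common-random-
numbers design.

## Pipeline and evaluation protocol

Three tiers are compared on a cohort table: **traditional** (univariate
screen at p < 0.10 → stepwise logistic on clinical/conventional variables →
linear-predictor score), **radiomic** (per-sequence selection on T1 + CE-T1
→ forest on the union), and **combined** (the same forest inputs plus the
IPH/MLA/enhancement-ratio columns; the combination mechanism is a design
choice, the emulated workflow does not state one).

Default scoring is resubstitution — the emulated study reports apparent
performance without held-out validation — and a stratified 5-fold
cross-validated AUC is always computed alongside as an explicit optimism
check. The two disagree in an instructive way on synthetic cohorts at n = 96:
the shallow forest's resubstitution AUC (~0.95) drops to ~0.75 under CV,
below the logistic model's CV AUC, so the reported three-tier ordering is a
statement about apparent (resubstitution) discrimination, exactly as in the
emulated workflow.

Exclusion bookkeeping asserts `included = screened − Σ excluded` on every
run; acute and sub-acute labels merge into one positive class.

## Synthetic cohort generator

One analysed slice per patient on a 64×64 grid at 0.3 mm spacing, 2 mm
thickness. Defaults reproduce the published cohort structure: 61/35 group
sizes; IPH prevalence 19/61 vs 1/35; MLA 3.78 ± 2.80 vs 2.39 ± 1.46 mm²
(gamma-distributed, matched on mean/SD — strictly positive, unlike a
truncated normal, which would bias the asymptomatic mean by ~ +0.2 mm²);
plaque burden ≈ 83/85 %; stenosis ≈ 54 %; enhancement ratio 24.2 ± 29.5 vs
3.4 ± 21.9 %; covariate prevalences from the published two-group table.
Geometry is a pair of concentric ellipses; with the published MLA and burden
values the implied plaque areas (≈ 19 vs 14 mm²) and outer diameters
(≈ 5.3 vs 4.4 mm) land on the published shape-feature magnitudes without
further tuning.

Texture: plaque intensity = base × (1 + 0.08 × field), where the field mixes
a Gaussian-smoothed component (correlation length shrinking with the
heterogeneity knob) with a white-noise component (weight growing with the
knob). Both effects push discretised co-occurrence entropy up, making batch-
mean entropy strictly increasing in the knob. Group defaults 0.65 vs 0.40
with per-patient SD 0.25. T2 uses a group-independent heterogeneity, so the
T2 arm carries no texture signal — mirroring the null T2 finding.

Two deliberate realism features matter downstream:

* **Receive-gain noise**: each sequence of each patient is scaled by an
  independent log-normal gain (log-SD 0.25). Absolute-intensity
  features are thereby blurred across patients while ratio-normalised
  quantities (enhancement ratio, the IPH rule, discretised textures) are
  untouched — giving the conventional metrics information the raw radiomic
  features cannot fully recover, which is why the combined tier beats the
  radiomic tier. This is the stated rationale for grey-matter normalisation
  in the clinical protocol.
* **IPH blob** (3–8 contiguous pixels at 1.6–2.2× muscle): it widens the
  in-mask T1 range, compressing the rest of the histogram into fewer bins and
  *lowering* T1 co-occurrence entropy for IPH-positive (mostly symptomatic)
  patients. The "higher entropy in the symptomatic group" structure is
  therefore asserted on CE-T1, where no blob is painted; on T1 the blob
  effect dominates at the published IPH prevalence.

CE-T1 is rendered by an additive mean shift to hit each patient's drawn
enhancement ratio exactly (on ROI means), leaving the noise floor unscaled.

The second-reader simulation jitters the lumen and outer-wall boundaries by
a level-set perturbation (signed distance + smooth noise scaled by the jitter
parameter, in pixels), preserving topology and the lumen-inside-wall
invariant; jitter 0 is the identity. Jitter 1 px on a 40-patient re-read
yields plaque-area ICC ≈ 0.8–0.95.

What the generator does **not** emulate: MR physics, coil profiles, partial
volume, 3D vessel tortuosity, reader-specific bias, or any correlation
structure between covariates beyond group membership. Passing tests
demonstrate that the pipeline recovers the modelled group structure; they do
not validate the clinical result on real images.

## Problem sizes and statistical checks in the test suite

Texture oracles run on 500 random ≤ 8×8 ROIs; the null-calibration checks use
1000 simulations × 8 features (t-test gate) and 50 seeds (held-out forest
AUC); the three-tier ordering experiment uses 50 independent n = 96 cohorts.
Distributional checks on the generator (group means at n = 200/group) use a
joint chi-square bound on standardised deviations with a 3-SE per-mean cap:
a per-mean 2-SE bound would fail ~5 % of fixed seeds for a perfectly
unbiased generator.

## Known limitations

* The feature catalogue is a documented superset (98 names) of the features
  the emulated study names; the original 94-feature list was never published.
* Resubstitution evaluation is optimistic by design (it emulates the
  original protocol); rely on the reported CV AUCs for generalisation.
* The stepwise procedure and the chi-squared variant are reconstructions of
  under-specified originals; both alternatives are exposed as options.
* Agreement statistics support exactly two raters.
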