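# Methods

## The classification problem

Enchondromas (EC) and atypical cartilaginous tumors (ACT) are cartilaginous
bone lesions with overlapping MRI appearance. Given a 3D volume and a
voxel-wise multi-label lesion segmentation (0 = background, 1 = EC, 2 = ACT),
the tool produces a case-level NT/EC/ACT decision by two independent routes,
both of which need only the segmentation and the image.

### Voxel-vote arm

The ACT fraction `f = n_ACT / (n_ACT + n_EC)` summarizes a predicted mask.
The fraction scale (not an odds ratio) is used so that majority voting
corresponds to `θ = 0.5`. Decisions use `f ≥ θ → ACT`; the tie at exactly θ
goes to ACT, the clinically costly class. An empty mask is a *no-tumor*
sentinel, never a fraction of 0: in the scouting phase it maps to NT, in the
final phase to EC (an empty prediction on a tumor-containing case is far more
likely a missed small enchondroma than a missed ACT, which are large).

θ is chosen by exhaustive search over every observed fraction plus 0 and 1+ε,
maximizing ACT F1; ties break toward the lower threshold (higher ACT
sensitivity). The optimizer is a plain function so it can be applied to
pooled out-of-fold fractions or nested inside a resampling loop.

Two-stage orchestration: a conservative "Scout" mask provider first routes
empty-mask cases to NT; the sensitive "Specialist" provider classifies the
remainder. A single-model mode uses one provider for both roles.

### Radiomics arm

Features are extracted inside the binarized lesion mask from ten filtered
images — original, logarithm (`log(1 + x − min)`, rescaled to the input
range), and the eight sub-bands of a single-level undecimated separable 3D
wavelet transform (coif1 kernel, periodic boundaries, filters scaled by
1/√2 per axis so the orthogonal bank conserves energy). Per image:
19 first-order statistics, 16 GLSZM, 14 GLDM and 5 NGTDM features; 14 shape
descriptors on the original mask only; 554 features total. Conventions:

* min-anchored fixed-bin-width discretization (default 25 intensity units),
  so every texture feature is invariant to global intensity shifts;
* zones/dependencies use 26-connected 3D neighborhoods; GLDM α = 0;
* Kurtosis is non-excess (Gaussian → 3); Variance divides by N;
* Elongation = √(λ2/λ1) and Flatness = √(λ3/λ1) from the covariance
  eigenvalues of physical voxel-center coordinates (1 = isotropic);
* degenerate inputs (single-voxel ROI, zero variance, non-finite values)
  yield sentinel 0 with a logged warning, keeping feature tables rectangular;
  the variance filter removes such columns downstream.

The classifier is an ensemble of 100 stratified 80/20 train/test XGBoost
trials (max_depth 3, 200 rounds, exact greedy splits — the histogram method
would place cuts on observed values and mis-side held-out cases inside a
class gap). The selection cascade (variance > 0, then greedy removal of
|Pearson ρ| > 0.40 pairs keeping the larger univariate Mann–Whitney effect,
in decreasing-effect order with name tie-breaks) is fitted per trial on the
training portion only, avoiding leakage; a global mode exists for sensitivity
analysis. Every case's ensemble probability is the arithmetic mean over the
trials that held it out; cases left uncovered after the scheduled trials get
targeted extra splits, so coverage is total by construction.

Importance ranking: mean gain across the trials that used a feature, and the
tie-corrected Mann–Whitney effect size r = |Z|/√N, each ranked separately and
combined 50/50; only features with two-sided p < 0.05 are retained; combined
ties break on the gain rank.

### Robustness protocol

Each test case gets 5 perturbed variants: additive Gaussian noise with
σ = 5 % of the volume's intensity range, then rotation by Uniform(−15°, +15°)
about a uniformly chosen grid axis through the volume center (order is a
config switch). Rotations act in physical millimeter space, honoring the
anisotropic spacing; volumes interpolate trilinearly, masks nearest-neighbor,
out-of-field voxels take the volume minimum (volume) or background (mask).
Variants are scored with the same held-out trial assignment as their original
case. The report gives per-variant AUCs, the min–max envelope, and a DeLong
comparison of original scores versus the per-case mean of perturbed scores.
Per-(case, variant) seeds derive from a CRC of the case id, so the report is
independent of processing order.

## Evaluation and inference

* DSC with both-empty → 1.0 and one-empty → 0.0 (flagged per case);
* MASD: symmetric mean nearest-surface distance in mm over 6-neighborhood
  boundary voxels, center-to-center; undefined (None) when either surface is
  empty;
* one-vs-all Precision/Sensitivity/Specificity/F1 with zero-denominator
  cells reported as 0 and flagged;
* rank-based AUC with midrank ties;
* BCa bootstrap CIs (scipy's implementation behind the module surface;
  degenerate bootstrap distributions collapse to the point interval);
* DeLong test via structural components (identical score vectors give
  p = 1 exactly; zero variance with unequal AUCs is rejected as inconsistent);
* paired permutation test: within-case A/B swaps with probability ½ and the
  add-one p-value `(1 + #{|null| ≥ |obs|})/(B + 1)`.

Iteration counts are config-scaled: tests and the default pipeline use
2000 bootstrap resamples / 2000 permutations; for publication-grade
inference set both to 10000.

## The phantom generator

The generator is the package's study-condition definition, not a tuning
knob. It emulates a proton-density fat-suppressed MRI cohort of knee and
shoulder cartilaginous tumors:

* grid 128 × 128 × 24 voxels at (0.6, 0.6, 4.5) mm — desk-scale in-plane
  extent with the clinical spacing and slice count; a clinical-scale flag
  generates (318, 304, 21) grids;
* background: smooth Gaussian random field (σ 6 mm, sd 40 on a [0, 1000]
  intensity scale, mean 300) plus a bone-like bright ellipsoid so the toy
  segmenter has non-trivial context;
* EC: diameter ~ lognormal moment-matched to mean 14, sd 12 mm; a smooth
  hyperintense lesion (base 760) with a coarse regular pattern (amplitude 60,
  correlation length 8 mm) and almost no voxel noise (sd 3). Its leading
  in-plane axes are nearly equal (axis ratio 0.9 → shape Elongation ≈ 0.9)
  and it is thin through-plane; lesions thinner than the slice spacing
  collapse to a single slice (with the center snapped to a voxel plane) so
  the 4.5 mm z-axis cannot dominate the covariance of small lesions;
* ACT: diameter ~ normal(54, 20) mm truncated above 10 mm; larger, expanding
  anisotropically in-plane (axis ratio 0.55 → Elongation ≈ 0.55), brighter
  (base 800), carrying both several large homogeneous plateaus (a 9 mm
  blotch field quantized to 4 levels, 90 units apart — driving GLSZM
  large-area emphasis and zone variance) and fine voxelwise noise (sd 18 —
  driving high-frequency wavelet energy and suppressing NGTDM strength);
* lesion edges taper over the outer 25 % of the ellipsoid radius, so
  segmentation thresholds trade boundary recall against false positives;
* diameters are redrawn (up to 10 times) when the rasterized lesion would
  not fit the grid with margin or would leave the [0.01 %, 5 %]
  voxel-fraction band; the raw samplers are exposed separately for testing
  the size laws themselves.

Together these choices reproduce the six qualitative contrasts the
classification arms rely on: wavelet-HF energy, GLSZM large-area emphasis,
total energy (logarithm filter) and zone variance higher in ACT; NGTDM
strength and shape elongation higher in EC. `separability_report` asserts
the directions and effect sizes on any generated cohort.

What the phantoms do **not** model: MR physics (no k-space, coil profiles,
bias fields), anatomy beyond one bone-like structure, multi-sequence
imaging, scanner/protocol variation, or the ambiguous mixed-texture lesions
that make the clinical problem hard. Passing tests therefore demonstrate
that the pipeline's machinery is correct and well calibrated on data with
known structure — not that clinical-grade accuracy is attained; phantom
AUCs near 1.0 reflect the deliberate separability of the generator.

## The toy segmenter

A deterministic stand-in for external segmentation models so the two-stage
design is testable end to end: z-score normalization (making it invariant to
affine intensity rescaling), 1 mm in-plane Gaussian smoothing, thresholding
at z = 4.8, removal of components below 60 mm³, then per-component EC/ACT
assignment by the variance of the 0.9 mm high-pass residual over the
in-plane-eroded component core (edges excluded — the bright lesion rim is
itself high-frequency structure); scores ≥ 0.02 → ACT. The Scout/Specialist
pair shifts the threshold by +0.3 / −0.4 and raises the Scout's minimum
component volume, reproducing the role asymmetry (Scout: better NT
detection; Specialist: better boundary recall). Thresholds were calibrated
once on the default phantom cohort and fixed in the config defaults.
External predictions are consumed instead via `load_predictions`
(`<case_id>_pred.nii.gz`, grid-checked, never resampled).

## Numerical and design choices

* Convex-hull hole filling is per-component, per-class, in 3D, iterated to a
  fixed point so it is idempotent even when filled components merge;
  components with fewer than 4 non-coplanar voxels are left unchanged;
  original labels are never overwritten and earlier components (raster
  order) win contested background voxels.
* Connected components default to 26-connectivity.
* No resampling anywhere: masks must match their volume grid (shape exactly,
  spacing to rtol 1e-3), and mismatches are errors.
* Feature extraction runs inside the lesion's padded bounding box; the pad
  (wavelet filter length + 1) makes in-ROI wavelet coefficients match a
  whole-volume computation except for lesions touching the volume edge.
* Seeds: every stage derives its seed from a master seed via
  `numpy.random.SeedSequence`, recorded in the run manifest; all derived
  seeds stay below 2³¹.

## Problem sizes

Default test/analysis sizes: mixed cohort 16 NT / 21 EC / 5 ACT (preserving
the 79:104:23 clinical class mix), balanced calibration cohort 50 EC /
50 ACT, 100 ensemble trials, robustness on a 24-case balanced subset with
5 variants per case, 2000 bootstrap resamples. These are the package's
desk-scale defaults; all counts are config parameters.

## Known limitations

* Phantom separability overstates clinical performance by construction.
* The toy segmenter is a calibrated rule, not a learned model; its DSC
  (~0.8–0.9 on phantoms) says nothing about real segmentation quality.
* Surface area uses the voxel-face approximation (overestimates smooth
  surfaces); MASD uses voxel-center distances.
* GLCM/GLRLM texture families are not in the default registry; the
  registry's 554-feature count is its own documented constant.
* BCa intervals inherit scipy's behavior for statistics that are unstable
  under jackknife resampling (errors are surfaced, not masked).
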