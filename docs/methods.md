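# Methods

This note records the scientific and numerical choices behind `strokefate`:
what each stage computes, which parameters matter, and where the design was
genuinely open.

## Problem setting

Acute ischemic stroke perfusion imaging acquires a 4D CT series (x, y, z,
t) after a contrast bolus. Each voxel's concentration-time curve (CTC) is
related to the arterial input function (AIF) by

    C(t) = (AIF * k)(t),        k(t) = CBF · R(t),

where `R(t)` is the residue function (fraction of tracer still inside the
voxel at time t after an idealized instantaneous arterial impulse), CBF is
cerebral blood flow, CBV = CBF · MTT is blood volume (central volume
theorem), and Tmax is the time of the deconvolved residue's maximum.
Tissue outcome prediction is voxelwise classification of the admission
perfusion data into future infarct vs. non-infarct under a given
treatment. The package implements five predictors over identical
cross-validation folds: optimal Tmax thresholding, a voxelwise random
decision forest (RDF) over (CBF, CBV, MTT, Tmax), and three UNet variants
— one fed the four parameter maps, and two fed per-voxel temporal features
learned by 1D convolutional blocks from residue curves or raw CTCs.

## Synthetic patients (`phantom`)

No clinical data ships with the package; a digital head phantom provides
ground truth for every downstream stage.

**Geometry.** Concentric ellipsoids on a 64×64×8 grid at 3×3×5 mm: a skull
shell (1000 HU), a subarachnoid CSF gap (5 HU), brain parenchyma (35 HU)
and two ventricles (5 HU). The CSF gap plays the same role as in real
heads: it keeps blurred skull intensity out of the parenchyma so the
threshold-based brain mask covers the true brain. Acquisition: 48 frames
at dt = 1.8 s.

**Hemodynamics.** Normal tissue: CBF 1 (relative units), MTT 4 s, bolus
delay = one frame interval (1.8 s). The delay equals a grid sample on
purpose: the residue's sampled maximum then equals CBF exactly, so
deconvolution accuracy can be assessed without a sampling artifact
entering the ground truth. One hemisphere carries an ellipsoidal
hypoperfused lesion with a plateau-like severity profile `s = 1 − ρ²`
(ρ = normalized radius): core CBF 0.15×, extra delay up to +9 s, MTT up
to 2.5×. Lesion radii are scaled per patient to realize arm-specific
lognormal volume distributions (IA 55.6 ± 74.4 ml, IV 117.5 ± 134.9 ml),
mirroring the cohort structure the package emulates (145 patients,
102 IA / 43 IV).

**AIF.** A gamma-variate `A(t) ∝ ((t−t0)/ab)^a exp(a − (t−t0)/b)` with
t0 = 8 s, a = 1.5, b = 0.8 s, peak 6 HU. The shape parameters sit at the
sharp end of plausible first-pass widths deliberately: the truncated-SVD
deconvolution zeroes spectral components of the AIF operator below 15% of
the largest singular value, and a broad, smooth AIF pushes most of its
spectrum under that threshold, biasing recovered CBF down by 30% or more.
With the sharp default the phantom honours its design contract — deconvolving
noise-free phantom curves with the generating AIF recovers CBF within 15%
(median, in practice exactly) and the delay within one temporal sample.

**Forward model and its discretization.** Curves are generated by the
discrete convolution `C[n] = dt · Σ_m A[m] k[n−m]` with the delayed
exponential residue. This left-Riemann discretization means the discrete
curve integral equals `dt·Σk`, which exceeds `∫k dt = CBF·MTT` by a factor
`(dt/MTT)/(1 − e^{−dt/MTT})` (~+24% at dt 1.8 s, MTT 4 s). CBV estimates
therefore converge to CBF·MTT only as dt → 0; tests check the
central-volume identity on fine grids (dt ≤ 0.25 s) and treat coarse-grid
CBV as carrying a known rectangle-rule bias. CBF and Tmax are unaffected.

**Follow-up infarct.** Each voxel infarcts with probability
`σ(β_t (Tmax − 6 s) + β_f (0.45 − CBF))`, drawn once per patient. Defaults
β_t = 1.5 /s, β_f = 4 give a learnable but noisy target; `β_t = ∞`
degenerates to the deterministic rule `Tmax > 6 s`. The link is a
stand-in: it encodes the qualitative physiology (infarction more likely
with long Tmax and low CBF) but no claim about clinical dose-response.

**What the phantom does not model:** beam hardening, motion, partial
volume, hemorrhage, gray/white heterogeneity, AIF dispersion or delay
differences between vascular territories, and measurement correlation
between neighbouring voxels (HU noise is i.i.d. Gaussian, σ = 2 HU).
Passing tests therefore demonstrate method correctness and end-to-end
learnability, not clinical performance.

## Preprocessing (`preproc`)

Baseline average = mean of the first three frames. Motion correction is a
pass-through hook (phantoms are motion-free); a per-frame rigid
registration callable can be injected for data that needs it. Baseline
subtraction converts to the concentration domain. Temporal resampling to
1 s uses a least-squares cubic B-spline with interior knots every 2 input
samples (approximation, i.e. mild smoothing; an interpolating spline is
available with `smooth=False`). The brain mask follows the fixed pipeline
blur → threshold → erode → largest component → dilate with: in-slice
Gaussian σ = 1 voxel (none across slices), exclusive HU bounds
1 < HU < 100, 5×5×1 structuring elements, 6-connected 3D components.
Exact idempotence of the mask under re-application is impossible with
blur-first ordering (once the skull is masked away, blur leaks across the
boundary); re-application preserves the interior and can only add a thin
boundary shell. Hemispheres are split at the midsagittal plane of the
mask bounding box; "left" is the lower-x half.

## Deconvolution (`perfusion`)

The AIF convolution matrix is zero-padded to `pad_factor × T` (default 2×)
and embedded in a circulant operator, making the deconvolution insensitive
to bolus delay; the operator's SVD is truncated at 15% of the largest
singular value and its pseudo-inverse applied to every voxel (one matrix,
shared). Conventions: CBF = max_t k(t) (negative lobes retained, optional
clipping), Tmax = dt · argmax k, CBV = ∫CTC / ∫AIF (trapezoid), MTT =
CBV/CBF with low-flow voxels (CBF ≤ 1e−6) flagged and set to 0. All
values are relative units; no hematocrit/density scaling is applied. In
the full pipeline the AIF is sampled on the native grid and passed through
the same resampling operator as the tissue curves, so both sides of the
deconvolution share one temporal transfer function.

## Tensor preparation (`mlprep`)

Contrast arrival is the first frame whose in-mask mean HU exceeds 115% of
the baseline-average mean (computed on the raw series, where "baseline
enhancement" is meaningful). The CTC temporal window of 32 samples is
centered on the peak mean intensity within 40 s after arrival, peak at
0-based position 16 (window [p−16, p+15]); when no arrival is detected the
global peak is used (logged). Residue curves keep their first 32 samples.
Windows extending past either end are filled with the mean of the
first/last three existing samples. Spatially, volumes are masked to the
ipsilateral hemisphere, cropped to its in-slice bounding box and padded
symmetrically (odd remainders lean to the leading edge) to a fixed shape:
480×320 at 0.45 mm for clinical-scale data, 32×64 or 96×64 for phantom
grids. Standardization is a per-feature z-score with statistics pooled
over every axis including time — one (mean, σ) pair per feature — fitted
on training data and reused verbatim at test time.

## Baseline predictors (`baselines`)

*Tmax thresholding*: predict infarct where Tmax strictly exceeds a
threshold. The candidate grid spans (0, 24] s at 0.2 s steps — 120 values;
the stated "0 to 24 s at 0.2 s" enumerates 121 inclusive values, and the
degenerate 0 s threshold is the one dropped. Each patient's operating
point maximizes the mean Dice over the *other* patients of the same arm
(leave-one-out; ties to the smallest threshold). 7.2 s is exposed as the
reference clinical operating point; it is cohort-dependent.

*Random decision forest*: a regression forest (100 trees, each fitted on a
bootstrap draw of 50% of the pooled instances — the `r` hyperparameter)
over the four perfusion parameters of each in-hemisphere voxel, standing
on scikit-learn's `RandomForestRegressor`. Class balance is restored per
patient before pooling: all minority-class voxels plus an equal random
draw of the majority class. Predictions are tree-averaged values in
[0, 1]. Noise reduction for the binarized maps: morphological closing
with a 3×3 kernel per slice, then removal of 3D 6-connected components
with fewer than 10 voxels (closing in-slice, components in 3D).

## Networks (`nn`, `deepnet`)

The models run on a compact NumPy layer library with explicit
backpropagation (2D/1D convolutions, dilated causal convolution, max
pooling, nearest upsampling, channel softmax, Adam); analytic gradients
are finite-difference checked in the test suite. Compute is float32
(memory-bandwidth bound); gradient tests switch the engine to float64.
Two exact optimizations matter for CPU throughput: 1D convolutions run
time-major so every kernel tap is a batched GEMM over contiguous views,
and time-constant background voxels (the zeroed out-of-hemisphere padding,
which standardizes to one shared value) are deduplicated through the
temporal block — identical windows share one forward row and their output
gradients are summed, leaving weight gradients exact.

*UNet trunk*: depth 4, base 64 filters by default (reduced configurations
are used at desk scale), two zero-padded 3×3 convolutions + ReLU per
level, 2×2 max pooling, nearest upsampling followed by a 3×3 convolution
on the decoder path, skip concatenation, and a 1×1 convolution with
2-channel softmax head; the infarct channel is the probability map. Batch
normalization is off. He-normal initialization, seeded.

*Temporal blocks* (per-voxel, weights shared across voxels): the simple
variant is three pairs of unpadded width-3 1D convolutions (32/16/8
filters) with factor-2 max pooling between pairs, collapsing
32→30→28→14→12→10→5→3→1 samples into 8 features; the causal variant is
five dilated causal convolutions (8 filters, width 2, dilations 1, 2, 4,
8, 16) whose final temporal element — the only position with a receptive
field covering all 32 inputs — is kept as the 8-feature vector.

*Training*: Adam with α = 5e-4, β₁ = 0.975, β₂ = 0.999, ε = 0.08 and a
weak L2 kernel regularizer (0.5e-4; biases exempt). The loss is soft Dice
`1 − (2Σpg + s)/(Σp + Σg + s)` aggregated over the batch, smoothing s = 1
during training (s = 0 only in analytic tests, where an empty truth is
rejected as undefined). Slices without infarct voxels are omitted from
training; validation loss is likewise computed over non-empty validation
slices. Early stopping after 8 epochs without validation improvement,
restoring the best-epoch weights. Batch size 8; epoch cap 500 by default.

Two training choices deserve explanation. First, ε = 0.08 is three orders
of magnitude above typical gradient RMS here, so Adam's step becomes
`(α/ε)·m̂` — a heavily damped regime suited to long training runs on large
cohorts. The desk-scale experiment preset caps optimization at 25 epochs,
where that damping cannot reach a useful operating point from a random
initialization; the preset therefore uses the conventional ε = 1e-7 while
keeping the reference α and β values. Second, the soft-Dice landscape has
an all-background plateau in which a rare unlucky initialization never
escapes, or escapes too slowly for the epoch budget; the experiment driver
scores each trained fold by its validation Dice at the best coarsely swept
threshold (a direct ranking-quality measure — the raw validation loss can
mislead when the output calibration is off), retrains a stalled fold
(score below 0.2) deterministically with a shifted seed and a doubled
learning rate (at most twice), and keeps the best-scoring attempt. The
rule is a pure function of the configured seeds.

## Evaluation (`evalharness`, `pipeline`)

Per treatment arm, a fivefold patient-level split is assigned once from
the fold seed and reused by every method; each fold's validation set
samples 15% of its training portion, giving the nominal 68/12/20
train/validation/test allocation. Probability maps are restored to scan
space, zeroed outside the ipsilateral hemisphere, and binarized at the
leave-one-out optimal threshold over an arm, scanned on the inclusive
grid 0.00–1.00 step 0.01 (101 values). Metrics per patient: Dice (both
masks empty defined as 1 — possible with tiny phantom lesions), an
empirical ROC from 100 thresholds (0.00–0.99) on in-hemisphere voxels
with (0,0)/(1,1) anchors and trapezoidal AUC — patient AUCs are averaged
for the summary statistic, while method-level curves are pointwise means
of patient curves — and signed/absolute volume errors in ml (positive =
overestimate). For Tmax thresholding the ROC sweeps the same 100-point
grid over the Tmax scale normalized by the 24 s grid maximum. Single-class
patients yield NaN AUC and are excluded from curve averaging. Each method
is additionally re-scored after noise-reduction filtering. Spearman rank
correlations between learned 8-channel temporal feature maps and the four
parameter maps over pooled test voxels are available as a separate
analysis step. Group-level statistical testing is deliberately exported
as tidy CSV for external statistics software rather than re-implemented.

All tables are stamped with a configuration hash; every random choice
(cohort, folds, undersampling, training) flows from a named seed, and a
re-run with identical seeds reproduces the metrics CSV byte for byte.

## Scaled experiment preset

`strokefate.config.scaled_experiment` defines the desk-scale study used
by the acceptance script and the heavier tests: a single-arm 20-patient
low-noise cohort (HU noise σ = 0.5; infarct-link slopes 6 /s and 12,
i.e. a nearly deterministic target), hemisphere tensors padded to 32×64,
a reduced UNet (depth 3, 16 base filters), at most 25 training epochs,
and methods Tmax thresholding, Param-UNet and CTC-Causal. These problem
sizes are the package's chosen desk-scale operating point; the full
clinical-scale defaults (145 patients, 480×320, depth-4/64-filter UNet)
remain available through the configuration objects.

## Known limitations

- Relative-unit perfusion maps only; absolute quantification constants
  are out of scope.
- The CBV rectangle bias at coarse dt (above) is inherent to the discrete
  forward model, not the estimator.
- The AIF is known by construction (or picked by a deliberately simple
  peak-voxel heuristic); automatic clinical AIF selection is out of scope.
- The infarct link and noise model are stand-ins; none of the reported
  desk-scale metrics are claims about clinical data.
- The NumPy engine is single-threaded CPU code; it is sized for the
  desk-scale experiments, not for 480×320 clinical training runs.
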