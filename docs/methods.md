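# Methods

This note documents the models, conventions and numerical choices behind
`redoxim`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Measurement model

A field of view (FOV) is a pair of single-channel grayscale images — NADH
(UV-excited) and Fp (blue-excited oxidized flavoproteins) — in native
camera counts at a declared bit depth (default 14 bit, stored in 16-bit
TIFF containers) and pixel size (default 0.293 µm/px).  Intensities are
never normalized to a reference standard: all comparisons are relative,
within one instrument and study.

**Background.**  Each channel carries an additive background with mean
`b` and noise SD `σ_b`.  Three estimators are provided: a cell-free blank
ROI in the same FOV (default), a separate blank frame, or the histogram
mode of the image with a robust SD (sample SD of pixels within ±3 MAD of
the mode).  A zero-variance blank is degenerate; the SD is floored at
1 count with a warning.  Which source real data should use depends on the
acquisition protocol; the choice is recorded in the `BackgroundEstimate`.

**SNR thresholding.**  Pixel SNR is `(raw − b)/σ_b`.  A pixel is retained
iff its SNR is ≥ `snr_min` (default 7.5, inclusive, fixed for determinism)
in **both** channels; the ratio is undefined on pixels that fail either
channel, so joint validity is applied to means, ratio pixels and areas
alike.  Thresholding on the raw rather than background-subtracted
intensity is available as a config option (`threshold_on: raw`); the
subtracted form is the default.

**Redox ratio.**  `ORR = Fp/(Fp + NADH)` is formed pixel-by-pixel on
retained (background-subtracted, strictly positive) values, so every ORR
pixel lies in (0, 1) and the grid is invariant under joint rescaling of
both channels.  Compartment ORR is the *mean of pixel ratios*, matching a
ratio-image-first workflow; the alternative (ratio of compartment means)
differs whenever intensity is spatially structured, and is not used.

**Compartments.**  Whole-cell and nucleus ROIs are inputs (polygons or
label masks — segmentation itself is out of scope).  Cytoplasm is defined
as cell AND NOT nucleus, pixel-exactly, so nucleus and cytoplasm always
partition the cell.  Pixel-raster rule for polygons: 0-based (row, col)
coordinates, a pixel belongs to an ROI iff its center is inside or on the
polygon boundary.  A nucleus overshooting the cell boundary is clipped
with a warning (manual polygons commonly overshoot by a pixel); a nucleus
empty after clipping is an error.

**Areas and N:C ratio.**  Areas are measured on the thresholded signal
footprint intersected with the ROI (configurable to the raw ROI raster).
The default estimator is the 2×2 pattern-weight algorithm: slide a 2×2
window over the zero-padded mask; each window contributes 0 (no on-pixel),
1/4 (one), 1/2 (two adjacent), 3/4 (two diagonal), 7/8 (three) or 1
(four); the sum estimates the area of the underlying smooth region better
than a raw count.  A plain pixel count is computed alongside.  The
cytoplasmic area is whole-cell minus nuclear area (same estimator), and
`N:C = nuclear / cytoplasmic area`.

**Compartment SNR.** Reported per channel as the compartment's mean
background-subtracted intensity divided by `σ_b` — a region-level summary
of signal quality, not a per-pixel threshold.

**Exclusions.**  A cell with any compartment empty after thresholding is
flagged, carried with NaN indices, excluded from aggregation, and counted
in the run log; it is never silently dropped.

## Aggregation

Two replication models:

* **dish-based** — cell values averaged within FOV (equal cell weight),
  FOV means averaged within dish (equal FOV weight regardless of how many
  cells survived thresholding — the documented choice for unbalanced
  FOVs), dish means are the replicates (N = dishes);
* **cell-based** — each cell is a replicate.

Pooling (by cell line, receptor group, or mitotic status) concatenates
replicate lists, so two 3-dish lines pool to N = 6 dish-based and
2 × 45 = 90 cell-based.  Under a fully balanced design the two models'
grand means coincide exactly; their SDs measure different things and are
never interchanged.  SDs use the n−1 denominator and require ≥ 2
replicates.

**Percent difference** is `100·(A − B)/B` with the *reference in the
second slot* ("A compared to B").  **Reliability gate:** a difference is
`reliable` iff statistically significant (p < α, default 0.05) *and*
|percent difference| strictly exceeds 15 % — a guard against residual
instrument variation; significant-but-smaller changes are labelled
`significant_but_below_threshold`.  The gate applies to all indices by
default.

## Statistics

All tests are two-sided, α = 0.05, with star tiers at 0.05 / 0.01 /
0.001 / 0.0001.

* **Welch's t** from raw samples or (mean, SD, n) summaries;
  Welch–Satterthwaite df; Cohen's d from the pooled (n−1-weighted) SD.
  The degenerate zero-variance/equal-means case returns t = 0, p = 1.
* **Brown–Forsythe one-way ANOVA** on means:
  `F* = Σ n_j(ȳ_j − ȳ)² / Σ (1 − n_j/N) s_j²`, numerator df k−1,
  Satterthwaite denominator df.  It reduces exactly to the classical
  one-way F when sample variances are equal in a balanced design (tested).
  Like other Satterthwaite-based procedures it is mildly liberal in small
  samples: at n = 15 per group with SDs 1/2/3 its measured size is ≈ 0.057
  at nominal 0.05 (20 000-replicate estimate), approaching nominal as n
  grows.
* **Dunnett's T3** all-pairwise comparisons: Welch-type t per pair with
  pairwise Welch df; adjusted p from the studentized maximum modulus
  (SMM) distribution with parameter = number of comparisons, evaluated by
  numerical integration over the studentizing chi density.  With one
  comparison the SMM tail reduces to the two-sided t tail (tested).  A
  Šidák fallback `1 − (1 − p_raw)^m` is provided and is at least as
  conservative.  Adjusted p never falls below raw p.  Commercial packages
  do not publish their T3 tables; numerical equivalence with any one of
  them is not claimed.
* **Regression and slope comparison.**  OLS via standard least squares
  (slope, intercept, slope SE, R², slope-p).  Two slopes are compared with
  `t = (b_a − b_b)/√(SE_a² + SE_b²)` and Welch–Satterthwaite df with
  component df (n−2) each — an ANCOVA-style unequal-variance construction;
  the df rule is this package's documented choice.  The statistic is
  antisymmetric under argument exchange.

## Synthetic data generator

The generator is first-class, tested code: it emulates the features of the
real acquisition that the pipeline is sensitive to, with exact ground
truth.

* **Geometry.**  Non-overlapping rotated elliptical cells (semi-axes
  uniform in 14–20 px by default) with concentric elliptical nuclei.
  Mitotic cells carry two disjoint nuclear lobes placed along the major
  axis with combined area = 1.8 × the nonmitotic target (nuclear
  enlargement during division).  Cell placement retries up to 1000 times
  before raising a packing error.
* **Intensity.**  Pixel = background mean + compartment signal (+ optional
  Poisson shot noise on the signal) + Gaussian read noise, clipped to the
  14-bit range; rounded to integer counts whenever any noise is enabled,
  kept floating-point in the noise-free regime so recovery can be checked
  to 1e-6.  A perinuclear ring (nucleus ellipse expanded by 15 % of its
  minor axis) is enriched by a factor 1.5 **in both channels equally** —
  emulating perinuclear mitochondrial clustering without perturbing the
  pixel ORR.  The cytoplasm base level is solved per cell so the realized
  cytoplasm mean (ring included) equals the preset target exactly.
* **Presets.**  `tnbc_like`: nuclear NADH = 0.51 × cytoplasmic, nuclear
  ORR = 1.18 × cytoplasmic (0.6608 vs 0.56), N:C target 0.16;
  `receptor_positive_like`: cytoplasmic NADH twice the TNBC level, equal
  nuclear and cytoplasmic ORR (0.40), nuclear NADH = 0.85 × cytoplasmic,
  N:C target 0.28.  These choices jointly fix the between-group contrasts
  (cytoplasmic NADH −50 %, cytoplasmic ORR +40 %, nuclear NADH −70 %)
  and imply a nuclear ORR contrast of +65 %.  Fp levels follow from
  NADH and the ORR targets; the resulting group Fp difference is ≈ −5 %
  (cytoplasm), i.e. essentially flat, as intended.
* **Noise and scatter.**  Default read noise SD 50 counts over a
  100-count background puts the weakest compartment (TNBC nucleus, 510
  counts) at region SNR ≈ 10 and cytoplasm ≥ 20, with the 7.5-SNR pixel
  threshold comfortably below the signal.  Per-cell biological scatter is
  a unit-mean lognormal factor (CV 15 %) drawn independently per channel,
  so group means stay at preset values while ORR varies across cells.
  N:C scatter is a unit-mean lognormal on the N:C ratio itself (CV 0.25
  TNBC-like, 0.50 receptor-positive-like — chosen to yield SDs of ≈ 0.04
  and ≈ 0.14); drawing it on the area *fraction* instead would bias the
  convex ratio upward.
* **Mitotic redox.**  Mitotic nuclei get a 7 % lower ORR implemented as a
  symmetric two-channel shift (NADH up, Fp down by the same factor), so
  no single intensity moves more than ~10 % — reproducing the pattern of
  a statistically detectable but below-reliability-threshold nuclear ORR
  dip with no reliable single-channel change.
* **Design.**  The default study: four lines (two per receptor group) ×
  3 dishes × 3 FOVs × 5 cells = 180 cells on 256×256 frames.  The frame
  is deliberately smaller than a real 1920×1216 acquisition; cells and
  contrasts are at native scale, so only the number of background pixels
  differs.  Identical spec + seed gives bit-identical images, masks and
  ground truth (seeds spawn per FOV from one root `SeedSequence`).

**What the synthetic validation does not show.**  The generator has
piecewise-constant compartments, elliptical geometry, stationary Gaussian
noise and no flat-field error, photobleaching, focus drift or segmentation
error.  Passing recovery tests therefore validates the *computational
chain* (thresholding, ratio formation, decomposition, areas, aggregation,
statistics), not the biological measurement itself; with manually drawn
ROIs on real data, segmentation subjectivity and optical effects enter
upstream of this pipeline.

Ground-truth bookkeeping: compartment means are measured on the noise-free
signal grids (exact, ring included); true areas carry both the
pattern-weight estimate of the true mask and the geometric ellipse area
πab.  The pattern-weight estimate of a digitized ellipse tracks πab to
within ~0.5 % (cells, semi-axes ≥ 14 px) per cell, and to within 2 % in
the study mean for nuclei (semi-axes 5–8 px), where per-cell digitization
jitter of a few percent averages out.

## Determinism and numerics

Every stochastic step takes an explicit seed; reruns with identical inputs
and config reproduce all output tables byte-for-byte (CSV floats at 12
significant digits).  Ties at the SNR threshold are resolved inclusively.
The SMM tail integral uses adaptive quadrature (`limit=200`) over the chi
density; its k = 1 reduction to the t tail is verified to 1e-6.  Empty
grids, zero-variance blanks, degenerate compartments and zero-variance
groups all have defined, tested behavior (see the exception hierarchy in
`redoxim.errors`).

## Problem sizes used in the validation suite

The packaged tests run the full study design (180 cells per replicate
study) for pattern-level checks — 20 independent replicates for the
group-pattern test — 2000 replicates per test for type-I calibration, and
reduced designs (1–2 dishes/FOVs) where only mechanics are exercised.
These sizes are the package's own validation choices and keep the whole
suite around a minute on one CPU.
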