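# Methods

`nucleomorph` quantifies nuclear morphology and chromatin texture from
grayscale fluorescence images of DAPI-stained nuclei and embeds the per-nucleus
measurements in a standardized-PCA feature space.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Pipeline model

An acquisition yields N frames of the same field (N >= 4 recommended for
low-signal devices).  The pipeline assumes:

1. **Alignment** — frames differ from frame 0 by small rigid translations
   only (stage drift / hand-held capture).  The shift maximizing the circular
   cross-correlation of mean-subtracted frames is applied at integer-pixel
   resolution; borders exposed by shifting are edge-replicated.  Sub-pixel
   registration is deliberately not used: integer shifts keep the subsequent
   pixel-wise average free of interpolation artifacts.  A shift above 10% of
   the image side is treated as registration failure.
2. **Averaging** — pixel-wise arithmetic mean; residual noise falls as
   1/sqrt(N).
3. **Background subtraction** — rolling ball.  The ball geometry couples the
   spatial radius to the gray axis, so the ball is rolled in 8-bit gray units
   (intensities x 255), the convention of the ImageJ algorithm this mirrors;
   rolled directly on [0, 1] data, any object wider than a few pixels would
   count as background.  The background is estimated on a 3x3-mean-smoothed
   copy so the ball rides the background level rather than noise valleys,
   then subtracted from the unsmoothed image and clipped at zero.  Default
   radius 50 px: much larger than intra-nuclear texture scales (so chromatin
   structure is not eroded), much smaller than a field.
4. **Median filtering** — radius 1 by default; the footprint follows the
   rank-filter convention (pixel included when d^2 <= r^2 + 1), so radius 1
   is the full 3x3 neighborhood.
5. **Segmentation** — global Otsu threshold (parameter-free and invariant to
   positive intensity rescaling) with a fixed-value override; binary fill
   holes; boundary regularization (a 3x3 majority vote removes single-pixel
   raggedness, then a Gaussian on the binary mask, σ = 1.5 px, re-thresholded
   at 0.5 smooths the threshold-level waviness that noise and dark
   boundary-adjacent chromatin induce — left in place, either would inflate
   perimeter estimates by up to ~10%); 4-connected components; area filter
   (default 200 px); border-touching components dropped by default.
   Segmented masks recover ground truth at IoU ≈ 0.99 on the noisy synthetic
   fields.  Touching nuclei are *not* split — they emerge as one component
   and are flagged by a shape-factor > 1.8 warning.

All internal math is floating point in [0, 1]; source bit depth (8/12/16) is
metadata.  Processing order is subtract -> median -> threshold.

## The nine per-nucleus parameters

| Parameter | Definition | Units |
|---|---|---|
| Projected area | foreground pixel count x pixel area | um^2 |
| Aspect ratio | major/minor axis of the second-moment ellipse | — |
| Perimeter | boundary length (see below) | um |
| Shape factor | P^2 / (4 pi A); 1 for a disk | — |
| Relative concavity | (convex hull area − area) / convex hull area | — |
| Centre–centroid mismatch | distance between mask centroid and intensity-weighted centroid | um |
| Entropy | −Σ p log2 p over a 256-bin histogram of min-max scaled intensities | bits |
| SD of normalized intensities | SD after min-max scaling to [0, 1] | — |
| Autocorrelation length-scale | first zero of the mean decorrelation curve | um |

**Perimeter estimator.**  The mask is lightly smoothed (Gaussian, σ = 1 px)
and the marching-squares contour at the 0.5 level is measured; the smoothing
removes the rasterization staircase that would otherwise inflate the length.
This calibration choice is driven by the shape factor: pixel-edge counting
overestimates a disk's perimeter by up to ~27%, and 4-direction Crofton
underestimates axis-aligned rectangles by ~6%; the smoothed contour is within
~1% of truth on both families, so the shape factor lands at 1.00 ± 0.01 for
disks and 4/pi ± 2% for squares, and the estimator is symmetric under 90°
rotation.

**Convex hull.**  Hull of pixel centers (no half-pixel corner offsets): with
corner offsets the hull of a convex rasterized ellipse exceeds the ellipse by
a half-pixel band, reading ~2% spurious concavity on a genuinely convex shape.

**Entropy binning** is fixed at 256 bins regardless of source bit depth,
mirroring 8-bit conversion of the intensity histogram.

## Autocorrelation length-scale

The statistic proxies the size of chromatin structures: the shift distance at
which bright structures on average meet dark ones.

1. The largest circle inscribed in the nucleus mask is found via the
   Euclidean distance transform (center = argmax, radius = max).  Intensities
   inside are min-max scaled to [0, 1], then mean-subtracted.  Pixels outside
   the circle are excluded from every subsequent sum (not zero-padded, which
   would bias coefficients toward zero at large shifts).
2. For every integer shift vector with magnitude below the circle diameter,
   the Pearson correlation coefficient between the image and its shifted copy
   is computed over the overlap of the two circular supports, with both sides
   re-centered on the overlap.  Shifts with overlap below 16 px, or with
   vanishing variance on either side, are excluded.
3. Coefficients are averaged in unit-width annular bins (bin k collects
   shifts whose magnitude rounds to k) to give the mean decorrelation curve;
   the full 2D coefficient map is retained for directional reporting.
4. The length-scale is the first sign change of the mean curve, linearly
   interpolated between the bracketing bins, converted to um.  A curve that
   never crosses zero yields a *missing* value (not zero, not the maximum
   distance); the pipeline counts such nuclei.  Nuclei with inscribed radius
   below 4 px are likewise flagged missing.

"Correlation coefficient" is implemented as the Pearson coefficient over the
overlap (re-centered per overlap), not raw normalized covariance: the
zero-mean pre-step plus the coefficient framing support this reading, and a
brute-force double-loop oracle in the test suite pins the contract to 1e−6.
The production path evaluates all shifts at once with FFT cross-correlations
of the value, squared-value and support arrays (each running sum of the
restricted Pearson formula is itself a cross-correlation); it matches the
brute-force loop to ~1e−15.

**Directional curves.**  The default report is the radial (all-directions)
average.  A major–minor mode reports curves along the mask's principal axes:
shifts whose perpendicular offset from the axis is within
max(1.5 px, tan 15° x |parallel|) are folded over both senses of the axis
and binned by the parallel distance.  For a cosine grating of period P the
along-grating curve is cos(2 pi d / P) and crosses zero at exactly P/4, the
analytic check used in the tests.  Results should state which mode was used.

## Feature space

Features from all nuclei are pooled; each column is standardized to mean 0,
SD 1 (sample SD, n−1).  Constant columns are dropped with a warning.  Rows
with missing length-scales are dropped by default (`median` imputation
optional) and counted.  Principal components come from the eigendecomposition
of the sample covariance (deterministic; no iterative solver): loadings are
unit-norm eigenvectors ordered by descending eigenvalue, each flipped so its
largest-magnitude entry is positive (bit-stable sign convention), scores are
the centered data projected on them, and component variances are the
eigenvalues.

"Groups occupy distinct regions" is operationalized — it must be assertable —
as (a) the silhouette coefficient on the first k scores (default k = 3) and
(b) leave-one-out nearest-centroid accuracy (each nucleus assigned to the
nearest group centroid computed without it).  Groups under 5 nuclei are
excluded with a warning.  The report also names the top-loading morphometric
and textural parameter per component; the centre–centroid mismatch belongs to
both families.  When several experimental comparisons are analyzed, each
comparison is standardized within itself.

## Synthetic data: what it emulates, what it does not

No reference image data is available to this package, so ground truth is
defined by construction.

**Shapes** are rasterized ellipses (area 50–300 um^2, aspect ratio 1–3
supported) with an optional concave pocket: a circular bite on the minor axis
whose center moves inward with its radius (depth d = b − 0.6 r), bisected
until the measured relative concavity is within ±0.02 of target, with an
outer loop keeping the final area within ~1% despite the removed mass.  For
elongated specs (AR >= 1.2) a damped correction also keeps the measured
moment AR at the spec value; for near-circular shapes the anisotropy a deep
single pocket induces (up to ~+0.5 in AR at concavity 0.3) is irreducible and
is documented rather than fought.

**Texture** inside each nucleus is one of: white noise filtered by a
difference-of-Gaussians G(σ) − G(2σ) (the `bandpass_noise` default), a cosine
grating, or a constant.  A DoG bandpass rather than a plain Gaussian blur is
essential: its autocorrelation genuinely crosses zero, matching the
statistic's premise (Gaussian-blurred noise decays monotonically and would
always read "missing").  The closed-form ACF of the filtered field,
G(√2 σ) − 2 G(√5 σ) + G(√8 σ), has its first zero at r = 2.1398 σ; the
generator sets σ = target/2.1398.  Measured zero-crossings land within ~5% of
target at scales of 2–12 px and increase strictly monotonically with the
generator scale.  Intensities are scaled to a requested SD about mean 0.5 and
clipped to [0, 1].

**Acquisition** adds, in order: a low-order 2D polynomial background (random
coefficients, amplitude-normalized) to exercise rolling-ball subtraction; an
independent integer translation per frame (frame 0 is the zero-shift
reference, so integer-pixel alignment is exactly invertible); additive
Gaussian sensor noise; quantization to 8/12/16 bits.  Default conditions:
4 frames, noise SD 0.02 of range, shifts <= 2 px, background amplitude 0.1,
12-bit, 0.2 um/px (a typical effective widefield pixel size; chosen once so a
~100 um^2 nucleus spans a tractable ~50 px).

**Two-population preset** — the stand-in for comparing cell lines, since the
biological comparisons cannot be reproduced without image data — draws two
groups of nuclei with lognormal within-group variation (10% CV on area and
texture scale), aspect ratios uniform in [1, 1.5], and group B scaled by the
requested effect sizes (defaults: 2x area, 2x texture correlation length).
n = 30 nuclei/group with 5 seeds is the study condition for the recovery
checks; each nucleus is emitted as its own small field so preprocessing and
segmentation are exercised per nucleus.

Not emulated, hence not validated by passing tests: optical PSF blur and
vignetting, photon (Poisson) noise — the pipeline never models it, so the
generator stays additive-Gaussian — color-mosaic artifacts, touching or
overlapping nuclei, and any calibration of the population presets to real
cell-line distributions (no distributional data exists to calibrate against).

## Numerical choices and degenerate inputs

- Zero-shift coefficient is pinned to exactly 1; FFT round-off (~1e−15) is
  clipped where variances go slightly negative.
- Constant-texture nuclei: SD = 0 with a warning, entropy 0, length-scale
  missing (the zero-mean crop is identically zero, correlation undefined).
- Inscribed radius < 4 px: length-scale missing, other features still
  reported.
- All-zero intensities inside a mask make the weighted centroid undefined —
  an error naming the nucleus.
- Collinear masks have no moment ellipse — a degenerate-geometry error;
  aspect ratios above 10 warn.
- PCA input is made C-contiguous before eigendecomposition so results are
  bit-identical regardless of the memory layout pandas supplies.
- End-to-end robustness of the centre–centroid mismatch is assessed against
  max(10% relative, half a pixel): it is a distance between two
  grid-quantized centroids and is typically a fraction of a pixel, below
  which differences are quantization, not signal.

## Study sizes used by the checks

The oracle-equivalence check uses 20 random 32-px circular images; the
grating limit uses periods {8, 16, 32} px in a 250 um^2 nucleus; texture
monotonicity uses scales {2, 4, 6, 8, 12} px x 10 seeds; population recovery
uses 30 nuclei/group x 5 seeds (2x effects) plus one null cohort; end-to-end
robustness uses one 8-frame stack at noise SD 0.05 of a 150 um^2, AR 1.3,
concavity 0.15 nucleus.  A full `pytest` run takes a few minutes on one CPU.

## Known limitations

- Integer-pixel alignment leaves up to half a pixel of residual blur per
  frame in the average.
- Touching nuclei are returned merged (flagged, not split); no watershed.
- The rolling-ball radius is a free parameter; the 50 px default suits
  nuclei tens of pixels across and must be rescaled with magnification.
- Deep single-pocket concave shapes necessarily read an elevated moment
  aspect ratio (see above).
- The decorrelation statistic needs an inscribed circle >= 4 px and genuine
  intensity variation; very small or very flat nuclei report missing values.
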