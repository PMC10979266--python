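# Methods

## The processing model

The package analyses 8-bit grayscale crops of mandibular trabecular bone
(5 × 5 mm regions of interest from panoramic radiographs) under the
assumption that radiopaque bone maps to high intensity. The segmentation
follows the White–Rudolph local-mean principle: after ×4 bicubic
enlargement, the image is blurred with a Gaussian of σ = 35 px truncated to
33 taps and renormalized — at that truncation the kernel is nearly flat, so
the blur is effectively a 33-pixel moving average. Subtracting the blur and
adding 128 centres each pixel on its local mean; thresholding at 128 then
marks pixels *above their local mean* as bone. Binarization uses `>=` so
ties go to foreground; the corrected image is snapped to 1e-6 gray levels so
an exactly flat region (zero residual) sits on the threshold rather than a
float epsilon below it. Blur boundaries are reflective: ROIs have no natural
padding. The threshold, kernel size, sigma and upsampling factor are all
configurable (`ChainConfig`); the defaults are the protocol values.

Because the kernel is specified in *pixels*, the chain is not invariant to
acquisition resolution: at a finer pixel pitch the physical averaging window
shrinks and the local-mean segmentation genuinely changes. Cohorts must
therefore be processed at a uniform pixel size, which is how the workflow is
used in practice.

Skeletonization uses Guo–Hall thinning (`skimage.morphology.thin`): it is
idempotent, preserves 8-connected component counts, and reduces a 3 × 3
solid block to a single pixel, which matched our reference enumeration where
the Zhang–Suen variant leaves two pixels.

## Features

**GLCM.** Intensities are uniformly quantized over [0, 255] into `levels`
bins (default 256), co-occurrences accumulated at one offset (default
(0, 1), i.e. distance 1 at 0°), symmetrized and normalized. Contrast,
correlation, energy and homogeneity use bin indices; correlation is
reported as NaN when a marginal is constant (a constant image has no
defined correlation). The GLCM is computed on the density-corrected
grayscale by default — it is a grayscale statistic — with a switch to use
the raw ROI instead.

**Fractal dimension.** Box counting on the skeleton: the image is tiled
from the top-left with s × s boxes (partial edge boxes count), box sizes
default to powers of two from 2 to a quarter of the image side, and FD is
the negative slope of the unweighted least-squares line of log N(s) against
log s. A fit with r² < 0.9 logs a warning rather than failing: sparse
skeletons legitimately produce noisy count curves. FD of a thinned skeleton
is not monotone in bone density (thicker struts can *shorten* a skeleton);
density response is monotone for the binarized mask, and the tests reflect
that distinction.

**Strut analysis.** Skeleton pixels are classified by their 8-connected
skeleton-neighbour count: terminus (1), strut (2), node (≥ 3), isolated (0).
Termini are counted as pixels (they cannot be adjacent in a thinned
skeleton); nodes are counted as 4-connected *clusters* of node pixels by
default, because a junction wider than one pixel is still one crossing
point (a per-pixel mode is available). Note that in a thinned cross the
pixels adjacent to the centre also see ≥ 3 neighbours through diagonal
contacts — the cluster convention absorbs exactly this. The periphery is
the set of foreground pixels with a background 4-neighbour, with the image
border treated as background. TSL is the skeleton pixel count by default; a
√2-weighted chain-code length is available behind a flag, but the fourteen
ratio features divide counts by counts, so a consistent unit is what
matters. Per-cm² densities use the *upsampled* pixel size, so physical
density is unaffected by the ×4 enlargement. Ratios with zero denominators
are reported as NaN and logged, never silently zeroed.

## Morphometric indices

Landmarks are polylines in mm. The measurement line passes through the
mental foramen perpendicular to the inferior border's nearest segment (no
tangent smoothing; annotations are expected to be piecewise linear). MI is
the distance between that line's intersections with the inferior and
endosteal borders; PMI divides MI by the distance from the inferior border
to the cortex upper edge along the same line. The classical PMI denominator
(inferior border to the foramen itself) is available via
`reference="foramen"`; the default follows the cortex-upper-edge wording of
the screening protocol, and the two can differ materially, so the choice is
explicit in the API. Normal-range flags use MI > 3.1 mm and PMI > 0.3, both
strict. MCI (Klemetti C1/C2/C3) is a visual grading consumed as an
annotation; the package validates and tabulates it but never infers it from
pixels.

## Statistics

Group comparisons use the pooled-variance two-sample t-test (Welch via
`equal_var=False`), two-sided, with per-comparison α = 0.05 and no
multiplicity correction by default — Bonferroni and Benjamini–Hochberg are
available behind a flag. Normality checks report Shapiro–Wilk and a
one-sample KS against a normal with estimated parameters (the Lilliefors
caveat applies and is noted in the docstring). Cronbach's alpha treats
observers as the parallel measurements over rated subjects, matching the
two-observer, twenty-image reliability design.

The sample-size solver starts from the normal approximation
`n = 2((z_α + z_power)/d)²` and steps to the smallest integer n whose exact
noncentral-t power reaches the target. One-tailed α = 0.05 with d = 0.4 and
power 0.95 gives 136 per group (272 total); the two-tailed solve gives 164
per group (the normal approximation alone suggests 163, but its exact power
is 0.9494, so the step-up adds one — statsmodels' continuous solve, 163.4,
agrees).

## The synthetic generator

The trabecular model is a thresholded smoothed Gaussian random field:
seeded white noise smoothed with an isotropic Gaussian of physical scale
`correlation_length_mm`, cut at the value of its `round(bf·N)`-th largest
pixel so the mask fraction equals the requested bone fraction to within
half a pixel. The mask is rendered bright (190) on dark (65), degraded with
a planar illumination ramp (peak-to-peak `gradient_amplitude`, emulating
the large-scale density variation of panoramic projection) and i.i.d.
Gaussian noise, and clamped to [0, 255]. Defaults: bone fraction 0.48
(post-menopausal-like cohorts are generated at 0.46 or below), correlation
length 0.4 mm, gradient 30, noise SD 8, 0.1 mm pixels, 5 mm ROI — bone
fractions chosen to match the magnitudes reported for mandibular ROIs, the
rest chosen once as plausible for panoramic detectors. Per-image seeds are
`base_seed + offset`, so cohorts are bit-reproducible.

What the generator does *not* emulate: anatomically structured (anisotropic,
plate-like) trabecular networks, panoramic ghost shadows and overlapping
anatomy, detector blur, or correlated noise. Passing tests therefore
demonstrate that the pipeline measures what it claims on controlled texture
with known truth — not that it discriminates clinical cohorts.

One degeneracy of the noiseless rendering is worth knowing: inside regions
that are uniformly bone (or uniformly marrow) over the whole blur window,
the corrected image sits exactly on the threshold, so the local-mean rule
carries no information there and tiny gradients can flip whole patches.
Real radiographs always carry internal texture and noise, which breaks the
degeneracy; ground-truth recovery is therefore assessed on the noiseless,
gradient-free configuration, where the binarized mask disagrees with the
generator truth on under 2% of pixels.

## Simulation sizes

The Monte-Carlo checks run the full chain per image and are sized for a
single CPU: the type-I calibration uses 500 null cohorts of 10 images per
group, and the group-difference recovery 100 cohorts of 20 per group, both
at 0.2 mm/px (25 px ROIs, ×4-upsampled to 100 px). At these sizes the null
rejection rate of each feature must land in [0.03, 0.07] at α = 0.05, and a
0.1 bone-fraction deficit must be detected (with the correct sign) in at
least 90% of cohorts — the measured effect size for `hda/total_area` at the
default noise levels is around d ≈ 2, so the detection requirement is far
from marginal.

## Known limitations

- The chain's pixel-denominated kernel ties results to acquisition
  resolution (see above).
- GLCM distance/angle/levels and FD box sizes are conventions, not
  protocol-fixed values; defaults are declared and configurable.
- TSL as a pixel count underestimates diagonal runs by up to √2; the
  weighted option exists but changes all TSL-based ratios.
- MI/PMI accuracy is bounded by annotation quality; the perpendicular is
  taken to the nearest segment, so noisy polylines should be smoothed
  upstream.
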