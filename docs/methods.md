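# Methods

This note documents the models and procedures rhizopipe implements, the
assumptions behind them, and the numerical and design choices made where
the problem left the design open.

## Instrument model and conventions

The pipeline targets cylindrical in-situ root scanners of the CI-600 class:
unwrapped 360° RGB scans at 300 dpi, 21.6 cm circumference × 19.6 cm
along-tube extent per fixed scanner position, with ~1 cm overlap between
consecutive positions. Tubes (70 mm outer diameter, 2 m long) are installed
at 30° from the soil surface with ~20 cm left above ground.

Raster orientation is normalised so the image's left edge is the top of the
tube and its right edge the bottom; rows run around the circumference.
Filenames follow a configurable `{tube}_{date}_p{index}` template — no
vendor naming scheme is assumed, this one is an arbitrary but documented
convention. 16-bit inputs are linearly rescaled to 8-bit with a warning.

## Stitching

Each consecutive pair is aligned by: grayscale conversion (luminance
weights 0.2125/0.7154/0.0721), ORB keypoint detection (default 500
keypoints), descriptor matching by minimum Hamming distance with
cross-check, and a RANSAC projective fit (min samples 4, residual threshold
2 px, max 1000 trials, seeded).

Two reductions reflect the instrument's rigid geometry:

- The projective model is reduced to its **horizontal displacement**,
  measured as the median column shift over the RANSAC inliers. Evaluating
  the fitted projective matrix at the image corner instead extrapolates far
  from the keypoint cluster and proved numerically fragile — a
  perspective-heavy fit can reproduce all inliers to 2 px yet place the
  corner a hundred pixels off.
- Keypoint search is restricted to a band of three nominal overlaps around
  the expected seam (configurable; disabled by setting
  `search_band_overlaps = 0`), which suppresses false matches between
  non-shared soil texture.

Merging is **crop-and-concatenate**: the columns of the right image that
duplicate the seam are dropped and the remainder appended. No warping or
blending is applied; vertical drift and exposure differences are out of
scope. A pair whose alignment fails — too few correspondences or inliers,
or an offset that would retain nothing of the next scan — falls back to
the nominal 1 cm overlap abutment; fallbacks are logged and counted.
`trim_overlap` (zeroing the nominal overlap band except a kept fraction of
the right image, default 0.5) is available as an optional preprocessing
step; the RANSAC-based crop is the primary overlap-removal mechanism.

## Segmentation network

A SegNet-style encoder–decoder in the SegRoot lineage: L encoder blocks of
conv3×3 → ReLU → dropout → maxpool2, mirrored by L decoder blocks of
nearest-upsample2 → conv3×3 → ReLU → dropout, closed by a 1×1 convolution
and sigmoid. There are no skip connections. Regularisation follows the
recipe that worked for field minirhizotron imagery: dropout rate 0.2 in
every encoder and decoder block, L2 weight penalty 1e-4 (applied as weight
decay on the Adam gradient), and early stopping once the validation loss
has not improved for 20 consecutive epochs; the best-validation-loss
checkpoint is returned. Loss is mean binary cross-entropy on root vs
background; a constant validation loss therefore stops training after
exactly 1 + patience epochs.

The implementation is pure numpy with hand-written backward passes
(im2col convolution, pooling argmax scatter, block-sum upsample gradient).
Numerical choices: He initialisation; inputs scaled to [-0.5, 0.5] —
zero-centering keeps the first convolution well-conditioned and sped up
convergence markedly across seeds; Adam (β = 0.9/0.999) at learning rate
3e-3, chosen over 1e-3 for robust convergence of the narrow preset within
~60 epochs; batch size 16. All randomness (init, dropout, shuffling,
splits) derives from the config seed, so identical data + config give
bit-identical training histories.

Two width presets: **narrow** (4, 8, 16, 32) — 4 levels, trainable on one
CPU in minutes at 32 px patches — and **wide** (64, 128, 256, 512)
mirroring the original SegRoot encoder. Input sides must be divisible by
2^levels; tiled inference rounds the patch size down accordingly.

Images are cut into square patches (default 256 px) on a grid with stride
floor(size × (1 − overlap)), overlap 0.3; the last origin per axis is
clamped so the final patch ends at the image edge, guaranteeing full
coverage. At inference, per-patch probabilities are averaged where patches
overlap and binarised at threshold 0.5 (p ≥ 0.5 is root).

Augmentation applies, per seeded draw: one morphological op on the mask
(dilate or close, 3×3), rotation by 0/90/180/270°, zoom 0.9–1.1 (rescale
then centre-crop/pad), horizontal/vertical flips each with probability 0.5,
brightness and contrast 0.9–1.1, and hue ±0.1 / saturation 0.9–1.1 in HSV.
Geometric transforms hit image and mask; photometric ones the image only;
the mask stays binary throughout.

Dice is the standard set-overlap 2·TP / (GT + Pred), 1 = perfect agreement;
the empty-vs-empty case is defined as 1.0 (needed for all-background
patches). Train/val/test splits default to 0.7/0.15/0.15, seeded.

## Root separation and length

Cleaning removes connected components below 20 px (8-connected) and applies
a morphological opening with a 3×3 **cross** — chosen over the 3×3 square
because the square's erosion severs 3-px-wide roots, the thin end of the
expected width range, while the cross denoises without eating them.

Separation is marker-controlled watershed: the cleaned mask is dilated
(3×3), its Euclidean distance transform computed and smoothed (Gaussian
σ = 1, stabilising plateau ridges), and local maxima (min separation 10 px,
at least one marker per connected component) seed a watershed on the
inverted distance map. Point markers over-fragment elongated ribbons, so
regions are **re-merged wherever the boundary saddle of the distance map
reaches 0.7 of the deeper region's peak** — i.e. where there is no real
constriction. A uniform-width root thus stays one component, while a wide
blob where two roots cross (saddle ≪ crossing peak) keeps its boundaries,
as does a thin root touching a thick one. Labels are finally restricted to
the input foreground, which they partition exactly.

Length is measured on the skeleton of the cleaned mask, computed **once**
globally so label boundaries never truncate it, with skeleton pixels
attributed to labels. From each label's orthogonal (No) and diagonal (Nd)
skeleton step counts (boundary-crossing steps counted half to each side),
length in px is the chain-length estimate

    L = sqrt(Nd² + (Nd + No/2)²) + No/2 ,

exact for straight horizontal/vertical (L = No) and diagonal (L = Nd·√2)
paths and within ~3 % for intermediate orientations. The plain step sum
No + Nd·√2 was rejected: it overestimates arbitrary orientations by ~5.5 %
on average (the classic digital chain-code bias), which alone would consume
the accuracy budget. Conversion to cm is 2.54/dpi, so doubling dpi exactly
halves reported lengths.

For spatial attribution every skeleton pixel carries a length weight (half
the plain step length of its incident edges, rescaled so the label's
weights sum to its chain-length estimate). Depth-bin and quarter sums are
therefore conserved by construction: Σ bins + overflow = Σ quarters = total
length, to floating-point precision.

## Tube geometry

A point at along-tube distance d below the soil entry maps to vertical
depth d·sin(α). Two modes are shipped:

- `paper` (default): α = 60°, i.e. boundary t/sin 60° for target depth t —
  the published conversion for this instrument layout (t = 15 cm → 17.32 cm
  along the tube; t = 30 cm → 34.64 cm).
- `physical`: α = 30°, the trigonometric identity for a tube inclined 30°
  from the surface.

The two differ by the constant factor sin 60°/sin 30° = √3. Both are
exposed because the published conversion is geometrically inconsistent with
a 30°-from-surface installation; fidelity to the published analysis takes
precedence for the default, and the discrepancy is left visible rather than
silently resolved. The soil entry column defaults to the 20 cm of
above-ground tube converted to pixels; columns above it clamp to depth 0
with a warning.

Depth bins are 0–30, 30–60, 60–90, 90–120 cm; length mapping beyond 120 cm
accumulates in an overflow bucket excluded from the profile. Attribution is
length-weighted per skeleton pixel, not per component — components crossing
a bin boundary are split proportionally.

Quarters divide the circumferential (row) axis into four equal bands in the
order above, right, below, left, after rotating by a configurable
`quarter_offset` (the scanner's rotational registration is
instrument-specific and defaults to 0).

## Method comparison

Per depth stratum (topsoil 0–30; pooled subsoil 30–120; each subsoil bin),
minirhizotron root length is regressed on soil-core RLD by closed-form OLS
with R² = 1 − SSres/SStot and a two-sided t-test on the slope. No unit
conversion is applied between core RLD (cm cm⁻³) and minirhizotron length
(cm); the methods are compared on their native scales. Profiles pair with
cores by plot and nearest sampling date within a configurable window
(default 21 days); unmatched profiles are dropped with a logged count, and
strata with fewer than 3 pairs are flagged unfit instead of fitted.
Quarter summaries reduce to a descriptive mean ± sd table (sd of a single
observation reported as missing) plus the tidy long-format table that
external mixed-model software consumes — the mixed-model ANOVA itself is
deliberately out of scope.

## Synthetic data: what it emulates, and what not

Backgrounds are three-band Gaussian noise (correlation lengths ~σ, σ/4 and
8σ, default σ = 4 px) around an earth-tone base, plus pixel grain — enough
fine texture for ORB to find repeatable keypoints, as real gritty soil
provides. Roots are self-avoiding bounded-curvature random-walk polylines
(step 4 px, max turn 0.2 rad, min self-distance 12 px), rasterised at
widths 3–7 px and blended towards a pale root colour at contrast 0.8.
Non-crossing placement (rejection with a 4 px margin) is the default
because length attribution under crossings is estimator-dependent;
crossing scenes can be enabled per spec. Ground-truth lengths are analytic
polyline arc lengths, never re-derived from the raster.

Tube series cut one wide rendered canvas into tiles with exact, known
overlaps; paired method data draw the predictor uniformly on 5–150 cm and
add Gaussian noise to a stated line (with slope 0.0104, intercept 0.10 and
σ = 0.35 the expected R² is ≈ 0.6 at n = 36).

Not modelled: condensation and blur artifacts, soil shrinkage gaps, root
decay and browning, illumination vignetting, or real soil heterogeneity.
Passing the synthetic suite therefore demonstrates the mechanics of the
pipeline — alignment, learnability, measurement accuracy, geometric
bookkeeping — not field-grade segmentation performance, which depends on a
labelled field dataset this package does not ship.

## Problem sizes in the shipped tests

The test suite and acceptance script run desk-scale configurations chosen
as the package's own defaults for reproducible CPU runs: 300×400–500 px
scenes for stitching (100 pairs), 50 scenes for length recovery, 200
patches of 32 px and the narrow width preset for training (60 epochs on
the brightness-threshold rule; 120 for the end-to-end root model), and 200
replicates for regression recovery. Full-scale scans (2551×2315 px) are
supported by the same code paths via the `full-scale` scene dimensions.

## Known limitations

- The stitcher assumes pure horizontal displacement; rotational or vertical
  scanner drift is not corrected.
- Watershed separation of roots crossing at shallow angles with similar
  widths may merge them (no geometric constriction exists to detect).
- The chain-length estimator is unbiased only for straight segments;
  high-curvature wiggles at the pixel scale bias length slightly upward.
- Training the wide preset at 256 px patches is impractical without a GPU;
  the numpy implementation targets the narrow preset.
- Depth attribution ignores the helical path of a root around the tube
  surface; depth is a function of the along-tube coordinate only.
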