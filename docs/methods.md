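# Methods

This note documents the models, conventions, defaults, and known
limitations behind `serialign`, at the level a user needs to judge what
results mean.

## Coordinate and transform conventions

* Coordinates are (x, y), 0-based, pixel-centre; shapes are reported as
  (width, height).
* A rigid transform is a 3×3 homogeneous **similarity** matrix
  (rotation, uniform scale, translation) mapping source coordinates *at
  registration scale* into the registered frame — the reference image's
  preview coordinate system. The reference image's matrix is exactly
  the identity; the canvas (bounding box of all warped images) is
  located by a separate recorded offset so matrices stay invertible.
* Displacement fields are **backward maps**: for each output pixel p
  the field says where to sample the moving image, `out(p) = img(p +
  F(p))`. A zero field is the identity warp, bit-exact. Fields live on
  a crop of the registered frame (the non-rigid bounding box) at their
  own resolution; vectors are multiplied by the resolution ratio
  whenever a field is resized.
* Composition: `compose(outer, inner)(p) = outer(p) + inner(p +
  outer(p))` with bilinear lookup, so warping with the composed field
  equals applying `inner` (nearer the source) then `outer`. Fields are
  inverted, when needed for forward point mapping, by fixed-point
  iteration (15 iterations or max update < 0.05 px).
* Image resampling is backward-mapped bilinear interpolation (nearest
  for label images), executed in tiles (default 2048 px) so a
  full-resolution displacement field is never materialized.

## Colour appearance model

Chroma standardization and background colour distance both run in
CAM16-UCS, implemented in `serialign.color` from the published CAM16
model equations plus the UCS (J′, a′, b′) projection. Fixed viewing
conditions: sRGB primaries, D65 white, Y_b = 20, "average" surround,
L_A = 64/π/5 cd/m², with the model's own (incomplete) chromatic
adaptation. The forward and inverse transforms round-trip to machine
precision; lightness J for the canonical published test stimulus agrees
to six digits. Setting C = 0.2, H = 0 can push bright saturated pixels
out of the sRGB gamut; such pixels are clipped into [0, 1], which is why
chroma standardization is idempotent only for in-gamut pixels.

## Preprocessing and masking choices

* Joint normalization targets are the across-image **means of the
  per-image knots** (5th percentile, mean, 95th percentile, in-mask
  when masks exist). For equal-sized images this tracks the pooled
  statistics; it also makes an identical image list an exact fixed
  point. The mapping is a monotone cubic (PCHIP) — a plain cubic can
  overshoot and de-sort intensities. Knot pairs are sorted and
  deduplicated first; spiky fluorescence histograms can otherwise place
  the mean below the 5th percentile.
* TV denoising weight defaults to 0.01 on [0, 1] images — enough to
  suppress sensor noise without rounding tissue edges.
* Brightfield masks: Otsu on the CAM16-UCS distance to the background
  colour (mean colour of pixels above the 99th luminosity percentile),
  morphological closing (3 px disk), per-component hole filling, and
  removal of components below 0.05% of the image area (dust).
* Fluorescence masks: the channel intensity plays the role of the
  colour-distance image, but is log-compressed and mildly blurred
  (σ = 2 px) before Otsu — otherwise the threshold separates bright
  nuclei from dim cytoplasm instead of tissue from background.
* The default fluorescence registration channel is the first whose name
  contains "dapi" or "hoechst" (case-insensitive), else channel 0.

## Feature matching and filtering

* Default detector/descriptor: scikit-image SIFT with `upsampling=1,
  c_dog=0.004`. Keypoint density matters more than per-keypoint
  quality here: heavily stained, low-contrast sections are exactly the
  ones that decide whether ordering and rigid alignment succeed, and
  the lowered DoG threshold keeps them feature-rich at a fraction of
  the cost of octave upsampling. ORB is available behind the same
  plugin contract `(image, mask) -> (keypoints, descriptors)`.
* Matching is exhaustive with cross-check (no ratio test). RANSAC uses
  a similarity model, 7 px reprojection threshold at registration
  scale, ≤ 2000 trials with early stopping (p = 0.999), and a seed from
  the run configuration — the only stochastic step in the pipeline.
* Tukey filtering warps matches with a preliminary least-squares
  similarity fit and keeps distances within [Q1 − 3·IQR, Q3 + 3·IQR];
  quartiles use linear interpolation so the fences are reproducible.
* Neighbour filtering keeps only matches whose keypoint (by detected
  keypoint identity) also survives matching to the other neighbour in
  the ordered series; below 4 survivors it falls back to the pairwise
  Tukey set with a warning.

## Ordering

Pairwise similarity is the number of post-Tukey matches. The matrix is
standardized to max 1 (diagonal excluded), D = 1 − S′ is clustered with
average linkage, and leaves are arranged by optimal leaf ordering;
orientation is canonicalized (smaller image index first). N < 3 keeps
the input order, as does an all-zero similarity matrix (with a warning).

The dendrogram constraint is a feature, not a limitation. The
unconstrained minimum-adjacent-distance path was tried and rejected: on
synthetic 8-stacks containing one weakly stained (feature-poor) section
it consistently parks that section at a terminus and stitches the two
remaining runs together in the wrong place, while the clustered leaf
order recovers the true sequence. The price is that on *unstructured*
random matrices the leaf order does not always attain the global
minimum-cost path; on serially structured similarity (what the pipeline
actually produces) it does, and that is the property the test suite
checks.

## Serial alignment and the non-rigid stage

Images are aligned *towards* the reference: the pairwise transform of
each image is composed with its inner neighbour's already-accumulated
transform, so errors do not reset at each step and distant features are
progressively drawn together. The optional mutual-information
refinement (Powell search over angle, translation, log-scale,
maximizing MI minus 0.1 × mean feature distance) only replaces a
transform when the objective improves; it is off by default.

The non-rigid mask keeps canvas pixels covered by ≥ 2 rigidly warped
masks plus single-mask components touching them (8-connectivity). Its
bounding box (padded 8 px) is re-extracted from each source at a
resolution targeting `nonrigid.max_dim` (850 px default), re-processed
and re-normalized, and warped by the scaled rigid transforms. Dense
displacement estimation defaults to TV-L1 optical flow (`num_warp=3`);
iterative Lucas–Kanade and a SimpleITK B-spline free-form deformation
are available behind the same plugin contract. Fields are zeroed
outside the non-rigid mask; a backend failure degrades that image to
rigid-only with a warning.

Micro-registration re-extracts the crops at `micro.fraction` of full
resolution, applies the accumulated transforms, estimates residual
fields in 512-px tiles with 25% overlap and linear feathering (empty
tiles contribute zero), and **adds** the residuals to the upsampled
accumulated fields. A `direct_to_reference` flag estimates every
residual against the reference instead of the serial neighbour.

## Error estimation

Feature error uses the post-Tukey (pre-neighbour-filter) matches of the
adjacent pairs in the inferred order: coordinates are scaled to level 0,
pushed through each image's full transform chain, and summarized as the
per-pair median distance (μm when the source records a pixel size) and
the match-count-weighted mean over pairs. Because these features come
from small previews, their localization is coarser than the transforms
themselves, and the estimate consistently sits *above* the true landmark
error on ground-truthed fixtures — read it as a conservative upper
indication, not a precise accuracy measurement. Landmark TRE is the
Euclidean distance between registered landmark pairs (× pixel size);
rTRE divides by the diagonal of the target image. All percentiles use
linear interpolation.

## Synthetic fixtures

The generator emulates a serial-section experiment end to end: a smooth
random blob with multi-octave texture on a bright background; persistent
nuclei (the ground-truth landmarks, tracked exactly through every warp);
*transient* nuclei alive over contiguous runs of sections (feature
turnover — without it the similarity matrix carries no order signal);
a texture random walk along the stack; per-section Beer–Lambert staining
with distinct absorbance vectors (including one heavily absorbing,
low-contrast stain, deliberately kept as a hard case); a random rigid
displacement (defaults: rotation ≤ 10°, translation ≤ 5% of width) and
a Gaussian-smoothed random deformation (default peak 5 px, correlation
length 45 px) applied as exact backward maps. The fluorescence variant
shares one nuclear channel across rounds (stain/wash cycles re-image
the same section, so there is no turnover) plus round-specific marker
channels. All randomness flows from one seed; identical seeds give
bit-identical series.

What the fixtures do **not** emulate: folds and tears, pen marks and
bubbles, out-of-focus regions, chromatic vignetting, and multi-gigapixel
scale. Passing tests therefore demonstrate the correctness of the
algorithmic machinery under controlled deformation and stain variation,
not robustness to every real-world artifact.

Default problem sizes used by the test suite and the acceptance script —
5-section series at 850 px (the pipeline's default registration size),
8-stacks at 420 px for ordering, 2-image pairs at 420 px for rigid
recovery, 3-section series at ~340 px for the error-estimate statistics —
were chosen so a full run completes on a laptop-class single core in
minutes while leaving the registration problem non-trivial (tens of
pixels of initial misalignment, multi-pixel deformations).

## Known limitations

* Vendor WSI formats (.svs, .mrxs, .ndpi) and out-of-core lazy
  evaluation are out of scope; sources are TIFF/OME-TIFF/PNG, flat or
  pyramidal.
* The groupwise simultaneous (3-D B-spline) non-rigid variant is not
  implemented; serial composition is the only accumulation strategy.
* A 3-channel fluorescence stack without metadata is indistinguishable
  from RGB; pass `SlideImage(..., is_rgb=False)` (or read from OME-TIFF
  with channel metadata) to disambiguate.
* With an unknown pixel size all physical-unit outputs fall back to
  pixels, flagged in the report units.
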