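# serialign

Groupwise serial registration of whole-slide histology image series.

Spatial analyses of tissue often need many markers on what is effectively
one section: serial slices stained for different markers, or one section
re-imaged over stain/wash cycles (cyclic IHC, CyCIF). The resulting
images do not line up — tissue is placed differently on every slide,
stretches and tears, and each stain colours it differently — and the
files are far too large to register at native resolution. `serialign`
aligns any number of brightfield and/or fluorescence images of the same
tissue into one coordinate frame, then applies the result to the
native-resolution images and to point data (cell centroids,
annotations).

## Method

Registration is estimated on small previews (max dimension 850 px by
default) and proceeds in stages:

1. **Preprocessing.** Brightfield images are made stain-agnostic by
   flattening every pixel's chroma and hue in the polar CAM16-UCS
   colourspace (C = 0.2, H = 0), converting to grayscale, and inverting
   so tissue is bright on a dark background; fluorescence images use a
   nuclear channel directly. Intensities are then jointly normalized: a
   monotone cubic maps each image's (5th percentile, mean, 95th
   percentile) onto the series-wide knots, followed by mild
   total-variation denoising.
2. **Masking.** The background colour is estimated from the brightest 1%
   of pixels; Otsu thresholding of the per-pixel CAM16-UCS colour
   distance **D**, followed by contour filling, yields a tissue mask.
3. **Matching.** SIFT keypoints inside the mask are matched by brute
   force between all image pairs, filtered by RANSAC (similarity model),
   then by Tukey's outer fences [Q1 − 3·IQR, Q3 + 3·IQR] on the
   distances of features warped with a preliminary similarity fit.
4. **Ordering.** The number of surviving matches builds a similarity
   matrix **S**; after standardizing (max = 1), **D** = 1 − **S**′ is
   clustered (average linkage) and the dendrogram leaves are arranged by
   optimal leaf ordering, so each image neighbours its most similar
   images. A known order can be forced by filename.
5. **Serial rigid registration.** Walking outward from the reference
   (the centre of the ordered stack unless specified), each image is
   aligned to the already-registered version of its inner neighbour by a
   least-squares similarity transform M_i, using only matches shared
   with *both* neighbours (neighbour match filtering).
6. **Serial non-rigid registration.** The rigidly warped masks combine
   into a non-rigid mask whose bounding box is re-extracted at higher
   resolution; dense TV-L1 optical flow estimates per-pair displacement
   fields (X_i, Y_i), accumulated by composition toward the reference so
   distant features are drawn together. An optional tiled
   **micro-registration** pass repeats this at a fraction of full
   resolution and adds the residual fields.
7. **Error estimation.** The median distance between registered matched
   features (μm when the pixel size is known), weighted by match count
   across pairs, summarizes each stage; with landmarks, TRE and
   rTRE (distance divided by the target image diagonal) are reported.

The transform chain (M_i, X_i, Y_i) is scaled on the fly to warp images
at native resolution (tiled, backward mapping) and to warp point
coordinates in either direction.

## Worked example

```python
import numpy as np
from serialign import (SyntheticParams, generate_series, register_series,
                       RunConfig, warp_points)

series = generate_series(SyntheticParams(), seed=1)   # 5 sections, 850 px
result = register_series(series.images, RunConfig())

print("order:", result.ordering.order)
for stage, report in result.errors.items():
    print(f"{stage:12s} {report.sample_error:6.2f} {report.units}")

ref = result.ordering.reference_image
warped = [warp_points(series.landmarks[k], result.chains[k])
          for k in range(5)]
tre = np.concatenate([np.linalg.norm(warped[k] - warped[ref], axis=1)
                      for k in range(5) if k != ref])
print("median landmark TRE:", round(float(np.median(tre)), 2), "px")
```

Output:

```
order: [0, 1, 2, 3, 4]
unregistered  55.88 px
rigid          1.89 px
nonrigid       1.00 px
median landmark TRE: 0.33 px
```

The five synthetic sections, generated with rotations up to ±10°,
translations up to 5% of width and smooth deformations up to 5 px, start
~56 px apart at their matched features; rigid alignment brings them to
~2 px and the composed displacement fields to ~1 px. The feature-based
estimate (1.00 px) sits above the true landmark error (0.33 px) — the
estimate is deliberately conservative.

The same pipeline runs from the shell on a directory of TIFF/OME-TIFF or
PNG images:

```sh
serialign make-fixture demo_slides --seed 1 --n-images 5
serialign register demo_slides -o demo_out
serialign warp-points demo_out demo_slides/section_01_landmarks.csv \
    --image section_01 -o warped.csv
```

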