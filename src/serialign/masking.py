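"""Tissue masks from colour distance to the background.

Brightfield slides have a bright, near-white background.  Its colour is
estimated as the mean CAM16-UCS colour of the brightest pixels (luminosity
above the 99th percentile); the per-pixel Euclidean distance to that colour
in (J', a', b') forms an image D in which tissue stands out regardless of
stain.  Otsu thresholding of D followed by hole filling of each connected
component yields the mask.  For fluorescence the background is dark, so the
processed channel itself plays the role of D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .color import srgb_to_cam16ucs
from .preprocessing import ProcessedImage, _as_unit_rgb
from .slide_io import ScalarImage

__all__ = [
    "TissueMask",
    "estimate_background_color",
    "color_distance_image",
    "make_tissue_mask",
]

MIN_COMPONENT_FRAC = 0.0005  # discard debris below 0.05% of image area
CLOSING_RADIUS = 3


@dataclass
class TissueMask:
    """Binary tissue mask with no interior holes."""

    mask: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def estimate_background_color(rgb: np.ndarray) -> np.ndarray:
    """Mean CAM16-UCS colour of pixels brighter than the 99th percentile.

    Returns an (L, A, B)-like triple (J', a', b' on unit scale).  Falls
    back to the single brightest pixel if the percentile selection is
    empty (constant images).
    """
    unit, _ = _as_unit_rgb(rgb)
    jab = srgb_to_cam16ucs(unit)
    J = jab[..., 0]
    cutoff = np.percentile(J, 99)
    sel = J > cutoff
    if not sel.any():
        sel = J >= J.max()
    return jab[sel].mean(axis=0)


def color_distance_image(rgb: np.ndarray, bg: np.ndarray,
                         scale: float = 1.0) -> ScalarImage:
    """Per-pixel Euclidean distance to ``bg`` in CAM16-UCS -> image D."""
    unit, _ = _as_unit_rgb(rgb)
    jab = srgb_to_cam16ucs(unit)
    d = np.linalg.norm(jab - np.asarray(bg), axis=-1)
    return ScalarImage(pixels=d, scale=scale)


def _fluorescence_distance(chan: np.ndarray) -> np.ndarray:
    """Single-channel analogue of the colour-distance image D.

    Background is dark, so intensity itself measures distance from
    background; log compression and a mild blur keep Otsu from splitting
    bright nuclei off the dimmer tissue instead of tissue off background.
    """
    peak = chan.max()
    if peak <= 0:
        return chan.astype(float)
    return ndi.gaussian_filter(np.log1p(10.0 * chan / peak), 2.0)


def _fill_and_clean(fg: np.ndarray) -> np.ndarray:
    """Close small gaps, fill holes per component, drop debris."""
    closed = ndi.binary_closing(fg, structure=disk(CLOSING_RADIUS))
    filled = ndi.binary_fill_holes(closed)
    labels, n = ndi.label(filled)
    if n == 0:
        return filled
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_size = MIN_COMPONENT_FRAC * fg.size
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep)


def make_tissue_mask(img: np.ndarray | ProcessedImage,
                     scale: float = 1.0) -> TissueMask:
    """Build a filled tissue mask.

    RGB input: Otsu threshold on the colour distance to the estimated
    background.  Single-channel (fluorescence-style) input: Otsu threshold
    on the intensities directly.  A constant distance image (degenerate
    Otsu) yields an empty mask with a warning.
    """
    if isinstance(img, ProcessedImage):
        d = _fluorescence_distance(img.pixels)
        scale = img.scale
    else:
        arr = np.asarray(img)
        if arr.ndim == 3:
            bg = estimate_background_color(arr)
            d = color_distance_image(arr, bg, scale=scale).pixels
        else:
            d = _fluorescence_distance(arr.astype(float))
    if np.ptp(d) < 1e-12:
        warnings.warn("constant image: Otsu threshold undefined, mask is empty")
        return TissueMask(mask=np.zeros(d.shape, dtype=bool), scale=scale)
    thresh = threshold_otsu(d)
    return TissueMask(mask=_fill_and_clean(d > thresh), scale=scale)
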