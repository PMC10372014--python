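"""Stain-agnostic preprocessing.

Brightfield images of differently stained sections look wildly different;
before features can be matched across them every image is reduced to a
single channel in which tissue is bright and background dark:

* chroma standardization — each pixel's chroma and hue in polar CAM16-UCS
  are replaced by fixed values (C = 0.2, H = 0 by default), keeping only
  lightness.  This makes any stain look like any other without needing a
  stain matrix.
* inverted grayscale — the standardized RGB is converted to luminance and
  inverted so the bright slide background becomes dark.
* fluorescence images skip both steps: a single channel (DAPI-like by
  default) is range-normalized, background is already dark.

The processed images are then jointly normalized: pooled 5th percentile,
mean and 95th percentile act as target knots of a monotone cubic mapping
applied to each image's own knots.  A final mild total-variation denoise
smooths sensor noise while keeping tissue edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from skimage.color import rgb2gray
from skimage.restoration import denoise_tv_chambolle

from .color import jch_to_srgb, srgb_to_jch
from .slide_io import SlideImage

__all__ = [
    "ProcessedImage",
    "standardize_chroma",
    "to_inverted_grayscale",
    "process_fluorescence",
    "process_brightfield",
    "normalize_image_set",
    "denoise",
]

DEFAULT_CHROMA = 0.2
DEFAULT_HUE = 0.0
DEFAULT_TV_WEIGHT = 0.01
DAPI_ALIASES = ("dapi", "hoechst")


@dataclass
class ProcessedImage:
    """Single-channel float image at registration scale, tissue bright."""

    pixels: np.ndarray
    scale: float = 1.0
    source_index: int = -1
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("processed image must be single-channel (2D)")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match pixels")


def _as_unit_rgb(rgb: np.ndarray) -> tuple[np.ndarray, float]:
    """Return image scaled into [0, 1] plus the factor to restore its range."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    peak = 255.0 if rgb.max() > 1.0 else 1.0
    return rgb / peak, peak


def standardize_chroma(
    rgb: np.ndarray, chroma: float = DEFAULT_CHROMA, hue: float = DEFAULT_HUE
) -> np.ndarray:
    """Set every pixel's chroma/hue in polar CAM16-UCS, keeping lightness.

    ``chroma`` is on the unit CAM16-UCS scale (0.2 default) and ``hue`` in
    degrees.  The output has the same shape and value range as the input.
    Idempotent up to colourspace round-trip error.
    """
    unit, peak = _as_unit_rgb(rgb)
    jch = srgb_to_jch(unit)
    jch[..., 1] = chroma
    jch[..., 2] = hue
    out = jch_to_srgb(jch)
    out = np.clip(out, 0.0, 1.0) * peak
    return out.astype(rgb.dtype) if np.issubdtype(np.asarray(rgb).dtype, np.integer) else out


def to_inverted_grayscale(rgb: np.ndarray, scale: float = 1.0,
                          source_index: int = -1) -> ProcessedImage:
    """Luminance-weighted grayscale, inverted so tissue is bright on dark."""
    unit, _ = _as_unit_rgb(rgb)
    gray = rgb2gray(unit)
    return ProcessedImage(pixels=gray.max() - gray, scale=scale,
                          source_index=source_index)


def process_brightfield(
    rgb: np.ndarray,
    chroma: float = DEFAULT_CHROMA,
    hue: float = DEFAULT_HUE,
    scale: float = 1.0,
    source_index: int = -1,
) -> ProcessedImage:
    """Chroma standardization followed by inverted grayscale."""
    flat = standardize_chroma(rgb, chroma=chroma, hue=hue)
    return to_inverted_grayscale(flat, scale=scale, source_index=source_index)


def default_fluorescence_channel(channel_names: list[str]) -> int:
    """First channel whose name looks like a nuclear stain, else channel 0."""
    for i, name in enumerate(channel_names):
        if any(alias in name.lower() for alias in DAPI_ALIASES):
            return i
    return 0


def process_fluorescence(
    slide: SlideImage | np.ndarray,
    channel: int | str | None = None,
    scale: float = 1.0,
    source_index: int = -1,
) -> ProcessedImage:
    """Select one fluorescence channel and range-normalize it to [0, 1].

    No inversion: fluorescence background is already dark.  A constant
    channel is passed through unchanged (no divide by zero).
    """
    if isinstance(slide, SlideImage):
        if channel is None:
            idx = default_fluorescence_channel(slide.channel_names)
        else:
            idx = slide.channel_index(channel)
        arr = slide.levels[0]
    else:
        arr = np.asarray(slide)
        idx = 0 if channel is None else int(channel)
        if arr.ndim == 3 and not 0 <= idx < arr.shape[2]:
            raise KeyError(f"channel index {idx} out of range")
    chan = arr[..., idx].astype(float) if arr.ndim == 3 else arr.astype(float)
    peak = chan.max()
    if peak > 0:
        chan = chan / peak
    return ProcessedImage(pixels=chan, scale=scale, source_index=source_index)


def _knots(img: ProcessedImage) -> np.ndarray:
    px = img.pixels[img.mask.astype(bool)] if img.mask is not None else img.pixels.ravel()
    if px.size == 0:
        px = img.pixels.ravel()
    return np.array([
        np.percentile(px, 5, method="linear"),
        float(px.mean()),
        np.percentile(px, 95, method="linear"),
    ])


def normalize_image_set(images: list[ProcessedImage]) -> list[ProcessedImage]:
    """Jointly normalize intensities across the series.

    Target knots (5th percentile, mean, 95th percentile) are computed from
    the pooled pixels of all images (in-mask pixels when masks exist); each
    image is remapped by a monotone cubic through its own knots onto the
    targets.  Images whose knots are degenerate (nearly constant) are
    returned unchanged with a warning.
    """
    if not images:
        raise ValueError("need at least one image")
    # target knots: the series-wide 5th pct / mean / 95th pct, taken as the
    # mean of the per-image statistics (identical lists are exact fixed
    # points; for equal-sized images this tracks the pooled statistics)
    all_knots = np.array([_knots(im) for im in images])
    target = all_knots.mean(axis=0)
    lo = float(np.mean([im.pixels.min() for im in images]))
    hi = float(np.mean([im.pixels.max() for im in images]))
    out = []
    for im in images:
        src = _knots(im)
        src_full = np.concatenate([[im.pixels.min()], src, [im.pixels.max()]])
        tgt_full = np.concatenate([[lo], target, [hi]])
        # spiky histograms can put the mean below the 5th percentile;
        # sort the knot pairs, then drop duplicates
        order = np.argsort(src_full, kind="stable")
        src_full, tgt_full = src_full[order], tgt_full[order]
        keep = np.concatenate([[True], np.diff(src_full) > 1e-9])
        if keep.sum() < 3:
            warnings.warn(
                f"image {im.source_index}: degenerate intensity knots; "
                "returned unnormalized"
            )
            out.append(im)
            continue
        src_k, tgt_k = src_full[keep], tgt_full[keep]
        # monotone targets are required for a monotone map
        tgt_k = np.maximum.accumulate(tgt_k)
        mapper = PchipInterpolator(src_k, tgt_k, extrapolate=True)
        mapped = np.clip(mapper(im.pixels), lo, hi)
        out.append(ProcessedImage(pixels=mapped, scale=im.scale,
                                  source_index=im.source_index, mask=im.mask))
    return out


def denoise(img: ProcessedImage, weight: float = DEFAULT_TV_WEIGHT) -> ProcessedImage:
    """Mild total-variation denoising; ``weight=0`` is the identity."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight == 0:
        return img
    den = denoise_tv_chambolle(img.pixels, weight=weight)
    return ProcessedImage(pixels=den, scale=img.scale,
                          source_index=img.source_index, mask=img.mask)
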