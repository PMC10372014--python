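"""Applying transform chains to native-resolution images and points.

Registration is estimated on small previews, but its result — a rigid
matrix plus an accumulated displacement field per image — can be scaled
to warp the original image at any resolution, and to warp point data
(cell centroids, annotations) between a slide and the registered frame.

Conventions: the rigid matrix maps source (x, y) at registration scale
into the registered frame (the reference image's preview coordinates);
the displacement field is a backward map in the registered frame; the
canvas is the bounding box of all rigidly warped images, located by
``canvas_offset``.  Images are resampled by backward mapping in tiles,
so a full-resolution displacement field is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .nonrigid import DisplacementField
from .rigid import RigidTransform
from .slide_io import SlideImage

__all__ = ["TransformChain", "scale_chain", "warp_image", "warp_points",
           "merge_channels"]

TILE_SIZE = 2048


@dataclass
class TransformChain:
    """Everything needed to place one image into the registered frame."""

    rigid: RigidTransform
    nonrigid: DisplacementField | None = None
    registration_scale: float = 1.0
    full_shape: tuple[int, int] = (0, 0)  # (w, h) of the source at level 0
    canvas_offset: tuple[float, float] = (0.0, 0.0)
    canvas_shape: tuple[int, int] = (0, 0)  # (w, h) at registration scale

    def displacement_at(self, p_reg: np.ndarray) -> np.ndarray:
        """Non-rigid displacement (registration-scale px) at registered points."""
        if self.nonrigid is None:
            return np.zeros_like(p_reg)
        f = self.nonrigid
        x0, y0, _, _ = f.bbox
        crop_xy = (p_reg - np.array([x0, y0])) * f.scale
        return f.sample(crop_xy) / f.scale

    def backward_map(self, p_reg: np.ndarray) -> np.ndarray:
        """Registered-frame points -> source points (registration scale)."""
        moved = p_reg + self.displacement_at(p_reg)
        return self.rigid.inverse().apply(moved)


def scale_chain(chain: TransformChain, target_scale: float) -> TransformChain:
    """Re-express a chain at another working scale.

    The rigid matrix is conjugated by the scale change (S M S^-1), the
    canvas geometry is rescaled, and the displacement field's vectors
    are multiplied by the scale ratio.  ``target_scale`` is relative to
    full resolution, like ``registration_scale``.
    """
    k = target_scale / chain.registration_scale
    if abs(k - 1.0) < 1e-12:
        return chain
    S = np.diag([k, k, 1.0])
    Sinv = np.diag([1.0 / k, 1.0 / k, 1.0])
    rigid = RigidTransform(matrix=S @ chain.rigid.matrix @ Sinv,
                           scale_at_fit=chain.rigid.scale_at_fit)
    nr = None
    if chain.nonrigid is not None:
        f = chain.nonrigid
        new_shape = (max(1, int(round(f.X.shape[0] * k))),
                     max(1, int(round(f.X.shape[1] * k))))
        g = f.resized(new_shape)
        x0, y0, w, h = f.bbox
        nr = DisplacementField(X=g.X, Y=g.Y,
                               bbox=(x0 * k, y0 * k, w * k, h * k),
                               scale=g.scale / k)
    return TransformChain(
        rigid=rigid, nonrigid=nr, registration_scale=target_scale,
        full_shape=chain.full_shape,
        canvas_offset=(chain.canvas_offset[0] * k, chain.canvas_offset[1] * k),
        canvas_shape=(int(round(chain.canvas_shape[0] * k)),
                      int(round(chain.canvas_shape[1] * k))),
    )


def warp_image(image: np.ndarray, chain: TransformChain,
               interpolation: str = "bilinear",
               source_scale: float | None = None,
               target_scale: float | None = None,
               background: float = 0.0,
               tile_size: int = TILE_SIZE) -> np.ndarray:
    """Resample a source image into the registered canvas.

    ``source_scale``/``target_scale`` are relative to full resolution and
    default to the scale implied by the image width (source) and to the
    source scale (target).  ``interpolation`` is "bilinear" for intensity
    images or "nearest" for label images.  Large outputs are processed in
    tiles.
    """
    image = np.asarray(image)
    r = chain.registration_scale
    if source_scale is None:
        source_scale = (image.shape[1] / chain.full_shape[0]
                        if chain.full_shape[0] else r)
    if target_scale is None:
        target_scale = source_scale
    order = {"nearest": 0, "bilinear": 1}[interpolation]
    out_w = max(1, int(round(chain.canvas_shape[0] * target_scale / r)))
    out_h = max(1, int(round(chain.canvas_shape[1] * target_scale / r)))
    bands = image[..., None] if image.ndim == 2 else image
    out = np.full((out_h, out_w, bands.shape[2]), background, dtype=float)
    off = np.asarray(chain.canvas_offset, dtype=float)
    for y0 in range(0, out_h, tile_size):
        for x0 in range(0, out_w, tile_size):
            y1 = min(y0 + tile_size, out_h)
            x1 = min(x0 + tile_size, out_w)
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            p_reg = pts * (r / target_scale) + off
            src = chain.backward_map(p_reg) * (source_scale / r)
            coords = [src[:, 1].reshape(yy.shape), src[:, 0].reshape(yy.shape)]
            for c in range(bands.shape[2]):
                out[y0:y1, x0:x1, c] = ndi.map_coordinates(
                    bands[..., c].astype(float), coords, order=order,
                    mode="constant", cval=background)
    out = out[..., 0] if image.ndim == 2 else out
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def warp_points(xy: np.ndarray, chain: TransformChain,
                inverse: bool = False, return_flags: bool = False):
    """Warp level-0 point coordinates through a chain.

    Forward maps slide coordinates into the registered canvas (level-0
    scale); ``inverse`` maps canvas coordinates back onto the slide.
    Points falling outside the displacement-field domain are carried by
    the rigid part alone and flagged (``return_flags=True`` returns the
    boolean flag array as a second value).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    r = chain.registration_scale
    off = np.asarray(chain.canvas_offset, dtype=float)
    f = chain.nonrigid
    if inverse:
        p_reg = xy * r + off
        src = chain.backward_map(p_reg) / r
        outside = _outside_field(p_reg, f)
        return (src, outside) if return_flags else src
    p_rigid = chain.rigid.apply(xy * r)
    p = p_rigid.copy()
    if f is not None:
        for _ in range(15):
            disp = chain.displacement_at(p)
            p_new = p_rigid - disp
            if np.abs(p_new - p).max() < 0.05 * r:
                p = p_new
                break
            p = p_new
    outside = _outside_field(p, f)
    result = (p - off) / r
    return (result, outside) if return_flags else result


def _outside_field(p_reg: np.ndarray, f: DisplacementField | None):
    if f is None:
        return np.zeros(len(p_reg), dtype=bool)
    x0, y0, w, h = f.bbox
    return ~((p_reg[:, 0] >= x0) & (p_reg[:, 0] <= x0 + w)
             & (p_reg[:, 1] >= y0) & (p_reg[:, 1] <= y0 + h))


def merge_channels(slides: list[SlideImage],
                   keep_duplicate_names: bool = True) -> SlideImage:
    """Stack the channels of registered fluorescence slides.

    All slides must already be warped onto the common canvas (identical
    level-0 shapes).  Channel names are prefixed with the slide name;
    with ``keep_duplicate_names=False``, repeated bare channel names
    (e.g. one DAPI per round) are kept only from the first slide that
    has them.
    """
    if not slides:
        raise ValueError("no slides to merge")
    shapes = {s.levels[0].shape[:2] for s in slides}
    if len(shapes) != 1:
        raise ValueError("slides must share the registered canvas shape")
    chans, names, seen = [], [], set()
    for s in slides:
        arr = s.levels[0]
        arr = arr[..., None] if arr.ndim == 2 else arr
        for c, cname in enumerate(s.channel_names):
            if not keep_duplicate_names:
                if cname.lower() in seen:
                    continue
                seen.add(cname.lower())
            chans.append(arr[..., c])
            names.append(f"{s.name}_{cname}")
    merged = np.stack(chans, axis=-1)
    return SlideImage(name="merged", levels=[merged], channel_names=names,
                      is_rgb=False, pixel_size_um=slides[0].pixel_size_um)
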