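"""Serial non-rigid registration via composed displacement fields.

After rigid alignment, residual local deformation (stretching, folds,
section-to-section tissue change) is captured by per-image 2D
displacement fields.  Fields follow the backward-mapping convention: for
each output pixel, the field says where to sample the moving image, so a
zero field is the identity warp.

Fields are estimated on higher-resolution crops: the rigidly warped
tissue masks are combined into a non-rigid mask (areas covered by at
least two masks, plus single-mask components touching them) whose
bounding box is re-extracted from each source at a resolution chosen so
its longest side is near a target size.  Pairwise fields are estimated
between adjacent images in series order (dense variational TV-L1 optical
flow by default) and accumulated by composition walking outward from the
reference, so transformations accumulate and distant features are drawn
together.  An optional micro-registration pass repeats the estimation at
a fraction of full resolution, in overlapping feathered tiles, and adds
the residual fields to the accumulated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import optical_flow_ilk, optical_flow_tvl1
from skimage.transform import SimilarityTransform, resize, warp

from .masking import TissueMask
from .preprocessing import ProcessedImage
from .rigid import RigidResult, RigidTransform

__all__ = [
    "DisplacementField",
    "build_nonrigid_mask",
    "extract_nonrigid_images",
    "estimate_displacement",
    "compose_displacements",
    "serial_nonrigid_register",
    "micro_register",
    "warp_with_field",
    "invert_field",
]


class MaskOverlapError(RuntimeError):
    """Rigid alignment left the tissue masks disjoint."""


@dataclass
class DisplacementField:
    """Backward-mapping displacement field on a registered-frame crop.

    ``X``/``Y`` hold x- and y-displacements in crop pixels on the crop
    grid.  ``bbox`` = (x0, y0, w, h) locates the crop in registered-frame
    registration-scale coordinates; ``scale`` is crop resolution over
    registration resolution, so a registered-frame point (x, y) maps to
    crop pixel ((x - x0) * scale, (y - y0) * scale).
    """

    X: np.ndarray
    Y: np.ndarray
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have the same shape")
        if not np.isfinite(self.X).all() or not np.isfinite(self.Y).all():
            raise ValueError("displacement fields must be finite")
        if self.bbox == (0.0, 0.0, 0.0, 0.0):
            h, w = self.X.shape
            self.bbox = (0.0, 0.0, w / self.scale, h / self.scale)

    @classmethod
    def zero(cls, shape: tuple[int, int], bbox=None,
             scale: float = 1.0) -> "DisplacementField":
        z = np.zeros(shape)
        if bbox is None:
            return cls(X=z, Y=z.copy(), scale=scale)
        return cls(X=z, Y=z.copy(), bbox=bbox, scale=scale)

    @property
    def shape(self):
        return self.X.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.X, self.Y)

    def sample(self, xy_crop: np.ndarray) -> np.ndarray:
        """Displacement (crop px) at crop-pixel positions; zero outside."""
        xy = np.atleast_2d(np.asarray(xy_crop, dtype=float))
        coords = np.stack([xy[:, 1], xy[:, 0]])
        dx = ndi.map_coordinates(self.X, coords, order=1, mode="constant")
        dy = ndi.map_coordinates(self.Y, coords, order=1, mode="constant")
        return np.column_stack([dx, dy])

    def resized(self, new_shape: tuple[int, int]) -> "DisplacementField":
        """Resample the field grid; vectors are rescaled with resolution."""
        if new_shape == self.X.shape:
            return self
        fy = new_shape[0] / self.X.shape[0]
        fx = new_shape[1] / self.X.shape[1]
        X = resize(self.X, new_shape, order=1, preserve_range=True) * fx
        Y = resize(self.Y, new_shape, order=1, preserve_range=True) * fy
        return DisplacementField(X=X, Y=Y, bbox=self.bbox,
                                 scale=self.scale * (fx + fy) / 2)


def warp_with_field(image: np.ndarray, field: DisplacementField,
                    order: int = 1, cval: float = 0.0) -> np.ndarray:
    """out(p) = image(p + F(p)); a zero field returns the input bit-exact."""
    if not field.X.any() and not field.Y.any():
        return np.asarray(image).copy()
    h, w = field.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndi.map_coordinates(np.asarray(image, dtype=float),
                               [yy + field.Y, xx + field.X],
                               order=order, mode="constant", cval=cval)


def build_nonrigid_mask(masks: list[TissueMask], rigid: RigidResult,
                        pad: int = 8) -> tuple[TissueMask, tuple]:
    """Combine rigidly warped masks into the non-rigid registration mask.

    Pixels covered by at least two warped masks are kept, together with
    connected components of single-mask coverage that touch them
    (8-connectivity).  Returns the mask on the rigid canvas and its
    padded bounding box (x0, y0, w, h).  Raises
    :class:`MaskOverlapError` when no two masks overlap at all.
    """
    from .rigid import warp_rigid

    cw, ch = rigid.canvas_shape
    cov = np.zeros((ch, cw), dtype=np.int32)
    for m, t in zip(masks, rigid.transforms):
        warped = warp_rigid(m.mask.astype(float), t,
                            canvas_offset=rigid.canvas_offset,
                            canvas_shape=rigid.canvas_shape, order=0)
        cov += warped > 0.5
    core = cov >= 2
    if not core.any():
        raise MaskOverlapError(
            "rigidly warped tissue masks do not overlap; rigid "
            "registration failed")
    singles = cov == 1
    labels, n = ndi.label(singles, structure=np.ones((3, 3)))
    touch = ndi.binary_dilation(core, structure=np.ones((3, 3)))
    keep_ids = np.unique(labels[touch & singles])
    keep_ids = keep_ids[keep_ids > 0]
    final = core | np.isin(labels, keep_ids)
    rows = np.any(final, axis=1)
    cols = np.any(final, axis=0)
    y0, y1 = np.flatnonzero(rows)[[0, -1]]
    x0, x1 = np.flatnonzero(cols)[[0, -1]]
    x0 = max(0, x0 - pad)
    y0 = max(0, y0 - pad)
    x1 = min(cw - 1, x1 + pad)
    y1 = min(ch - 1, y1 + pad)
    bbox = (float(x0 + rigid.canvas_offset[0]),
            float(y0 + rigid.canvas_offset[1]),
            float(x1 - x0 + 1), float(y1 - y0 + 1))
    return TissueMask(mask=final, scale=masks[0].scale), bbox


def extract_rigid_crop(image: np.ndarray, transform: RigidTransform,
                       bbox: tuple, scale: float = 1.0, order: int = 1,
                       cval: float = 0.0,
                       src_scale: float = 1.0) -> np.ndarray:
    """Warp ``image`` by its rigid transform and crop to ``bbox``.

    ``scale`` is the crop resolution over registration resolution;
    ``src_scale`` is the source array's resolution over registration
    resolution (>1 when re-read from a finer pyramid level).  Crop pixel
    q maps to source pixel src_scale * M^-1 (q / scale + origin).
    """
    x0, y0, w, h = bbox
    out_shape = (int(round(h * scale)), int(round(w * scale)))
    A = np.array([[1 / scale, 0, x0], [0, 1 / scale, y0], [0, 0, 1]])
    S = np.diag([src_scale, src_scale, 1.0])
    inv_map = SimilarityTransform(
        matrix=S @ np.linalg.inv(transform.matrix) @ A)
    return warp(np.asarray(image, dtype=float), inv_map, order=order,
                cval=cval, output_shape=out_shape, preserve_range=True)


def extract_nonrigid_images(
    sources: list,
    rigid: RigidResult,
    bbox: tuple,
    target_dim: int = 850,
    process=None,
    registration_scale: float = 1.0,
) -> tuple[list[ProcessedImage], float]:
    """Slice the non-rigid bounding box out of each source at higher detail.

    ``sources`` may be raw arrays (already at registration scale) or
    callables ``f(desired_scale) -> (array, actual_scale)`` re-reading a
    finer pyramid level (scales relative to registration scale).
    ``process`` turns a raw array into a 2D processed image before
    warping.  Returns the crops (one per image, common shape) and the
    crop scale actually used.
    """
    x0, y0, w, h = bbox
    upscale = target_dim / max(w, h)
    upscale = max(upscale, 1e-6)
    # never exceed native resolution
    max_upscale = 1.0 / registration_scale
    scale = min(upscale, max_upscale)
    crops = []
    for idx, (src, t) in enumerate(zip(sources, rigid.transforms)):
        if callable(src):
            arr, src_scale = src(scale)
        else:
            arr, src_scale = src, 1.0
        if process is not None:
            arr = process(arr, idx)
        if isinstance(arr, ProcessedImage):
            arr = arr.pixels
        crop = extract_rigid_crop(arr, t, bbox, scale=scale,
                                  src_scale=src_scale)
        crops.append(ProcessedImage(pixels=crop, scale=scale,
                                    source_index=idx))
    return crops, scale


# ---------------------------------------------------------------------------
# displacement estimation backends

def _flow_tvl1(fixed, moving):
    v = optical_flow_tvl1(fixed, moving, num_warp=3)
    return v[1], v[0]


def _flow_ilk(fixed, moving):
    v = optical_flow_ilk(fixed, moving, radius=16)
    return v[1], v[0]


def _flow_bspline(fixed, moving):
    """Free-form B-spline deformation via SimpleITK (optional backend)."""
    import SimpleITK as sitk

    f = sitk.GetImageFromArray(fixed.astype(np.float32))
    m = sitk.GetImageFromArray(moving.astype(np.float32))
    mesh = [max(2, s // 64) for s in fixed.shape[::-1]]
    tx0 = sitk.BSplineTransformInitializer(f, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(32)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=50)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(tx0, inPlace=True)
    tx = reg.Execute(f, m)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(f)
    disp = sitk.GetArrayFromImage(filt.Execute(tx))
    return disp[..., 0], disp[..., 1]


FLOW_METHODS = {"tvl1": _flow_tvl1, "ilk": _flow_ilk, "bspline": _flow_bspline}


def estimate_displacement(moving: ProcessedImage | np.ndarray,
                          fixed: ProcessedImage | np.ndarray,
                          method="tvl1",
                          mask: np.ndarray | None = None) -> DisplacementField:
    """Estimate the backward field warping ``moving`` onto ``fixed``.

    Sampling the moving image at (x + X, y + Y) approximates the fixed
    image.  The field is zeroed outside ``mask`` when one is given.  A
    backend failure degrades to a zero field with a warning (rigid-only
    for that image).
    """
    mv = moving.pixels if isinstance(moving, ProcessedImage) else np.asarray(moving)
    fx = fixed.pixels if isinstance(fixed, ProcessedImage) else np.asarray(fixed)
    if mv.shape != fx.shape:
        raise ValueError("moving and fixed must have the same shape")
    fn = FLOW_METHODS[method] if isinstance(method, str) else method
    try:
        X, Y = fn(fx.astype(float), mv.astype(float))
    except Exception as exc:
        warnings.warn(f"displacement estimation failed ({exc}); "
                      "falling back to a zero field")
        X = np.zeros(mv.shape)
        Y = np.zeros(mv.shape)
    if mask is not None:
        X = X * mask
        Y = Y * mask
    return DisplacementField(X=X, Y=Y)


def compose_displacements(outer: DisplacementField,
                          inner: DisplacementField) -> DisplacementField:
    """Functional composition of two backward maps on a shared grid.

    The composed field C satisfies C(p) = outer(p) + inner(p + outer(p)),
    i.e. warping with C equals warping with ``inner`` first (closer to
    the source) and ``outer`` second.  A zero field is the neutral
    element on either side.
    """
    if outer.shape != inner.shape:
        inner = inner.resized(outer.shape)
    h, w = outer.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    px = xx + outer.X
    py = yy + outer.Y
    ix = ndi.map_coordinates(inner.X, [py, px], order=1, mode="nearest")
    iy = ndi.map_coordinates(inner.Y, [py, px], order=1, mode="nearest")
    return DisplacementField(X=outer.X + ix, Y=outer.Y + iy, bbox=outer.bbox,
                             scale=outer.scale)


def invert_field(field: DisplacementField, iterations: int = 15,
                 tol: float = 0.05) -> DisplacementField:
    """Numerically invert a smooth backward field by fixed-point iteration.

    Finds G with G(p) approx -F(p + G(p)), so composing F and G is near
    zero.  Stops after ``iterations`` rounds or when the maximum update
    falls below ``tol`` pixels.
    """
    h, w = field.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    Gx = -field.X.copy()
    Gy = -field.Y.copy()
    for _ in range(iterations):
        px = xx + Gx
        py = yy + Gy
        nx = -ndi.map_coordinates(field.X, [py, px], order=1, mode="nearest")
        ny = -ndi.map_coordinates(field.Y, [py, px], order=1, mode="nearest")
        update = max(np.abs(nx - Gx).max(), np.abs(ny - Gy).max())
        Gx, Gy = nx, ny
        if update < tol:
            break
    return DisplacementField(X=Gx, Y=Gy, bbox=field.bbox, scale=field.scale)


def serial_nonrigid_register(
    images: list[ProcessedImage],
    ordering,
    method="tvl1",
    mask: np.ndarray | None = None,
) -> list[DisplacementField]:
    """Estimate accumulated fields for rigidly aligned crops, serially.

    ``images`` are the non-rigid crops (same shape, already rigidly
    warped into the crop frame), indexed by series position.  The
    reference image gets a zero field; walking outward, each image's
    field composes its inner neighbor's accumulated field with the
    pairwise field estimated against that neighbor's rigid image.
    """
    n = len(images)
    order = ordering.order or list(range(n))
    ref_pos = ordering.reference_index if ordering.reference_index >= 0 else n // 2
    shape = images[0].pixels.shape
    scale = images[0].scale
    fields: list[DisplacementField | None] = [None] * n
    fields[order[ref_pos]] = DisplacementField.zero(shape, scale=scale)

    def step(pos, inner_pos):
        img, inner = order[pos], order[inner_pos]
        pairwise = estimate_displacement(images[img], images[inner],
                                         method=method, mask=mask)
        acc = compose_displacements(fields[inner], pairwise)
        fields[img] = DisplacementField(X=acc.X, Y=acc.Y, scale=scale)

    for pos in range(ref_pos - 1, -1, -1):
        step(pos, pos + 1)
    for pos in range(ref_pos + 1, n):
        step(pos, pos - 1)
    return fields  # type: ignore[return-value]


def _tile_slices(h, w, tile, overlap):
    step = max(tile - overlap, 1)
    ys = list(range(0, max(h - overlap, 1), step))
    xs = list(range(0, max(w - overlap, 1), step))
    for y in ys:
        for x in xs:
            yield slice(y, min(y + tile, h)), slice(x, min(x + tile, w))


def _feather(shape, sl_y, sl_x, overlap):
    h = sl_y.stop - sl_y.start
    w = sl_x.stop - sl_x.start
    wy = np.ones(h)
    wx = np.ones(w)
    ramp = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
    if sl_y.start > 0 and h > overlap:
        wy[:overlap] = ramp
    if sl_y.stop < shape[0] and h > overlap:
        wy[-overlap:] = ramp[::-1]
    if sl_x.start > 0 and w > overlap:
        wx[:overlap] = ramp
    if sl_x.stop < shape[1] and w > overlap:
        wx[-overlap:] = ramp[::-1]
    return np.outer(wy, wx)


def tiled_displacement(moving: np.ndarray, fixed: np.ndarray, method="tvl1",
                       tile: int = 512, overlap_frac: float = 0.25,
                       mask: np.ndarray | None = None) -> DisplacementField:
    """Estimate a field tile by tile with linear feathering in overlaps.

    Tiles with no tissue (empty mask) contribute a zero residual.
    """
    h, w = fixed.shape
    if max(h, w) <= tile:
        return estimate_displacement(moving, fixed, method=method, mask=mask)
    overlap = int(tile * overlap_frac)
    accX = np.zeros((h, w))
    accY = np.zeros((h, w))
    weight = np.zeros((h, w))
    for sl_y, sl_x in _tile_slices(h, w, tile, overlap):
        sub_mask = mask[sl_y, sl_x] if mask is not None else None
        if sub_mask is not None and not sub_mask.any():
            continue
        sub = estimate_displacement(moving[sl_y, sl_x], fixed[sl_y, sl_x],
                                    method=method, mask=sub_mask)
        wgt = _feather((h, w), sl_y, sl_x, overlap)
        accX[sl_y, sl_x] += sub.X * wgt
        accY[sl_y, sl_x] += sub.Y * wgt
        weight[sl_y, sl_x] += wgt
    nz = weight > 0
    accX[nz] /= weight[nz]
    accY[nz] /= weight[nz]
    return DisplacementField(X=accX, Y=accY)


def micro_register(
    micro_images: list[ProcessedImage],
    fields: list[DisplacementField],
    ordering,
    method="tvl1",
    tile: int = 512,
    direct_to_reference: bool = False,
    mask: np.ndarray | None = None,
) -> list[DisplacementField]:
    """Second non-rigid pass on higher-resolution crops.

    ``micro_images`` are rigid-warped crops at micro resolution (same
    bbox as the first pass, larger grid); ``fields`` the accumulated
    first-pass fields.  Each image is warped with its upsampled field,
    the residual field against its inner neighbor (or directly against
    the reference when ``direct_to_reference``) is estimated per tile,
    and added to the accumulated field.  Returns updated fields at micro
    resolution.
    """
    n = len(micro_images)
    order = ordering.order or list(range(n))
    ref_pos = ordering.reference_index if ordering.reference_index >= 0 else n // 2
    ref = order[ref_pos]
    shape = micro_images[0].pixels.shape
    scale = micro_images[0].scale
    up = [f.resized(shape) for f in fields]
    for f in up:
        f.scale = scale
    warped = [warp_with_field(im.pixels, f)
              for im, f in zip(micro_images, up)]
    out: list[DisplacementField] = list(up)

    def refine(pos, fixed_idx):
        img = order[pos]
        residual = tiled_displacement(warped[img], warped[fixed_idx],
                                      method=method, tile=tile, mask=mask)
        out[img] = DisplacementField(X=up[img].X + residual.X,
                                     Y=up[img].Y + residual.Y,
                                     bbox=up[img].bbox, scale=scale)
        warped[img] = warp_with_field(micro_images[img].pixels, out[img])

    if direct_to_reference:
        for pos in range(n):
            if order[pos] != ref:
                refine(pos, ref)
    else:
        for pos in range(ref_pos - 1, -1, -1):
            refine(pos, order[pos + 1])
        for pos in range(ref_pos + 1, n):
            refine(pos, order[pos - 1])
    return out
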