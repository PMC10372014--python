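"""Serial rigid (similarity) registration toward the reference.

Each image is aligned *towards* the reference, not directly to it: the
image adjacent to the reference is aligned to the reference, the next one
to the already-registered version of its inner neighbor, and so on,
walking outward.  Transform matrices therefore compose along the ordered
series and all live in the common registered frame (the reference image's
registration-scale coordinate system; the reference's own matrix is
exactly the identity).

Matrices are 3x3 homogeneous similarity transforms mapping source (x, y)
at registration scale into registered-frame coordinates; image resampling
uses the inverse (backward mapping).  Pairwise transforms are estimated
from matched feature coordinates by least squares (Umeyama's method, as
implemented in scikit-image).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import SimilarityTransform, warp

from .features import MatchSet, get_pair
from .ordering import SeriesOrdering

__all__ = [
    "RigidTransform",
    "RigidResult",
    "neighbor_filter",
    "estimate_similarity",
    "serial_rigid_register",
    "warp_rigid",
    "mi_refine",
]

MIN_SHARED = 4


class EstimationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Homogeneous similarity transform source -> registered frame."""

    matrix: np.ndarray
    scale_at_fit: float = 1.0
    residual_rms: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")

    @classmethod
    def identity(cls, scale: float = 1.0) -> "RigidTransform":
        return cls(matrix=np.eye(3), scale_at_fit=scale)

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0],
                                           self.matrix[0, 0])))

    @property
    def scale_factor(self) -> float:
        return float(np.hypot(self.matrix[0, 0], self.matrix[1, 0]))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        h = np.column_stack([xy, np.ones(len(xy))])
        out = h @ self.matrix.T
        return out[:, :2]

    def inverse(self) -> "RigidTransform":
        return RigidTransform(matrix=np.linalg.inv(self.matrix),
                              scale_at_fit=self.scale_at_fit)


@dataclass
class RigidResult:
    """Per-image transforms plus the shared canvas geometry.

    ``canvas_offset`` is the registered-frame coordinate of canvas pixel
    (0, 0); subtracting it maps registered-frame points onto the canvas.
    """

    transforms: list[RigidTransform]
    canvas_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(2))
    canvas_shape: tuple[int, int] = (0, 0)  # (width, height)


def neighbor_filter(ms_inner: MatchSet, ms_outer: MatchSet) -> MatchSet:
    """Keep matches of image i shared with both of its series neighbors.

    ``ms_inner`` holds the matches between image i and its inner neighbor
    (the one closer to the reference, which i will be aligned to);
    ``ms_outer`` the matches between i and its outer neighbor.  A match of
    ``ms_inner`` survives when the keypoint of i behind it also takes part
    in a surviving match of ``ms_outer``.  If fewer than 4 survive, the
    unfiltered set is returned with a warning.
    """
    if ms_inner.i != ms_outer.i:
        raise ValueError("both match sets must be anchored on the same image")
    shared = np.isin(ms_inner.idx_i, ms_outer.idx_i)
    if shared.sum() < MIN_SHARED:
        warnings.warn(
            f"image {ms_inner.i}: only {int(shared.sum())} features shared "
            "with both neighbors; falling back to pairwise matches")
        return ms_inner
    return ms_inner.take(shared)


def estimate_similarity(xy_src: np.ndarray, xy_dst: np.ndarray,
                        scale: float = 1.0) -> RigidTransform:
    """Least-squares similarity transform minimizing sum ||M p_src - p_dst||^2."""
    xy_src = np.asarray(xy_src, dtype=float)
    xy_dst = np.asarray(xy_dst, dtype=float)
    if len(xy_src) < 2 or len(xy_src) != len(xy_dst):
        raise EstimationError("need at least 2 point pairs")
    model = SimilarityTransform.from_estimate(xy_src, xy_dst)
    if not model or not np.all(np.isfinite(model.params)):
        raise EstimationError("degenerate point configuration")
    resid = np.linalg.norm(model(xy_src) - xy_dst, axis=1)
    return RigidTransform(matrix=model.params, scale_at_fit=scale,
                          residual_rms=float(np.sqrt((resid**2).mean())))


def serial_rigid_register(
    matches: dict[tuple[int, int], MatchSet],
    ordering: SeriesOrdering,
    image_shapes: list[tuple[int, int]] | None = None,
    use_neighbor_filter: bool = True,
) -> RigidResult:
    """Estimate all rigid transforms by walking outward from the reference.

    ``matches`` are post-Tukey all-pairs matches keyed by (i, j), i < j;
    ``image_shapes`` (per image, (height, width)) are used to compute the
    common canvas.  Returns transforms indexed by series position (the
    original image indices, not the inferred order).
    """
    order = ordering.order or list(range(ordering.n))
    n = len(order)
    ref_pos = ordering.reference_index if ordering.reference_index >= 0 else n // 2
    transforms: list[RigidTransform | None] = [None] * n
    transforms[order[ref_pos]] = RigidTransform.identity()

    def pairwise(pos: int, inner_pos: int, outer_pos: int | None) -> RigidTransform:
        img, inner = order[pos], order[inner_pos]
        ms = get_pair(matches, img, inner)
        if use_neighbor_filter and outer_pos is not None:
            ms_outer = get_pair(matches, img, order[outer_pos])
            if not ms.is_empty and not ms_outer.is_empty:
                ms = neighbor_filter(ms, ms_outer)
        if len(ms) < 2:
            raise EstimationError(
                f"images {img} and {inner}: not enough matches to align")
        return estimate_similarity(ms.xy_i, ms.xy_j)

    # walk left of the reference, then right
    for pos in range(ref_pos - 1, -1, -1):
        outer = pos - 1 if pos - 1 >= 0 else None
        pw = pairwise(pos, pos + 1, outer)
        inner_m = transforms[order[pos + 1]].matrix
        transforms[order[pos]] = RigidTransform(
            matrix=inner_m @ pw.matrix, residual_rms=pw.residual_rms)
    for pos in range(ref_pos + 1, n):
        outer = pos + 1 if pos + 1 < n else None
        pw = pairwise(pos, pos - 1, outer)
        inner_m = transforms[order[pos - 1]].matrix
        transforms[order[pos]] = RigidTransform(
            matrix=inner_m @ pw.matrix, residual_rms=pw.residual_rms)

    result = RigidResult(transforms=transforms)  # type: ignore[arg-type]
    if image_shapes is not None:
        corners_all = []
        for t, (h, w) in zip(transforms, image_shapes):
            corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]],
                               dtype=float)
            corners_all.append(t.apply(corners))
        pts = np.vstack(corners_all)
        lo = np.floor(pts.min(axis=0))
        hi = np.ceil(pts.max(axis=0))
        result.canvas_offset = lo
        result.canvas_shape = (int(hi[0] - lo[0]) + 1, int(hi[1] - lo[1]) + 1)
    return result


def warp_rigid(image: np.ndarray, transform: RigidTransform,
               canvas_offset: np.ndarray = np.zeros(2),
               canvas_shape: tuple[int, int] | None = None,
               order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` into the registered canvas (backward mapping)."""
    # canvas pixel -> registered frame (add offset) -> source (inverse of M)
    offset = SimilarityTransform(translation=np.asarray(canvas_offset,
                                                        dtype=float))
    inv_map = SimilarityTransform(
        matrix=np.linalg.inv(transform.matrix) @ offset.params)
    out_shape = None
    if canvas_shape is not None:
        out_shape = (canvas_shape[1], canvas_shape[0])
    return warp(np.asarray(image, dtype=float), inv_map, order=order,
                cval=cval, output_shape=out_shape, preserve_range=True)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / max(hist.sum(), 1)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def mi_refine(
    img: np.ndarray,
    img_ref: np.ndarray,
    transform: RigidTransform,
    matches_xy: tuple[np.ndarray, np.ndarray] | None = None,
    feature_weight: float = 0.1,
    canvas_offset: np.ndarray = np.zeros(2),
) -> RigidTransform:
    """Optionally refine a rigid transform by mutual information.

    Gradient-free local search over (angle, tx, ty, log-scale) around the
    current transform, maximizing the mutual information between the
    warped image and the reference minus ``feature_weight`` times the mean
    matched-feature distance.  The refined transform is returned only if
    the objective improved; otherwise the input is returned unchanged.
    """
    from scipy.optimize import minimize

    h, w = img_ref.shape[:2]
    base = transform.matrix

    def build(p):
        da, dx, dy, dls = p
        c, s = np.cos(np.radians(da)), np.sin(np.radians(da))
        k = np.exp(dls)
        delta = np.array([[k * c, -k * s, dx], [k * s, k * c, dy], [0, 0, 1]])
        return delta @ base

    def objective(p):
        m = build(p)
        t = RigidTransform(matrix=m)
        warped = warp_rigid(img, t, canvas_offset=canvas_offset,
                            canvas_shape=(w, h))
        mi = _mutual_information(warped, img_ref)
        pen = 0.0
        if matches_xy is not None:
            src, dst = matches_xy
            pen = float(np.linalg.norm(t.apply(src) - dst, axis=1).mean())
        return -(mi - feature_weight * pen)

    f0 = objective(np.zeros(4))
    try:
        res = minimize(objective, np.zeros(4), method="Powell",
                       options={"maxiter": 60, "xtol": 1e-3, "ftol": 1e-5})
    except Exception as exc:  # pragma: no cover - optimizer failure path
        warnings.warn(f"MI refinement failed ({exc}); keeping input transform")
        return transform
    if res.fun < f0 - 1e-12:
        return RigidTransform(matrix=build(res.x),
                              scale_at_fit=transform.scale_at_fit)
    return transform
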