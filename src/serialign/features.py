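"""Keypoint detection, matching, and match filtering.

Matches between image pairs are the currency of the whole rigid stage:
they drive the similarity ordering, the serial rigid alignment, and the
final error estimate.  Three successive filters remove bad matches:

1. RANSAC with a similarity (rotation + scale + translation) model;
2. a Tukey outer-fence filter on the distances between matched features
   after warping with a preliminary similarity fit (fences at
   Q1 - 3*IQR and Q3 + 3*IQR, quartiles by linear interpolation);
3. neighbor filtering (in :mod:`serialign.rigid`): only features shared
   with both adjacent images in the ordered series survive.

Detectors are pluggable: anything callable as ``(image, mask) ->
(keypoints_xy, descriptors)``.  The default is SIFT; ORB is available as
a faster binary-descriptor alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

__all__ = [
    "MatchSet",
    "FeatureSet",
    "sift_detector",
    "orb_detector",
    "detect_and_describe",
    "match_pair",
    "tukey_filter",
    "match_all_pairs",
    "get_pair",
]

RANSAC_THRESHOLD_PX = 7.0
RANSAC_MAX_TRIALS = 2000
RANSAC_MIN_SAMPLES = 3
TUKEY_K = 3.0
MIN_MATCHES = 4


class RegistrationError(RuntimeError):
    pass


@dataclass
class FeatureSet:
    """Keypoints (x, y at registration scale) and row-aligned descriptors."""

    keypoints: np.ndarray
    descriptors: np.ndarray

    def __len__(self):
        return len(self.keypoints)


@dataclass
class MatchSet:
    """Filtered matched keypoints between images ``i`` and ``j``.

    ``idx_i``/``idx_j`` are indices into each image's detected keypoint
    array, preserving keypoint identity for neighbor filtering.  Counts
    record the surviving matches after each filter stage and are
    monotonically non-increasing.
    """

    i: int
    j: int
    xy_i: np.ndarray
    xy_j: np.ndarray
    idx_i: np.ndarray
    idx_j: np.ndarray
    n_raw: int = 0
    n_after_ransac: int = 0
    n_after_tukey: int = 0
    descriptor_distances: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a match set joins two distinct images")
        if len(self.xy_i) != len(self.xy_j):
            raise ValueError("paired coordinate arrays must be equally long")

    def __len__(self):
        return len(self.xy_i)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def swapped(self) -> "MatchSet":
        """Same matches viewed from the other image."""
        return MatchSet(
            i=self.j, j=self.i, xy_i=self.xy_j, xy_j=self.xy_i,
            idx_i=self.idx_j, idx_j=self.idx_i, n_raw=self.n_raw,
            n_after_ransac=self.n_after_ransac,
            n_after_tukey=self.n_after_tukey,
            descriptor_distances=self.descriptor_distances,
        )

    def take(self, keep: np.ndarray) -> "MatchSet":
        return MatchSet(
            i=self.i, j=self.j, xy_i=self.xy_i[keep], xy_j=self.xy_j[keep],
            idx_i=self.idx_i[keep], idx_j=self.idx_j[keep], n_raw=self.n_raw,
            n_after_ransac=self.n_after_ransac,
            n_after_tukey=self.n_after_tukey,
            descriptor_distances=(
                self.descriptor_distances[keep]
                if len(self.descriptor_distances) == len(self.xy_i)
                else self.descriptor_distances
            ),
        )


def _empty_matchset(i: int, j: int, n_raw: int = 0) -> MatchSet:
    z = np.empty((0, 2))
    zi = np.empty(0, dtype=int)
    return MatchSet(i=i, j=j, xy_i=z, xy_j=z.copy(), idx_i=zi, idx_j=zi.copy(),
                    n_raw=n_raw)


def sift_detector(image: np.ndarray, mask: np.ndarray | None = None):
    """SIFT keypoints + descriptors, restricted to ``mask`` when given."""
    det = SIFT(upsampling=1, c_dog=0.004)
    det.detect_and_extract(np.ascontiguousarray(image, dtype=float))
    kp_rc = det.keypoints
    desc = det.descriptors
    xy = kp_rc[:, ::-1].astype(float)
    if mask is not None and len(xy):
        inside = mask[kp_rc[:, 0], kp_rc[:, 1]].astype(bool)
        xy, desc = xy[inside], desc[inside]
    return xy, desc


def orb_detector(image: np.ndarray, mask: np.ndarray | None = None,
                 n_keypoints: int = 2000):
    det = ORB(n_keypoints=n_keypoints)
    det.detect_and_extract(np.ascontiguousarray(image, dtype=float))
    kp_rc = det.keypoints
    desc = det.descriptors
    xy = kp_rc[:, ::-1].astype(float)
    if mask is not None and len(xy):
        rc = np.clip(np.rint(kp_rc).astype(int), 0,
                     np.array(mask.shape) - 1)
        inside = mask[rc[:, 0], rc[:, 1]].astype(bool)
        xy, desc = xy[inside], desc[inside]
    return xy, desc


DETECTORS = {"sift": sift_detector, "orb": orb_detector}


def detect_and_describe(image: np.ndarray, mask: np.ndarray | None = None,
                        detector="sift", name: str = "?") -> FeatureSet:
    """Detect keypoints inside the tissue mask and describe them.

    Raises :class:`RegistrationError` when fewer than 4 usable keypoints
    are found (the image cannot participate in registration).
    """
    fn = DETECTORS[detector] if isinstance(detector, str) else detector
    try:
        xy, desc = fn(image, mask)
    except RuntimeError:  # detectors raise when nothing at all is found
        xy, desc = np.empty((0, 2)), np.empty((0, 1))
    if len(xy) < MIN_MATCHES:
        raise RegistrationError(
            f"image {name}: only {len(xy)} keypoints detected (need >= 4)")
    return FeatureSet(keypoints=xy, descriptors=desc)


def match_pair(feat_i: FeatureSet, feat_j: FeatureSet, i: int = 0, j: int = 1,
               ransac_threshold: float = RANSAC_THRESHOLD_PX,
               seed: int = 0) -> MatchSet:
    """Brute-force descriptor matching with cross-check, then RANSAC.

    RANSAC fits a similarity model; an unusable pair (fewer than 4 raw
    matches or inliers) yields an empty :class:`MatchSet` rather than an
    exception.
    """
    if len(feat_i) == 0 or len(feat_j) == 0:
        return _empty_matchset(i, j)
    pairs = match_descriptors(feat_i.descriptors, feat_j.descriptors,
                              cross_check=True)
    n_raw = len(pairs)
    if n_raw < MIN_MATCHES:
        return _empty_matchset(i, j, n_raw=n_raw)
    xy_i = feat_i.keypoints[pairs[:, 0]]
    xy_j = feat_j.keypoints[pairs[:, 1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, inliers = ransac(
            (xy_i, xy_j), SimilarityTransform,
            min_samples=RANSAC_MIN_SAMPLES,
            residual_threshold=ransac_threshold,
            max_trials=RANSAC_MAX_TRIALS, stop_probability=0.999,
            rng=seed,
        )
    if model is None or inliers is None or inliers.sum() < MIN_MATCHES:
        return _empty_matchset(i, j, n_raw=n_raw)
    inliers = inliers.astype(bool)
    di = feat_i.descriptors[pairs[inliers, 0]].astype(float)
    dj = feat_j.descriptors[pairs[inliers, 1]].astype(float)
    return MatchSet(
        i=i, j=j, xy_i=xy_i[inliers], xy_j=xy_j[inliers],
        idx_i=pairs[inliers, 0], idx_j=pairs[inliers, 1],
        n_raw=n_raw, n_after_ransac=int(inliers.sum()),
        descriptor_distances=np.linalg.norm(di - dj, axis=1),
    )


def tukey_filter(ms: MatchSet, k: float = TUKEY_K) -> MatchSet:
    """Drop matches outside Tukey's outer fences of warped-feature distance.

    A preliminary similarity transform is fitted on the current matches;
    source coordinates are warped and the Euclidean distances to the
    target coordinates are gathered.  Matches with distances outside
    [Q1 - k*IQR, Q3 + k*IQR] (quartiles by linear interpolation) are
    removed.  Degenerate fits return the input unchanged with a warning.
    """
    if len(ms) < MIN_MATCHES:
        out = ms.take(np.arange(len(ms)))
        out.n_after_tukey = len(ms)
        return out
    model = SimilarityTransform.from_estimate(ms.xy_i, ms.xy_j)
    if not model:
        warnings.warn(f"pair ({ms.i},{ms.j}): degenerate preliminary "
                      "transform; Tukey filter skipped")
        out = ms.take(np.arange(len(ms)))
        out.n_after_tukey = len(ms)
        return out
    d = np.linalg.norm(model(ms.xy_i) - ms.xy_j, axis=1)
    q1, q3 = np.percentile(d, [25, 75], method="linear")
    iqr = q3 - q1
    keep = (d >= q1 - k * iqr) & (d <= q3 + k * iqr)
    out = ms.take(keep)
    out.n_after_tukey = int(keep.sum())
    return out


def match_all_pairs(features: list[FeatureSet],
                    ransac_threshold: float = RANSAC_THRESHOLD_PX,
                    seed: int = 0,
                    apply_tukey: bool = True) -> dict[tuple[int, int], MatchSet]:
    """Match every unordered pair of images; keys are (i, j) with i < j.

    Use :func:`get_pair` for symmetric access with swapped coordinates.
    """
    out: dict[tuple[int, int], MatchSet] = {}
    n = len(features)
    for i in range(n):
        for j in range(i + 1, n):
            ms = match_pair(features[i], features[j], i=i, j=j,
                            ransac_threshold=ransac_threshold, seed=seed)
            if apply_tukey:
                ms = tukey_filter(ms)
            out[(i, j)] = ms
    return out


def get_pair(matches: dict[tuple[int, int], MatchSet], i: int,
             j: int) -> MatchSet:
    """Symmetric lookup: ``get_pair(m, j, i)`` swaps the coordinate arrays."""
    if (i, j) in matches:
        return matches[(i, j)]
    return matches[(j, i)].swapped()
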