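"""Registration error estimates.

Two complementary views of accuracy:

* feature error — no ground truth needed: the surviving matched features
  of each adjacent pair are scaled to level 0, pushed through both
  images' transform chains, and the median distance between them (in um
  when the pixel size is known) summarizes the pair.  The sample error is
  the mean of pair medians weighted by each pair's match count.  This
  estimate tends to sit above the true landmark error, making it a
  conservative indicator of registration quality.
* landmark error — when corresponding landmarks exist: TRE is the
  Euclidean distance between registered landmark pairs (physical units),
  and rTRE divides by the diagonal of the target image, normalizing to
  [0, 1].

Percentiles use linear interpolation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MatchSet, get_pair
from .warping import TransformChain, warp_points

__all__ = ["ErrorReport", "PairError", "feature_error", "rtre", "tre_um",
           "summarize_rtre"]


@dataclass
class PairError:
    i: int
    j: int
    median_distance: float
    n_matches: int
    stage: str = "nonrigid"


@dataclass
class ErrorReport:
    per_pair: list[PairError] = field(default_factory=list)
    units: str = "px"

    @property
    def sample_error(self) -> float:
        """Match-count-weighted mean of the pair medians.

        Pairs without matches carry zero weight and are excluded.
        """
        usable = [p for p in self.per_pair
                  if p.n_matches > 0 and np.isfinite(p.median_distance)]
        n = sum(p.n_matches for p in usable)
        if n == 0:
            return float("nan")
        return sum(p.median_distance * p.n_matches for p in usable) / n


def feature_error(
    matches: dict[tuple[int, int], MatchSet],
    chains: list[TransformChain],
    pairs: list[tuple[int, int]] | None = None,
    pixel_size_um: float | None = None,
    stage: str = "nonrigid",
) -> ErrorReport:
    """Estimate registration error from registered matched features.

    Match coordinates (registration scale) are scaled to level 0, warped
    by each image's chain into the registered canvas, and the per-pair
    median Euclidean distance is taken — in um when ``pixel_size_um`` is
    given, else in full-resolution pixels.  ``pairs`` defaults to all
    pairs present in ``matches``.
    """
    if pairs is None:
        pairs = sorted(matches.keys())
    unit_factor = pixel_size_um if pixel_size_um is not None else 1.0
    report = ErrorReport(units="um" if pixel_size_um is not None else "px")
    for i, j in pairs:
        ms = get_pair(matches, i, j)
        if ms.is_empty:
            report.per_pair.append(PairError(i, j, float("nan"), 0, stage))
            continue
        ri = chains[i].registration_scale
        rj = chains[j].registration_scale
        pi = warp_points(ms.xy_i / ri, chains[i])
        pj = warp_points(ms.xy_j / rj, chains[j])
        d = np.linalg.norm(pi - pj, axis=1) * unit_factor
        report.per_pair.append(
            PairError(i, j, float(np.median(d)), len(ms), stage))
    return report


def rtre(warped_landmarks: np.ndarray, target_landmarks: np.ndarray,
         target_shape: tuple[int, int]) -> np.ndarray:
    """Relative target registration error.

    Per-landmark Euclidean distance divided by the diagonal of the
    target image (``target_shape`` = (width, height)), normalizing error
    into [0, 1] for in-image landmarks.
    """
    w, h = target_shape
    diag = float(np.hypot(w, h))
    d = np.linalg.norm(np.asarray(warped_landmarks, dtype=float)
                       - np.asarray(target_landmarks, dtype=float), axis=1)
    return d / diag


def summarize_rtre(values: list[np.ndarray]) -> dict:
    """Median per pair and the median of pair medians (MMrTRE)."""
    medians = [float(np.median(v)) for v in values if len(v)]
    return {
        "median_per_pair": medians,
        "median_of_medians": float(np.median(medians)) if medians else float("nan"),
    }


def tre_um(warped_landmarks: np.ndarray, target_landmarks: np.ndarray,
           pixel_size_um: float = 1.0) -> np.ndarray:
    """Target registration error in physical units (um)."""
    d = np.linalg.norm(np.asarray(warped_landmarks, dtype=float)
                       - np.asarray(target_landmarks, dtype=float), axis=1)
    return d * pixel_size_um


def tre_summary(tre: np.ndarray) -> dict:
    """Mean / median / 90th percentile (linear interpolation)."""
    tre = np.asarray(tre, dtype=float)
    return {
        "mean": float(tre.mean()),
        "median": float(np.median(tre)),
        "p90": float(np.percentile(tre, 90, method="linear")),
    }
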