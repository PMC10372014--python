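"""Inferring the serial order of an image series.

When the physical order of sections is unknown, images are sequenced so
that each one neighbors its most similar images: the number of good
(post-Tukey) feature matches between each pair forms a similarity matrix
S, standardized so its maximum is 1; the distance matrix D = 1 - S' is
clustered hierarchically (average linkage) and the dendrogram leaves are
arranged by optimal leaf ordering, minimizing the sum of adjacent
distances.  An ordering and its reverse are equivalent; the canonical
form puts the smaller image index first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import squareform

from .features import MatchSet

__all__ = ["SeriesOrdering", "build_similarity", "order_by_similarity",
           "choose_reference"]


@dataclass
class SeriesOrdering:
    """Similarity/distance matrices, inferred order, and reference position."""

    S: np.ndarray
    S_std: np.ndarray | None = None
    Dm: np.ndarray | None = None
    order: list[int] = field(default_factory=list)
    reference_index: int = -1

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def reference_image(self) -> int:
        """Series index of the reference image."""
        return self.order[self.reference_index]

    def position_of(self, image: int) -> int:
        return self.order.index(image)


def build_similarity(matches: dict[tuple[int, int], MatchSet],
                     n: int | None = None) -> SeriesOrdering:
    """S[i, j] = number of post-Tukey matches between images i and j.

    The diagonal is set to the maximum off-diagonal value (an image is at
    least as similar to itself as to any other image).
    """
    if n is None:
        n = max(max(i, j) for i, j in matches) + 1 if matches else 1
    S = np.zeros((n, n))
    for (i, j), ms in matches.items():
        S[i, j] = S[j, i] = ms.n_after_tukey
    off_max = S.max() if n > 1 else 1.0
    np.fill_diagonal(S, off_max)
    return SeriesOrdering(S=S)


def order_by_similarity(so: SeriesOrdering) -> SeriesOrdering:
    """Fill ``S_std``, ``Dm`` and ``order`` by clustering + leaf ordering.

    With all-zero similarities the input order is kept (with a warning);
    N < 3 trivially keeps the identity order.
    """
    n = so.n
    S = so.S.copy()
    off = S[~np.eye(n, dtype=bool)]
    if n < 2 or off.max() <= 0:
        if n >= 2:
            warnings.warn("no matches between any pair; keeping input order")
        so.S_std = np.zeros_like(S)
        so.Dm = 1.0 - so.S_std
        np.fill_diagonal(so.Dm, 0.0)
        so.order = list(range(n))
        return so
    S_std = S / off.max()
    Dm = 1.0 - S_std
    np.fill_diagonal(Dm, 0.0)
    Dm = np.maximum(Dm, 0.0)
    so.S_std, so.Dm = S_std, Dm
    if n < 3:
        so.order = list(range(n))
        return so
    # average-linkage clustering + optimal leaf ordering: the tree
    # constraint regularizes the sequence, which keeps one poorly
    # matching image (noisy similarity row) from derailing the order the
    # way an unconstrained minimum-cost path can
    condensed = squareform(Dm, checks=False)
    Z = optimal_leaf_ordering(linkage(condensed, method="average"),
                              condensed)
    order = list(int(k) for k in leaves_list(Z))
    if order[0] > order[-1]:  # canonical direction
        order = order[::-1]
    so.order = order
    return so


def choose_reference(so: SeriesOrdering,
                     user_ref: int | None = None) -> SeriesOrdering:
    """Reference = user-specified image, else the center of the z-stack.

    ``user_ref`` is a series index (position in the input list); the
    stored ``reference_index`` is its position in the inferred order.
    """
    if not so.order:
        so.order = list(range(so.n))
    if user_ref is not None:
        so.reference_index = so.position_of(int(user_ref))
    else:
        so.reference_index = len(so.order) // 2
    return so
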