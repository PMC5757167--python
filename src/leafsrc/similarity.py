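"""Gaussian-kernel similarity between contour rasters.

Two rasters x, y are compared through s(x, y) = exp(-||x - y||^2 / (2 b^2)),
where ||.|| is the Euclidean (Frobenius) distance between the pixel arrays
and b is the kernel width.  The width is not hand-tuned: the midrange
heuristic b = (d_max + d_min) / 2 over a set of cross-pair distances adapts
it to the scale of the data at hand.  Two widths appear in the classifier:
`beta` for partitioning the training set against the representative shapes,
and `beta1`, recomputed per test sample, for weighting atoms of the routed
subdictionary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KernelConfig",
    "euclidean_distance",
    "gaussian_similarity",
    "auto_width",
    "cross_distances",
]


@dataclass
class KernelConfig:
    """Kernel widths for partitioning (beta) and atom weighting (beta1).

    When `auto` is set, each width is derived from the data by the midrange
    rule instead of the stored values."""

    beta: float = 1.0
    beta1: float = 1.0
    auto: bool = True

    def __post_init__(self):
        if self.beta <= 0 or self.beta1 <= 0:
            raise ValueError("kernel widths must be positive")


def _pixels(x) -> np.ndarray:
    return np.asarray(getattr(x, "pixels", x), dtype=float)


def euclidean_distance(x, y) -> float:
    """Frobenius distance between two rasters (or arrays) of equal shape."""
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    return float(np.linalg.norm(xa - ya))


def gaussian_similarity(x, y, beta: float) -> float:
    """s(x, y) = exp(-||x - y||^2 / (2 beta^2)), in (0, 1]."""
    if beta <= 0:
        raise ValueError(f"kernel width must be positive, got {beta}")
    d = euclidean_distance(x, y)
    return float(np.exp(-(d * d) / (2.0 * beta * beta)))


def cross_distances(refs: Sequence, others: Sequence) -> np.ndarray:
    """All pairwise Euclidean distances d(refs[i], others[j]) as an
    (len(refs), len(others)) array."""
    if len(refs) == 0 or len(others) == 0:
        raise ValueError("both raster lists must be nonempty")
    ra = np.stack([_pixels(x).ravel() for x in refs])
    oa = np.stack([_pixels(x).ravel() for x in others])
    sq = (
        np.sum(ra * ra, axis=1)[:, None]
        + np.sum(oa * oa, axis=1)[None, :]
        - 2.0 * ra @ oa.T
    )
    return np.sqrt(np.maximum(sq, 0.0))


def auto_width(refs: Sequence, others: Sequence) -> float:
    """Midrange kernel width (d_max + d_min) / 2 over all cross pairs.

    Raises on a degenerate dataset where every cross distance is zero."""
    d = cross_distances(refs, others)
    width = 0.5 * (float(d.max()) + float(d.min()))
    if width <= 0:
        raise ValueError("degenerate data: all cross-pair distances are zero")
    return width
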