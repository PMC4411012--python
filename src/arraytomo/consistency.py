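"""Between-round stain-consistency metrics with a 180°-rotation null.

After an antibody is eluted and the same section re-stained in a later
round, a reliable stain reproduces its pixel pattern. Consistency is
quantified two ways: the Pearson correlation of pixel intensities
between rounds, and the "percent consistent" — of the pixels above a
foreground threshold (1 000 a.u. on the 16-bit scale) in *either* round,
the percentage above threshold in *both* (a Jaccard index × 100).
Rotating one round's image 180° destroys the spatial correspondence
while preserving all single-image statistics, so the rotated metrics
estimate the chance level of each score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoSignalError, ShapeMismatchError

__all__ = [
    "ConsistencyReport",
    "rotate180",
    "percent_consistent",
    "background_percent_consistent",
    "consistency_report",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 1000.0


@dataclass
class ConsistencyReport:
    """All six between-round metrics for one antibody."""

    r: float
    r_rotated: float
    pct_consistent: float
    pct_consistent_rotated: float
    bg_pct_consistent: float
    bg_pct_consistent_rotated: float
    threshold: float


def rotate180(image: np.ndarray) -> np.ndarray:
    """Reverse both in-plane axes of a 2D image (or of every section of a
    3D stack). Exact involution: applying it twice returns the input
    bit-identically."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img[::-1, ::-1].copy()
    if img.ndim == 3:
        return img[::-1, ::-1, :].copy()
    raise ShapeMismatchError("rotate180 expects a 2D image or a 3D stack")


def _jaccard_pct(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        warnings.warn("empty union of masks; percent consistent defined as 0")
        return 0.0
    inter = np.logical_and(mask_a, mask_b).sum()
    return 100.0 * float(inter) / float(union)


def percent_consistent(
    image_a: np.ndarray, image_b: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """100 × |A∩B| / |A∪B| over the above-threshold pixel sets.

    A pixel is foreground when strictly above ``threshold``. Symmetric in
    its arguments; 100 iff the two foreground masks are equal and
    non-empty; 0 (with a warning) when both masks are empty.
    """
    a = np.asarray(image_a)
    b = np.asarray(image_b)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"image shapes differ: {a.shape} vs {b.shape}")
    return _jaccard_pct(a > threshold, b > threshold)


def background_percent_consistent(
    image_a: np.ndarray, image_b: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Same Jaccard metric on the subthreshold (background) pixel sets."""
    a = np.asarray(image_a)
    b = np.asarray(image_b)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"image shapes differ: {a.shape} vs {b.shape}")
    return _jaccard_pct(a <= threshold, b <= threshold)


def consistency_report(
    round1: np.ndarray, round3: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ConsistencyReport:
    """All consistency metrics for a pair of registered same-shape images
    from two staining rounds, plus their 180°-rotation null values."""
    a = np.asarray(round1, dtype=np.float64)
    b = np.asarray(round3, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"image shapes differ: {a.shape} vs {b.shape}")
    b_rot = rotate180(b)

    pct = percent_consistent(a, b, threshold)
    pct_rot = percent_consistent(a, b_rot, threshold)
    bg = background_percent_consistent(a, b, threshold)
    bg_rot = background_percent_consistent(a, b_rot, threshold)

    if a.std() == 0 or b.std() == 0:
        raise NoSignalError(
            "Pearson r undefined for a zero-variance image "
            f"(percent consistent: {pct:.2f}, background: {bg:.2f})"
        )
    r = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
    r_rot = float(np.corrcoef(a.ravel(), b_rot.ravel())[0, 1])
    return ConsistencyReport(r, r_rot, pct, pct_rot, bg, bg_rot, threshold)
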