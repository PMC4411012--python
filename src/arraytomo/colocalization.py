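"""Pairwise shift cross-correlation analysis of channel colocalization.

Two registered antibody channels are shifted against each other in x and
y; at each integer shift the Pearson correlation of the overlapping
region is computed per section and averaged over sections. Colocalized
antibody pairs (both staining the same synaptic compartment) produce
sharp central peaks; pairs marking apposed pre- and postsynaptic
compartments produce broader, more diffuse peaks because the two puncta
populations are displaced by the synaptic cleft geometry.

The peak is summarized by a half-max contour: the iso-line of the
correlation map at background + (peak − background)/2, traced with
marching squares so that its area (and the diameter of the equal-area
circle) resolve fractions of a shift cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage import measure

from .core import DataVolume
from .errors import FlatMapError, NoSignalError, ShapeMismatchError

__all__ = [
    "CrossCorrSummary",
    "crosscorr_map",
    "summarize_peak",
    "pairwise_matrix",
]

DEFAULT_MAX_SHIFT = 10
DEFAULT_N_SECTIONS = 10


@dataclass
class CrossCorrSummary:
    """Shift-indexed correlation map with peak and contour statistics.

    ``map`` is indexed ``[du + max_shift, dv + max_shift]`` for shifts
    ``|du|, |dv| <= max_shift``. ``contour_diameter`` is the diameter of
    the circle with the same area as the half-max contour:
    ``2·sqrt(area/π)``.
    """

    map: np.ndarray
    max_shift: int
    peak_r: float = np.nan
    peak_shift: tuple[int, int] = (0, 0)
    background_r: float = np.nan
    half_max: float = np.nan
    contour_area: float = np.nan
    contour_diameter: float = np.nan

    def r(self, du: int, dv: int) -> float:
        return float(self.map[du + self.max_shift, dv + self.max_shift])


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def crosscorr_map(
    sections_a,
    sections_b,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> np.ndarray:
    """Shift-indexed Pearson correlation map, averaged over sections.

    ``sections_a``/``sections_b`` are sequences of registered 2D images
    (or single 2D images). For each shift (du, dv) the Pearson r is
    computed over the overlap of each section pair and averaged across
    sections with equal weight; zero-variance sections are excluded with
    a warning.
    """
    if isinstance(sections_a, np.ndarray) and sections_a.ndim == 2:
        sections_a = [sections_a]
    if isinstance(sections_b, np.ndarray) and sections_b.ndim == 2:
        sections_b = [sections_b]
    sections_a = [np.asarray(s, dtype=np.float64) for s in sections_a]
    sections_b = [np.asarray(s, dtype=np.float64) for s in sections_b]
    if len(sections_a) != len(sections_b) or not sections_a:
        raise ShapeMismatchError("need equal, nonzero numbers of sections")
    for a, b in zip(sections_a, sections_b):
        if a.shape != b.shape:
            raise ShapeMismatchError(f"section shapes differ: {a.shape} vs {b.shape}")

    usable = []
    for idx, (a, b) in enumerate(zip(sections_a, sections_b)):
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"section {idx} has zero variance; excluded")
            continue
        usable.append((a, b))
    if not usable:
        raise NoSignalError("all sections have zero variance")

    size = 2 * max_shift + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    # r(du, dv) correlates A(x, y) against B(x + du, y + dv): content of B
    # displaced by +(du, dv) relative to A peaks at +(du, dv)
    for a, b in usable:
        for du in range(-max_shift, max_shift + 1):
            for dv in range(-max_shift, max_shift + 1):
                ax0, ax1 = max(0, -du), min(a.shape[0], a.shape[0] - du)
                ay0, ay1 = max(0, -dv), min(a.shape[1], a.shape[1] - dv)
                sub_a = a[ax0:ax1, ay0:ay1]
                sub_b = b[ax0 + du:ax1 + du, ay0 + dv:ay1 + dv]
                r = _pearson(sub_a, sub_b)
                if r is not None:
                    acc[du + max_shift, dv + max_shift] += r
                    cnt[du + max_shift, dv + max_shift] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return out


def summarize_peak(corr_map: np.ndarray, background_ring_width: int = 2) -> CrossCorrSummary:
    """Peak, background and half-max contour statistics of a shift map.

    The background is the mean correlation over the ring of shifts whose
    Chebyshev radius lies within ``background_ring_width`` of the window
    edge. The half-max threshold sits midway between peak and background;
    its contour is traced by marching squares (linear interpolation
    between shift cells) and only the closed contour containing the peak
    is measured: area by the shoelace formula, diameter as the equal-area
    circle's.
    """
    m = np.asarray(corr_map, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 2 != 1:
        raise ShapeMismatchError("correlation map must be a square odd-sized grid")
    max_shift = m.shape[0] // 2

    peak_idx = np.unravel_index(np.nanargmax(m), m.shape)
    peak_r = float(m[peak_idx])
    peak_shift = (int(peak_idx[0] - max_shift), int(peak_idx[1] - max_shift))

    gx, gy = np.mgrid[-max_shift:max_shift + 1, -max_shift:max_shift + 1]
    cheb = np.maximum(np.abs(gx), np.abs(gy))
    ring = cheb >= max_shift - background_ring_width
    background_r = float(np.nanmean(m[ring]))

    if not peak_r > background_r + 1e-9:
        raise FlatMapError(
            f"peak r {peak_r:.4f} does not exceed background {background_r:.4f}"
        )
    half_max = background_r + (peak_r - background_r) / 2.0

    contour_area = np.nan
    filled = np.where(np.isnan(m), background_r, m)
    for contour in measure.find_contours(filled, half_max):
        if not np.allclose(contour[0], contour[-1]):
            continue  # open contour hitting the window edge
        poly = Polygon(contour)
        if poly.is_valid and poly.contains(Point(peak_idx)):
            contour_area = float(poly.area)
            break
    if np.isnan(contour_area):
        # peak cell above half-max but no closed iso-line (single-cell
        # peak near the edge): fall back to the suprathreshold cell count
        # of the peak's connected region.
        lab = measure.label(filled >= half_max)
        contour_area = float((lab == lab[peak_idx]).sum())
    contour_diameter = 2.0 * np.sqrt(contour_area / np.pi)

    return CrossCorrSummary(
        map=m,
        max_shift=max_shift,
        peak_r=peak_r,
        peak_shift=peak_shift,
        background_r=background_r,
        half_max=half_max,
        contour_area=contour_area,
        contour_diameter=contour_diameter,
    )


def pairwise_matrix(
    volume: DataVolume,
    channels: list[str] | None = None,
    max_shift: int = DEFAULT_MAX_SHIFT,
    n_sections: int = DEFAULT_N_SECTIONS,
) -> pd.DataFrame:
    """Colocalization summary for every unordered channel pair.

    Correlations are averaged over the first ``n_sections`` sections
    (or all, if fewer). Returns a long-format table with columns
    channelA, channelB, peak_r, peak_du, peak_dv, background_r,
    contour_area_px2, contour_diameter_px.
    """
    names = channels if channels is not None else volume.channel_names
    if len(names) < 2:
        raise ShapeMismatchError("need at least 2 channels for a pairwise matrix")
    nz = min(n_sections, volume.shape[2])
    secs = {
        n: [volume.get_channel(n).section(z) for z in range(nz)] for n in names
    }
    rows = []
    for i, na in enumerate(names):
        for nb in names[i:]:
            cmap = crosscorr_map(secs[na], secs[nb], max_shift)
            try:
                s = summarize_peak(cmap)
                rows.append(
                    {
                        "channelA": na,
                        "channelB": nb,
                        "peak_r": s.peak_r,
                        "peak_du": s.peak_shift[0],
                        "peak_dv": s.peak_shift[1],
                        "background_r": s.background_r,
                        "contour_area_px2": s.contour_area,
                        "contour_diameter_px": s.contour_diameter,
                    }
                )
            except FlatMapError:
                peak_idx = np.unravel_index(np.nanargmax(cmap), cmap.shape)
                rows.append(
                    {
                        "channelA": na,
                        "channelB": nb,
                        "peak_r": float(cmap[peak_idx]),
                        "peak_du": int(peak_idx[0] - max_shift),
                        "peak_dv": int(peak_idx[1] - max_shift),
                        "background_r": np.nan,
                        "contour_area_px2": np.nan,
                        "contour_diameter_px": np.nan,
                    }
                )
    return pd.DataFrame(rows)
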