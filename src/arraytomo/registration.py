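"""Mosaic stitching, session registration and serial-section alignment.

Between imaging sessions the coverslip-mounted ribbon shifts slightly, so
images of one physical section taken in different sessions differ by a
small in-plane rigid transform. The DAPI nuclear counterstain, present in
every session, serves as the fiducial: nuclei are detected as
Laplacian-of-Gaussian blobs, matched across sessions, and the rigid model
is estimated with RANSAC followed by an orthogonal Procrustes refit on the
inliers. The same transform is then applied to every channel of the
moving session.

Stack alignment (registering consecutive physical sections to remove
per-section stage/placement jitter) uses the densest, most reliable
synaptic channel, typically Synapsin1, which stains synapses consistently
across neighbouring 70 nm sections. Alignment here is rigid per section;
nonlinear (elastic) section deformation is out of scope.

All 2D transforms use point coordinates ``(x, y)`` in pixels, rotate
about a caller-supplied center (by convention the image center), and
compose center-independently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.registration import phase_cross_correlation

from .core import ChannelVolume, VoxelSize
from .errors import (
    InsufficientPointsError,
    NoConsensusError,
    NoSignalError,
    StitchGraphError,
)

__all__ = [
    "RigidTransform2D",
    "StitchLayout",
    "estimate_pairwise_offset",
    "stitch_mosaic",
    "detect_blobs",
    "estimate_rigid_ransac",
    "register_session",
    "align_stack",
    "warp_volume",
]


def _rot(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotation ``theta`` (degrees, counter-
    clockwise about the chosen center) followed by translation
    ``(dx, dy)`` in pixels.

    With a shared center convention, composition and inversion are
    center-independent: ``compose`` and ``inverse`` act purely on
    ``(theta, dx, dy)``.
    """

    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy])

    def apply(self, points: np.ndarray, center=(0.0, 0.0)) -> np.ndarray:
        """Map (N, 2) points: p' = R(p - c) + c + t."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = np.asarray(center, dtype=np.float64)
        return (pts - c) @ _rot(self.theta).T + c + self.translation

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``self`` first, then ``other``."""
        t = _rot(other.theta) @ self.translation + other.translation
        return RigidTransform2D(self.theta + other.theta, t[0], t[1])

    def inverse(self) -> "RigidTransform2D":
        t = -(_rot(-self.theta) @ self.translation)
        return RigidTransform2D(-self.theta, t[0], t[1])

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.theta) < tol and abs(self.dx) < tol and abs(self.dy) < tol

    def warp(self, image: np.ndarray, center=None, order: int = 1) -> np.ndarray:
        """Resample a 2D image (indexed [x, y]) under this transform.

        ``out(p) = in(T⁻¹(p))`` with bilinear interpolation by default;
        ``center`` defaults to the image center.
        """
        img = np.asarray(image, dtype=np.float64)
        if center is None:
            center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
        c = np.asarray(center, dtype=np.float64)
        rinv = _rot(-self.theta)
        offset = -rinv @ (c + self.translation) + c
        return ndimage.affine_transform(img, rinv, offset=offset, order=order, mode="constant")

    def to_dict(self) -> dict:
        return {"theta": self.theta, "dx": self.dx, "dy": self.dy}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(float(d["theta"]), float(d["dx"]), float(d["dy"]))


def transforms_to_json(transforms, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(transforms, dict):
        payload = {str(k): t.to_dict() for k, t in transforms.items()}
    else:
        payload = [t.to_dict() for t in transforms]
    path.write_text(json.dumps(payload, indent=2))
    return path


# ---------------------------------------------------------------------------
# Mosaic stitching
# ---------------------------------------------------------------------------


def estimate_pairwise_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    expected_offset: tuple[float, float] = (0.0, 0.0),
    search_radius: int = 20,
) -> tuple[int, int, float]:
    """Estimate the translation of ``tile_b`` relative to ``tile_a``.

    ``expected_offset`` is the nominal origin difference (ox_b - ox_a,
    oy_b - oy_a) from the microscope stage; the true offset is searched
    within ``search_radius`` pixels of it by maximising the Pearson
    correlation of the overlapping region at each candidate integer
    shift. Returns ``(dx, dy, confidence)`` where confidence is the peak
    correlation in [-1, 1].
    """
    a = np.asarray(tile_a, dtype=np.float64)
    b = np.asarray(tile_b, dtype=np.float64)
    ex, ey = int(round(expected_offset[0])), int(round(expected_offset[1]))
    best = (ex, ey, -np.inf)
    for du in range(ex - search_radius, ex + search_radius + 1):
        for dv in range(ey - search_radius, ey + search_radius + 1):
            r = _shifted_pearson(a, b, du, dv)
            if r is not None and r > best[2]:
                best = (du, dv, r)
    if not np.isfinite(best[2]):
        raise NoSignalError("no overlapping window with signal in either tile")
    return best


def _shifted_pearson(a: np.ndarray, b: np.ndarray, du: int, dv: int) -> float | None:
    """Pearson r between a and b placed at offset (du, dv); None if the
    overlap is empty or zero-variance."""
    ax0, ax1 = max(0, du), min(a.shape[0], b.shape[0] + du)
    ay0, ay1 = max(0, dv), min(a.shape[1], b.shape[1] + dv)
    if ax1 - ax0 < 2 or ay1 - ay0 < 2:
        return None
    sub_a = a[ax0:ax1, ay0:ay1]
    sub_b = b[ax0 - du:ax1 - du, ay0 - dv:ay1 - dv]
    sa, sb = sub_a.std(), sub_b.std()
    if sa == 0 or sb == 0:
        return None
    return float(np.mean((sub_a - sub_a.mean()) * (sub_b - sub_b.mean())) / (sa * sb))


@dataclass
class StitchLayout:
    """Solved mosaic geometry: per-tile origins with tile 0 at (0, 0)."""

    origins: np.ndarray  # (n_tiles, 2) float
    residuals: np.ndarray  # per-constraint residuals, (n_edges, 2)

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.residuals.size else 0.0


def stitch_mosaic(
    tiles: list[np.ndarray],
    pairwise_offsets: list[tuple[int, int, tuple[float, float]]],
    fused_shape: tuple[int, int] | None = None,
) -> tuple[StitchLayout, np.ndarray]:
    """Globally place tiles from pairwise offsets and fuse them.

    ``pairwise_offsets`` holds ``(i, j, (dx, dy))`` constraints meaning
    origin_j - origin_i = (dx, dy). Global origins are the least-squares
    solution with tile 0 pinned at the origin (requires a connected
    constraint graph). Fusion blends overlaps with linear feathering
    (weights taper to zero at each tile border).
    """
    n = len(tiles)
    if n == 1:
        layout = StitchLayout(np.zeros((1, 2)), np.zeros((0, 2)))
        return layout, np.asarray(tiles[0], dtype=np.float64)

    # connectivity check
    adj = {i: set() for i in range(n)}
    for i, j, _ in pairwise_offsets:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for k in adj[stack.pop()]:
            if k not in seen:
                seen.add(k)
                stack.append(k)
    if len(seen) != n:
        raise StitchGraphError(f"offset graph disconnected: reached {len(seen)} of {n} tiles")

    # least squares per axis: rows (e_j - e_i) @ origins = d, plus origin_0 = 0
    m = len(pairwise_offsets)
    A = np.zeros((m + 1, n))
    bx = np.zeros(m + 1)
    by = np.zeros(m + 1)
    for row, (i, j, d) in enumerate(pairwise_offsets):
        A[row, i], A[row, j] = -1.0, 1.0
        bx[row], by[row] = d[0], d[1]
    A[m, 0] = 1.0  # pin reference tile
    ox = np.linalg.lstsq(A, bx, rcond=None)[0]
    oy = np.linalg.lstsq(A, by, rcond=None)[0]
    origins = np.column_stack([ox, oy])
    origins -= origins[0]

    res = np.array(
        [
            origins[j] - origins[i] - np.asarray(d, dtype=np.float64)
            for i, j, d in pairwise_offsets
        ]
    )
    layout = StitchLayout(origins, res)

    # fuse with linear feathering
    int_origins = np.rint(origins).astype(int)
    shift = int_origins.min(axis=0)
    int_origins = int_origins - shift
    if fused_shape is None:
        hx = max(o[0] + t.shape[0] for o, t in zip(int_origins, tiles))
        hy = max(o[1] + t.shape[1] for o, t in zip(int_origins, tiles))
        fused_shape = (hx, hy)
    acc = np.zeros(fused_shape)
    wacc = np.zeros(fused_shape)
    for (ox_, oy_), tile in zip(int_origins, tiles):
        t = np.asarray(tile, dtype=np.float64)
        wx = np.minimum(np.arange(t.shape[0]) + 1, t.shape[0] - np.arange(t.shape[0]))
        wy = np.minimum(np.arange(t.shape[1]) + 1, t.shape[1] - np.arange(t.shape[1]))
        w = np.outer(wx, wy).astype(np.float64)
        acc[ox_:ox_ + t.shape[0], oy_:oy_ + t.shape[1]] += t * w
        wacc[ox_:ox_ + t.shape[0], oy_:oy_ + t.shape[1]] += w
    fused = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
    return layout, fused


# ---------------------------------------------------------------------------
# Feature detection and rigid estimation
# ---------------------------------------------------------------------------


def detect_blobs(
    image: np.ndarray,
    scale_range_nm: tuple[float, float] = (1000.0, 4000.0),
    voxel: VoxelSize | None = None,
    threshold_rel: float = 0.1,
) -> np.ndarray:
    """Bright LoG blobs in a 2D image, subpixel-refined.

    ``scale_range_nm`` brackets the blob *radius*; it is converted to LoG
    sigmas with sigma = radius / sqrt(2). Returns an (N, 3) array of
    ``(x, y, strength)`` sorted by decreasing strength then position.
    Constant images yield an empty set.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0 or img.max() == img.min():
        return np.zeros((0, 3))
    vox = voxel if voxel is not None else VoxelSize()
    px = (vox.vx + vox.vy) / 2.0
    sig_lo = max(scale_range_nm[0] / px / np.sqrt(2), 0.8)
    sig_hi = max(scale_range_nm[1] / px / np.sqrt(2), sig_lo + 0.5)
    norm = (img - img.min()) / (img.max() - img.min())
    blobs = blob_log(
        norm, min_sigma=sig_lo, max_sigma=sig_hi, num_sigma=6, threshold=threshold_rel
    )
    if blobs.shape[0] == 0:
        return np.zeros((0, 3))

    out = []
    for bx, by, bs in blobs:
        # subpixel centroid refinement in a window of ~1 blob radius
        r = max(int(round(bs)), 1)
        x0, x1 = int(max(0, bx - r)), int(min(img.shape[0], bx + r + 1))
        y0, y1 = int(max(0, by - r)), int(min(img.shape[1], by + r + 1))
        win = norm[x0:x1, y0:y1]
        w = win - win.min()
        if w.sum() > 0:
            gx, gy = np.mgrid[x0:x1, y0:y1]
            cx, cy = float((gx * w).sum() / w.sum()), float((gy * w).sum() / w.sum())
        else:
            cx, cy = float(bx), float(by)
        strength = float(norm[int(round(bx)), int(round(by))])
        out.append((cx, cy, strength))
    arr = np.array(out)
    order = np.lexsort((arr[:, 1], arr[:, 0], -arr[:, 2]))
    return arr[order]


def _procrustes_rigid(src: np.ndarray, dst: np.ndarray, center) -> RigidTransform2D:
    """Least-squares rigid transform (no scaling) mapping src -> dst
    about ``center`` (orthogonal Procrustes via SVD)."""
    c = np.asarray(center, dtype=np.float64)
    a = src - src.mean(axis=0)
    b = dst - dst.mean(axis=0)
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    R = (u @ np.diag([1.0, d]) @ vt).T
    theta = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    t = dst.mean(axis=0) - (R @ (src.mean(axis=0) - c)) - c
    return RigidTransform2D(theta, float(t[0]), float(t[1]))


def estimate_rigid_ransac(
    points_a: np.ndarray,
    points_b: np.ndarray,
    inlier_tolerance_px: float = 2.0,
    iterations: int = 1000,
    seed: int = 0,
    center=(0.0, 0.0),
) -> tuple[RigidTransform2D, np.ndarray]:
    """RANSAC rigid fit from matched point pairs a[i] <-> b[i].

    Minimal samples of 2 points define a candidate rotation+translation;
    the candidate with the largest inlier set (residual <=
    ``inlier_tolerance_px``) is refit on its inliers by orthogonal
    Procrustes. Deterministic under a fixed seed. Raises
    :class:`NoConsensusError` when fewer than 3 inliers support the best
    model (2 matched pairs alone always fit exactly and carry no
    consensus evidence).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(points_b, dtype=np.float64))
    if a.shape[0] < 2 or b.shape[0] < 2 or a.shape != b.shape:
        raise InsufficientPointsError(
            f"need >= 2 matched points in each set, got {a.shape[0]} and {b.shape[0]}"
        )
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    best_inliers = np.zeros(n, dtype=bool)
    for _ in range(iterations):
        i, j = rng.choice(n, size=2, replace=False)
        va, vb = a[j] - a[i], b[j] - b[i]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na < 1e-9 or nb < 1e-9:
            continue
        theta = np.rad2deg(np.arctan2(vb[1], vb[0]) - np.arctan2(va[1], va[0]))
        R = _rot(theta)
        c = np.asarray(center, dtype=np.float64)
        t = b[i] - (R @ (a[i] - c)) - c
        cand = RigidTransform2D(float(theta), float(t[0]), float(t[1]))
        resid = np.linalg.norm(cand.apply(a, center) - b, axis=1)
        inliers = resid <= inlier_tolerance_px
        if inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers.sum() < 3:
        raise NoConsensusError(
            f"best consensus set has {int(best_inliers.sum())} inliers (< 3)"
        )
    fit = _procrustes_rigid(a[best_inliers], b[best_inliers], center)
    resid = np.linalg.norm(fit.apply(a, center) - b, axis=1)
    inliers = resid <= inlier_tolerance_px
    if inliers.sum() >= 3:
        fit = _procrustes_rigid(a[inliers], b[inliers], center)
    else:
        inliers = best_inliers
    return fit, inliers


def register_session(
    reference_section: np.ndarray,
    moving_section: np.ndarray,
    scale_range_nm: tuple[float, float] = (1000.0, 4000.0),
    voxel: VoxelSize | None = None,
    inlier_tolerance_px: float = 2.0,
    iterations: int = 1000,
    seed: int = 0,
    match_radius_px: float = 15.0,
) -> RigidTransform2D:
    """Rigid transform mapping the moving session onto the reference.

    Fiducial blobs (nuclei) are detected in both sections; a coarse
    translation from phase correlation guides correspondence search
    (mutual nearest neighbours within ``match_radius_px`` after the
    coarse shift); RANSAC + Procrustes produce the final transform, whose
    *inverse warp* brings the moving section into registry. The returned
    transform applies identically to every channel of the moving session.
    """
    ref = np.asarray(reference_section, dtype=np.float64)
    mov = np.asarray(moving_section, dtype=np.float64)
    if ref.std() == 0 or mov.std() == 0:
        raise NoSignalError("constant section cannot be registered")
    blobs_ref = detect_blobs(ref, scale_range_nm, voxel)
    blobs_mov = detect_blobs(mov, scale_range_nm, voxel)
    if blobs_ref.shape[0] < 2 or blobs_mov.shape[0] < 2:
        raise NoConsensusError("too few fiducial blobs detected for registration")

    shift, *_ = phase_cross_correlation(mov, ref, upsample_factor=4, normalization=None)
    pa, pb = blobs_ref[:, :2], blobs_mov[:, :2]
    shifted = pa + shift  # predicted positions of reference blobs in moving frame
    d = np.linalg.norm(shifted[:, None, :] - pb[None, :, :], axis=2)
    nn_ab = d.argmin(axis=1)
    nn_ba = d.argmin(axis=0)
    pairs = [
        (i, j)
        for i, j in enumerate(nn_ab)
        if nn_ba[j] == i and d[i, j] <= match_radius_px
    ]
    if len(pairs) < 2:
        raise NoConsensusError("no mutual fiducial correspondences found")
    ia, ib = zip(*pairs)
    center = ((ref.shape[0] - 1) / 2.0, (ref.shape[1] - 1) / 2.0)
    fit, _ = estimate_rigid_ransac(
        pa[list(ia)], pb[list(ib)], inlier_tolerance_px, iterations, seed, center
    )
    return fit


def align_stack(
    reference: ChannelVolume | np.ndarray,
    upsample_factor: int = 20,
) -> list[RigidTransform2D]:
    """Per-section rigid chain aligning a stack to a middle anchor section.

    Each section is registered to its predecessor by (masked) phase
    correlation — adjacent 70 nm sections of a dense synaptic stain are
    similar enough for subpixel translation recovery — and the pairwise
    transforms are chained outward from the middle section, halving drift
    accumulation. Returns one transform per section (identity at the
    anchor); apply each transform's warp to the matching section of every
    channel.
    """
    data = reference.data if isinstance(reference, ChannelVolume) else np.asarray(reference)
    nz = data.shape[2]
    if nz < 2:
        raise InsufficientPointsError("stack alignment needs >= 2 sections")

    pair = [RigidTransform2D()]  # pair[z] maps section z onto section z-1
    for z in range(1, nz):
        prev, cur = data[:, :, z - 1], data[:, :, z]
        if prev.std() == 0 or cur.std() == 0:
            warnings.warn(f"no signal between sections {z-1} and {z}; identity used")
            pair.append(RigidTransform2D())
            continue
        shift, *_ = phase_cross_correlation(
            prev, cur, upsample_factor=upsample_factor, normalization=None
        )
        pair.append(RigidTransform2D(0.0, float(shift[0]), float(shift[1])))

    anchor = nz // 2
    chain = [RigidTransform2D()] * nz
    acc = RigidTransform2D()
    for z in range(anchor + 1, nz):
        acc = pair[z].compose(acc)  # to previous, then previous-to-anchor
        chain[z] = acc
    acc = RigidTransform2D()
    for z in range(anchor - 1, -1, -1):
        acc = pair[z + 1].inverse().compose(acc)
        chain[z] = acc
    return chain


def warp_volume(channel: ChannelVolume, transforms: list[RigidTransform2D]) -> ChannelVolume:
    """Apply a per-section transform chain to every section of a channel."""
    if len(transforms) != channel.n_sections:
        raise InsufficientPointsError("one transform per section required")
    out = np.empty_like(channel.data, dtype=np.float64)
    for z, t in enumerate(transforms):
        out[:, :, z] = t.warp(channel.section(z))
    return ChannelVolume(channel.name, np.clip(out, 0, 65535), channel.voxel)
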