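"""Core domain types and volume addressing.

Array-tomography data volumes are multichannel 3D intensity grids with
strongly anisotropic voxels: the in-plane sampling is set by the camera
(typically 100 nm/px after deconvolution) while the axial sampling equals
the physical section thickness (70 nm for ultrathin resin sections).
Channels are named ``"<antibody>-<round>"`` (e.g. ``"Synapsin1-2"``) and
may also be addressed by their 1-based position in the volume.

Arrays are indexed ``data[x, y, z]``; a "section" is the 2D plane
``data[:, :, z]`` corresponding to one physical ultrathin section.
All cutout ranges are 0-based and half-open, so a range ``(700, 1700)``
has width 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ChannelNotFoundError,
    CompositeError,
    GeometryError,
    RangeError,
    ShapeMismatchError,
)

__all__ = [
    "VoxelSize",
    "DEFAULT_VOXEL",
    "ChannelVolume",
    "DataVolume",
    "ROIMask",
    "physical_volume",
    "cutout",
    "mcfc_composite",
    "MCFC_COLORS",
]

MAX_INTENSITY = 65535.0


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel dimensions in nanometres.

    ``vz`` is the section thickness. The default (100, 100, 70) nm is the
    effective post-deconvolution resolution of array-tomography stacks
    cut at 70 nm.
    """

    vx: float = 100.0
    vy: float = 100.0
    vz: float = 70.0

    def __post_init__(self) -> None:
        if not (self.vx > 0 and self.vy > 0 and self.vz > 0):
            raise GeometryError(f"voxel dimensions must be positive, got {self}")

    @property
    def volume_nm3(self) -> float:
        return self.vx * self.vy * self.vz

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.vx, self.vy, self.vz)


DEFAULT_VOXEL = VoxelSize(100.0, 100.0, 70.0)


@dataclass
class ChannelVolume:
    """One antibody channel: a 3D intensity grid plus voxel geometry.

    ``data`` is indexed ``[x, y, z]``, non-negative, on the 16-bit
    acquisition scale (0–65535 a.u.). ``name`` follows the
    ``"<antibody>-<round>"`` convention.
    """

    name: str
    data: np.ndarray
    voxel: VoxelSize = field(default_factory=lambda: DEFAULT_VOXEL)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"channel data must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise GeometryError(f"channel dimensions must be >= 1, got {self.data.shape}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > MAX_INTENSITY):
            raise GeometryError("intensities must lie in [0, 65535] a.u.")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nx, ny, nz)

    @property
    def n_sections(self) -> int:
        return self.data.shape[2]

    def section(self, z: int) -> np.ndarray:
        """The 2D image of physical section ``z`` (a view, shape (nx, ny))."""
        return self.data[:, :, z]

    def sections(self):
        for z in range(self.n_sections):
            yield self.data[:, :, z]


@dataclass
class DataVolume:
    """An ordered multichannel reconstruction identified by a token.

    Channels may be addressed by name or by 1-based numeric token (the
    position in the channel list).
    """

    token: str
    channels: list[ChannelVolume]

    def __post_init__(self) -> None:
        if not self.channels:
            raise GeometryError("a DataVolume needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise GeometryError(f"channel names must be unique, got {names}")
        shape0, voxel0 = self.channels[0].shape, self.channels[0].voxel
        for c in self.channels[1:]:
            if c.shape != shape0:
                raise ShapeMismatchError(
                    f"channel {c.name!r} shape {c.shape} != {shape0}"
                )
            if c.voxel != voxel0:
                raise ShapeMismatchError(f"channel {c.name!r} voxel size differs")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def voxel(self) -> VoxelSize:
        return self.channels[0].voxel

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def get_channel(self, key: str | int) -> ChannelVolume:
        """Look up a channel by name or 1-based numeric token."""
        if isinstance(key, str) and key.isdigit():
            key = int(key)
        if isinstance(key, int):
            if not 1 <= key <= len(self.channels):
                raise ChannelNotFoundError(
                    f"numeric channel token {key} out of range 1..{len(self.channels)}"
                )
            return self.channels[key - 1]
        for c in self.channels:
            if c.name == key:
                return c
        raise ChannelNotFoundError(f"no channel named {key!r} in {self.token!r}")


@dataclass
class ROIMask:
    """A labelled boolean region congruent with its parent volume."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError("ROI mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def physical_volume(
    nx: int, ny: int, nz: int, voxel: VoxelSize = DEFAULT_VOXEL
) -> tuple[float, int]:
    """Physical volume of an ``nx × ny × nz`` grid, in µm³.

    Returns ``(exact, rounded)`` where ``rounded`` is the nearest integer
    (ties away from zero), the convention used when data-volume sizes are
    reported in µm³.
    """
    if not (nx >= 1 and ny >= 1 and nz >= 1):
        raise GeometryError(f"voxel counts must be >= 1, got {(nx, ny, nz)}")
    exact = nx * ny * nz * voxel.volume_nm3 / 1e9
    rounded = int(math.floor(exact + 0.5))  # half away from zero; volumes are > 0
    return exact, rounded


def _pool2x2_xy(data: np.ndarray) -> np.ndarray:
    """2×2 mean pooling in x and y (z untouched); odd trailing row/col dropped."""
    nx, ny = data.shape[0] - data.shape[0] % 2, data.shape[1] - data.shape[1] % 2
    d = data[:nx, :ny]
    if d.ndim == 3:
        return d.reshape(nx // 2, 2, ny // 2, 2, d.shape[2]).mean(axis=(1, 3))
    return d.reshape(nx // 2, 2, ny // 2, 2).mean(axis=(1, 3))


def _check_range(rng: tuple[int, int], n: int, axis: str) -> tuple[int, int]:
    lo, hi = int(rng[0]), int(rng[1])
    if not (0 <= lo < hi <= n):
        raise RangeError(f"{axis}-range [{lo},{hi}) outside [0,{n})")
    return lo, hi


def _check_index(i: int, n: int, axis: str) -> int:
    i = int(i)
    if not 0 <= i < n:
        raise RangeError(f"{axis} index {i} outside [0,{n})")
    return i


def cutout(
    volume: DataVolume,
    channel: str | int,
    plane: str = "3d",
    resolution: int = 0,
    x_range: tuple[int, int] | int | None = None,
    y_range: tuple[int, int] | int | None = None,
    z_range: tuple[int, int] | int | None = None,
) -> np.ndarray:
    """Extract a 2D plane or 3D subvolume from one channel.

    ``plane`` is ``"xy"``, ``"xz"``, ``"yz"`` or ``"3d"``. For a 2D plane
    the orthogonal axis takes a single index instead of a range. Ranges
    are half-open ``[min, max)`` in the coordinates of the requested
    resolution level: level 0 is the stored grid, level 1 halves x and y
    by 2×2 mean pooling (z is never downsampled — resolution levels are
    in-plane display mipmaps). Omitted ranges default to the full axis.
    The returned array is always a copy.
    """
    chan = volume.get_channel(channel)
    data = chan.data.astype(np.float64) if resolution == 1 else chan.data
    if resolution not in (0, 1):
        raise RangeError(f"resolution must be 0 or 1, got {resolution}")
    if resolution == 1:
        data = _pool2x2_xy(data)
    nx, ny, nz = data.shape

    if plane == "3d":
        xr = _check_range(x_range if x_range is not None else (0, nx), nx, "x")
        yr = _check_range(y_range if y_range is not None else (0, ny), ny, "y")
        zr = _check_range(z_range if z_range is not None else (0, nz), nz, "z")
        return data[xr[0]:xr[1], yr[0]:yr[1], zr[0]:zr[1]].copy()
    if plane == "xy":
        xr = _check_range(x_range if x_range is not None else (0, nx), nx, "x")
        yr = _check_range(y_range if y_range is not None else (0, ny), ny, "y")
        z = _check_index(z_range, nz, "z")
        return data[xr[0]:xr[1], yr[0]:yr[1], z].copy()
    if plane == "xz":
        xr = _check_range(x_range if x_range is not None else (0, nx), nx, "x")
        zr = _check_range(z_range if z_range is not None else (0, nz), nz, "z")
        y = _check_index(y_range, ny, "y")
        return data[xr[0]:xr[1], y, zr[0]:zr[1]].copy()
    if plane == "yz":
        yr = _check_range(y_range if y_range is not None else (0, ny), ny, "y")
        zr = _check_range(z_range if z_range is not None else (0, nz), nz, "z")
        x = _check_index(x_range, nx, "x")
        return data[x, yr[0]:yr[1], zr[0]:zr[1]].copy()
    raise RangeError(f"unknown plane {plane!r}; expected xy, xz, yz or 3d")


# False-color slot order for multichannel composites.
MCFC_COLORS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("cyan", (0.0, 1.0, 1.0)),
    ("yellow", (1.0, 1.0, 0.0)),
    ("magenta", (1.0, 0.0, 1.0)),
    ("red", (1.0, 0.0, 0.0)),
    ("green", (0.0, 1.0, 0.0)),
    ("blue", (0.0, 0.0, 1.0)),
)

PLACEHOLDER = "0"


def mcfc_composite(
    volume: DataVolume,
    channel_tokens: Sequence[str | int],
    plane: str = "xy",
    resolution: int = 0,
    x_range: tuple[int, int] | int | None = None,
    y_range: tuple[int, int] | int | None = None,
    z_range: tuple[int, int] | int | None = None,
) -> np.ndarray:
    """Additive false-color composite of up to six channels.

    The k-th listed channel is rendered in the k-th color of
    (cyan, yellow, magenta, red, green, blue); the placeholder token
    ``"0"`` consumes a color slot without drawing anything, so e.g.
    ``["0", "0", "0", "Synapsin1-2", "PSD95-1", "DAPI-1"]`` renders
    Synapsin1 red, PSD95 green and DAPI blue. Channels are min–max
    scaled individually, multiplied by their slot color, summed and
    clipped to [0, 1]. Returns an RGB float array with a trailing axis
    of size 3.
    """
    tokens = list(channel_tokens)
    if len(tokens) > len(MCFC_COLORS):
        raise CompositeError(f"at most {len(MCFC_COLORS)} channel tokens, got {len(tokens)}")

    def is_placeholder(t) -> bool:
        return t == 0 or (isinstance(t, str) and t.strip() == PLACEHOLDER)

    if all(is_placeholder(t) for t in tokens):
        raise CompositeError("composite needs at least one non-placeholder channel")

    out = None
    for (slot_name, color), tok in zip(MCFC_COLORS, tokens):
        if is_placeholder(tok):
            continue
        img = cutout(volume, tok, plane, resolution, x_range, y_range, z_range)
        img = np.asarray(img, dtype=np.float64)
        lo, hi = img.min(), img.max()
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        if out is None:
            out = np.zeros(img.shape + (3,), dtype=np.float64)
        out += scaled[..., None] * np.asarray(color)
    return np.clip(out, 0.0, 1.0)
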