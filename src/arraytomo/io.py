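"""On-disk containers: HDF5 data volumes, per-channel TIFF stacks, PNG.

The HDF5 layout is one file per :class:`~arraytomo.core.DataVolume`:

* ``/channels/<name>`` — one 3D ``uint16`` dataset per channel, stored
  in page order (z, y, x);
* root attributes ``voxel_nm`` (3 floats, x/y/z), ``token`` and
  ``channel_order`` (to keep the 1-based numeric channel tokens stable).

TIFF import/export is one multi-page (z-paged) file per channel, pages
in ImageJ order (z, y, x).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import ChannelVolume, DataVolume, VoxelSize

__all__ = [
    "save_hdf5",
    "load_hdf5",
    "write_channel_tiff",
    "read_channel_tiff",
    "save_png",
]


def _to_pages(data: np.ndarray) -> np.ndarray:
    """(x, y, z) -> (z, y, x) page order, rounded to uint16."""
    return np.clip(np.rint(data), 0, 65535).astype(np.uint16).transpose(2, 1, 0)


def _from_pages(pages: np.ndarray) -> np.ndarray:
    if pages.ndim == 2:  # single-section file
        pages = pages[None]
    return pages.transpose(2, 1, 0)


def save_hdf5(volume: DataVolume, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["token"] = volume.token
        f.attrs["voxel_nm"] = np.asarray(volume.voxel.as_tuple(), dtype=np.float64)
        f.attrs["channel_order"] = [c.name for c in volume.channels]
        grp = f.create_group("channels")
        for c in volume.channels:
            grp.create_dataset(
                c.name, data=_to_pages(c.data), compression="gzip", track_times=False
            )
    return path


def load_hdf5(path: str | Path) -> DataVolume:
    with h5py.File(path, "r") as f:
        token = str(f.attrs["token"])
        vx, vy, vz = (float(v) for v in f.attrs["voxel_nm"])
        voxel = VoxelSize(vx, vy, vz)
        order = [str(n) for n in f.attrs["channel_order"]]
        channels = [
            ChannelVolume(name, _from_pages(f["channels"][name][()]).astype(np.float64), voxel)
            for name in order
        ]
    return DataVolume(token, channels)


def write_channel_tiff(channel: ChannelVolume, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, _to_pages(channel.data), imagej=True)
    return path


def read_channel_tiff(
    path: str | Path, name: str | None = None, voxel: VoxelSize | None = None
) -> ChannelVolume:
    """Read a z-paged TIFF stack as a channel; 2D files become single-section volumes."""
    pages = tifffile.imread(path)
    return ChannelVolume(
        name if name is not None else Path(path).stem,
        _from_pages(np.asarray(pages)).astype(np.float64),
        voxel if voxel is not None else VoxelSize(),
    )


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2D intensity image (min–max scaled) or an RGB float image.

    Images are indexed (x, y[, rgb]); the PNG is written in row/column
    display order.
    """
    import imageio.v3 as iio

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        lo, hi = img.min(), img.max()
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        out = (scaled.T * 255).astype(np.uint8)
    elif img.ndim == 3 and img.shape[-1] == 3:
        out = (np.clip(img, 0, 1).transpose(1, 0, 2) * 255).astype(np.uint8)
    else:
        raise ValueError("expected a 2D intensity or (x, y, 3) RGB image")
    iio.imwrite(Path(path), out)
    return Path(path)
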