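"""Ground-truthed synthetic array-tomography scenes.

The generator plants a homogeneous Poisson field of synapse loci in the
neuropil (the volume minus cell bodies) and renders, per antibody
channel, an anisotropic 3D Gaussian punctum at each locus the channel
participates in. Channels marking presynaptic proteins sit on the locus;
channels marking postsynaptic proteins are displaced by a short vector of
random direction (pre/postsynaptic compartments are ~150 nm apart), which
is what broadens their cross-channel correlation peaks. A DAPI-like
channel renders bright nuclei; Synapsin-like channels are excluded from
somata, whose interiors carry no synapse loci. Additive Gaussian read
noise and optional Poisson shot noise come last.

Every random draw flows from a single seed, so a scene is bit-identical
under the same spec, and all planted quantities (loci, per-channel
punctum centers and amplitudes, session transforms, per-section jitter)
are recorded for recovery tests.

Default condition: synapse density 1.0 loci/µm³ of neuropil (the
textbook cortical neuropil figure), punctum widths near the diffraction
limit (σ 150×150×100 nm), punctum peak amplitude 20 000 a.u. on the
16-bit scale with Gaussian read noise σ 2 000 a.u. — i.e. peak SNR 10.
None of these defaults is an estimate of any real dataset; they are a
plausible operating point for exercising the pipeline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ChannelVolume, DataVolume, VoxelSize, DEFAULT_VOXEL, MAX_INTENSITY
from .errors import DegenerateInputError, GeometryError, ChannelNotFoundError
from .registration import RigidTransform2D

__all__ = [
    "ChannelModel",
    "SceneSpec",
    "SyntheticScene",
    "generate_scene",
    "apply_session_transform",
    "tile_mosaic",
    "demo_spec",
]


@dataclass
class ChannelModel:
    """Statistical model for one synthetic antibody channel.

    kind
        ``"puncta"`` renders synaptic puncta at participating loci;
        ``"nuclei"`` renders DAPI-like nuclear spheres instead.
    participation
        Fraction of synapse loci bearing a punctum in this channel.
    amplitude_mean, amplitude_sd
        Punctum peak amplitude draw (a.u., clipped at 0).
    sigma_nm
        Gaussian punctum widths (σx, σy, σz) in nm.
    offset_mean_nm, offset_sd_nm
        Length of the displacement of the punctum center from the synapse
        locus (random direction per synapse). Presynaptic-style channels
        use 0; postsynaptic-style channels ~150 nm.
    """

    kind: str = "puncta"
    participation: float = 1.0
    amplitude_mean: float = 20000.0
    amplitude_sd: float = 2000.0
    sigma_nm: tuple[float, float, float] = (150.0, 150.0, 100.0)
    offset_mean_nm: float = 0.0
    offset_sd_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("puncta", "nuclei"):
            raise GeometryError(f"unknown channel kind {self.kind!r}")
        if not 0.0 <= self.participation <= 1.0:
            raise GeometryError("participation must be in [0, 1]")
        if any(s <= 0 for s in self.sigma_nm):
            raise GeometryError("punctum widths must be positive")


@dataclass
class SceneSpec:
    """Full specification of a synthetic scene; the seed fixes everything."""

    shape: tuple[int, int, int] = (128, 128, 20)
    voxel: VoxelSize = field(default_factory=lambda: DEFAULT_VOXEL)
    synapse_density: float = 1.0  # loci per µm³ of neuropil
    channels: dict[str, ChannelModel] = field(default_factory=dict)
    nucleus_count: int = 0
    nucleus_radius_nm: float = 2500.0
    soma_count: int = 0
    soma_radius_nm: float = 4000.0
    noise_sd: float = 2000.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synapse_density < 0:
            raise GeometryError("synapse density must be >= 0")
        if any(s < 1 for s in self.shape):
            raise GeometryError("scene dimensions must be >= 1")

    @property
    def volume_um3(self) -> float:
        nx, ny, nz = self.shape
        return nx * ny * nz * self.voxel.volume_nm3 / 1e9

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise GeometryError(f"unknown scene spec keys: {sorted(unknown)}")
        if "voxel" in d and not isinstance(d["voxel"], VoxelSize):
            d["voxel"] = VoxelSize(*d["voxel"])
        if "shape" in d:
            d["shape"] = tuple(int(v) for v in d["shape"])
        if "channels" in d:
            chans = {}
            for name, cm in d["channels"].items():
                if isinstance(cm, ChannelModel):
                    chans[name] = cm
                else:
                    cm = dict(cm)
                    if "sigma_nm" in cm:
                        cm["sigma_nm"] = tuple(float(v) for v in cm["sigma_nm"])
                    unknown = set(cm) - set(ChannelModel.__dataclass_fields__)
                    if unknown:
                        raise GeometryError(
                            f"unknown channel model keys for {name!r}: {sorted(unknown)}"
                        )
                    chans[name] = ChannelModel(**cm)
            d["channels"] = chans
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel"] = list(self.voxel.as_tuple())
        d["shape"] = list(self.shape)
        d["channels"] = {
            k: {**asdict(v), "sigma_nm": list(v.sigma_nm)} for k, v in self.channels.items()
        }
        return d


@dataclass
class SyntheticScene:
    """A rendered scene plus every piece of planted ground truth."""

    spec: SceneSpec
    loci: pd.DataFrame          # one row per synapse locus (voxel + µm coords)
    puncta_truth: pd.DataFrame  # one row per rendered punctum
    nuclei: pd.DataFrame        # centers + radius (voxels)
    somata: pd.DataFrame
    rendered: DataVolume
    session_transforms: dict = field(default_factory=dict)
    jitter_truth: pd.DataFrame | None = None

    @property
    def neuropil_volume_um3(self) -> float:
        """Volume of the scene minus the planted somata (truth, µm³)."""
        vox_um3 = self.spec.voxel.volume_nm3 / 1e9
        soma_vox = _soma_mask(self.spec, self.somata).sum()
        nx, ny, nz = self.spec.shape
        return (nx * ny * nz - int(soma_vox)) * vox_um3


def _soma_mask(spec: SceneSpec, somata: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    if len(somata) == 0:
        return mask
    vx, vy, vz = spec.voxel.as_tuple()
    gx, gy, gz = np.mgrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    for _, row in somata.iterrows():
        r2 = (
            ((gx - row.x_vox) * vx) ** 2
            + ((gy - row.y_vox) * vy) ** 2
            + ((gz - row.z_vox) * vz) ** 2
        )
        mask |= r2 <= row.radius_nm**2
    return mask


def _render_gaussian(data: np.ndarray, center, sigma_vox, amplitude, trunc: float = 4.0):
    """Add one anisotropic Gaussian punctum, truncated at ``trunc``·σ."""
    lo = [max(0, int(np.floor(c - trunc * s))) for c, s in zip(center, sigma_vox)]
    hi = [
        min(n, int(np.ceil(c + trunc * s)) + 1)
        for c, s, n in zip(center, sigma_vox, data.shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    ax = [np.arange(l, h) for l, h in zip(lo, hi)]
    q = [((a - c) / s) ** 2 for a, c, s in zip(ax, center, sigma_vox)]
    g = amplitude * np.exp(
        -0.5 * (q[0][:, None, None] + q[1][None, :, None] + q[2][None, None, :])
    )
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += g


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene from its spec (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    vx, vy, vz = spec.voxel.as_tuple()
    vox_um3 = spec.voxel.volume_nm3 / 1e9

    somata = pd.DataFrame(
        {
            "x_vox": rng.uniform(0, nx, spec.soma_count),
            "y_vox": rng.uniform(0, ny, spec.soma_count),
            "z_vox": rng.uniform(0, nz, spec.soma_count),
            "radius_nm": np.full(spec.soma_count, spec.soma_radius_nm),
        }
    )
    nuclei = pd.DataFrame(
        {
            "x_vox": rng.uniform(0, nx, spec.nucleus_count),
            "y_vox": rng.uniform(0, ny, spec.nucleus_count),
            "z_vox": rng.uniform(0, nz, spec.nucleus_count),
            "radius_nm": np.full(spec.nucleus_count, spec.nucleus_radius_nm),
        }
    )

    soma_vox = _soma_mask(spec, somata)
    neuropil_um3 = (nx * ny * nz - int(soma_vox.sum())) * vox_um3

    n_loci = int(rng.poisson(spec.synapse_density * neuropil_um3))
    pts = []
    while len(pts) < n_loci:
        cand = rng.uniform([0, 0, 0], [nx, ny, nz], size=(max(n_loci, 16), 3))
        if len(somata):
            idx = np.clip(np.floor(cand).astype(int), 0, [nx - 1, ny - 1, nz - 1])
            keep = ~soma_vox[idx[:, 0], idx[:, 1], idx[:, 2]]
            cand = cand[keep]
        pts.extend(cand.tolist())
    pts = np.asarray(pts[:n_loci]).reshape(n_loci, 3)

    loci = pd.DataFrame(pts, columns=["x_vox", "y_vox", "z_vox"])
    loci.insert(0, "locus_id", np.arange(n_loci))
    loci["x_um"] = loci.x_vox * vx / 1000
    loci["y_um"] = loci.y_vox * vy / 1000
    loci["z_um"] = loci.z_vox * vz / 1000

    channels: list[ChannelVolume] = []
    truth_rows: list[dict] = []
    for name, cm in spec.channels.items():
        data = np.zeros(spec.shape, dtype=np.float64)
        if cm.kind == "nuclei":
            for _, row in nuclei.iterrows():
                sig = (
                    row.radius_nm / 2 / vx,
                    row.radius_nm / 2 / vy,
                    row.radius_nm / 2 / vz,
                )
                amp = max(rng.normal(cm.amplitude_mean, cm.amplitude_sd), 0.0)
                _render_gaussian(data, (row.x_vox, row.y_vox, row.z_vox), sig, amp)
        else:
            present = rng.random(n_loci) < cm.participation
            sig_vox = (cm.sigma_nm[0] / vx, cm.sigma_nm[1] / vy, cm.sigma_nm[2] / vz)
            for k in np.flatnonzero(present):
                if cm.offset_mean_nm > 0 or cm.offset_sd_nm > 0:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction) + 1e-12
                    length = max(rng.normal(cm.offset_mean_nm, cm.offset_sd_nm), 0.0)
                    off_nm = direction * length
                else:
                    off_nm = np.zeros(3)
                center = pts[k] + off_nm / np.array([vx, vy, vz])
                amp = max(rng.normal(cm.amplitude_mean, cm.amplitude_sd), 0.0)
                _render_gaussian(data, center, sig_vox, amp)
                truth_rows.append(
                    {
                        "locus_id": int(k),
                        "channel": name,
                        "x_vox": center[0],
                        "y_vox": center[1],
                        "z_vox": center[2],
                        "amplitude": amp,
                    }
                )
        if np.mean(data > MAX_INTENSITY) > 0.5:
            raise DegenerateInputError(
                f"channel {name!r}: more than half the voxels saturate before noise"
            )
        if spec.shot_noise:
            data = rng.poisson(np.clip(data, 0, None)).astype(np.float64)
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        channels.append(
            ChannelVolume(name, np.clip(data, 0.0, MAX_INTENSITY), spec.voxel)
        )

    puncta_truth = pd.DataFrame(
        truth_rows, columns=["locus_id", "channel", "x_vox", "y_vox", "z_vox", "amplitude"]
    )
    return SyntheticScene(
        spec=spec,
        loci=loci,
        puncta_truth=puncta_truth,
        nuclei=nuclei,
        somata=somata,
        rendered=DataVolume(f"synthetic-{spec.seed}", channels),
    )


def apply_session_transform(
    scene: SyntheticScene,
    channels: list[str],
    rotation: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    per_section_jitter: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Misregister a subset of channels as one imaging session.

    Every z-section of the listed channels is resampled under the same
    rigid transform (rotation in degrees about the section center,
    translation in voxels) plus an independent per-section translation
    jitter of s.d. ``per_section_jitter`` voxels, shared across the
    session's channels (they are imaged simultaneously). The planted
    transform and jitter table are recorded on the returned scene for
    recovery tests. The input scene is not modified.
    """
    for name in channels:
        scene.rendered.get_channel(name)  # raises ChannelNotFoundError
    rng = np.random.default_rng(seed)
    nz = scene.rendered.shape[2]
    jit = rng.normal(0.0, per_section_jitter, size=(nz, 2)) if per_section_jitter > 0 else np.zeros((nz, 2))
    base = RigidTransform2D(rotation, translation[0], translation[1])

    new_channels = []
    for c in scene.rendered.channels:
        if c.name in channels:
            out = np.empty_like(c.data, dtype=np.float64)
            for z in range(nz):
                t = RigidTransform2D(rotation, translation[0] + jit[z, 0], translation[1] + jit[z, 1])
                out[:, :, z] = t.warp(c.section(z))
            new_channels.append(ChannelVolume(c.name, np.clip(out, 0, MAX_INTENSITY), c.voxel))
        else:
            new_channels.append(ChannelVolume(c.name, c.data.copy(), c.voxel))

    jitter_df = pd.DataFrame(
        {"section": np.arange(nz), "jx_vox": jit[:, 0], "jy_vox": jit[:, 1]}
    )
    out_scene = SyntheticScene(
        spec=scene.spec,
        loci=scene.loci.copy(),
        puncta_truth=scene.puncta_truth.copy(),
        nuclei=scene.nuclei.copy(),
        somata=scene.somata.copy(),
        rendered=DataVolume(scene.rendered.token, new_channels),
        session_transforms={**scene.session_transforms, tuple(sorted(channels)): base},
        jitter_truth=jitter_df,
    )
    return out_scene


def tile_mosaic(
    section: np.ndarray, tile_shape: tuple[int, int], overlap_fraction: float
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut a 2D section into overlapping microscope fields of view.

    Tiles of ``tile_shape`` cover the section with nominal stride
    ``tile × (1 − overlap_fraction)``, evenly redistributed so the last
    tile ends flush with the section edge. Returns
    ``[(true_origin, tile), ...]`` for stitching-recovery tests.
    """
    img = np.asarray(section)
    if not 0.0 < overlap_fraction <= 0.5:
        raise DegenerateInputError("overlap_fraction must lie in (0, 0.5]")
    tx, ty = int(tile_shape[0]), int(tile_shape[1])
    if tx > img.shape[0] or ty > img.shape[1]:
        raise GeometryError(f"tile {tile_shape} larger than section {img.shape}")

    def origins(n: int, t: int) -> np.ndarray:
        if n == t:
            return np.array([0])
        stride = t * (1.0 - overlap_fraction)
        count = int(np.ceil((n - t) / stride)) + 1
        return np.round(np.linspace(0, n - t, count)).astype(int)

    tiles = []
    for oy in origins(img.shape[1], ty):
        for ox in origins(img.shape[0], tx):
            tiles.append(((int(ox), int(oy)), img[ox:ox + tx, oy:oy + ty].copy()))
    return tiles


def demo_spec(seed: int = 0, shape: tuple[int, int, int] = (128, 128, 20)) -> SceneSpec:
    """A small representative scene: presynaptic, postsynaptic and
    partially participating channels plus DAPI-like nuclei and
    Synapsin-excluded somata."""
    return SceneSpec(
        shape=shape,
        synapse_density=1.0,
        channels={
            "Synapsin1-1": ChannelModel(participation=0.95),
            "PSD95-1": ChannelModel(participation=0.85, offset_mean_nm=150.0, offset_sd_nm=30.0),
            "vGluT2-1": ChannelModel(participation=0.5),
            "DAPI-1": ChannelModel(kind="nuclei", amplitude_mean=30000.0, amplitude_sd=2000.0),
        },
        nucleus_count=10,
        soma_count=2,
        noise_sd=2000.0,
        seed=seed,
    )
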