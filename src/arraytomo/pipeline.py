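"""Configurable end-to-end pipeline on synthetic or stored volumes.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages to
run and their parameters; unknown keys are rejected up front so a typo
cannot silently fall back to a default. Outputs land in one artifact
directory together with the effective configuration and a provenance
record (config hash, seed, package version), and deterministic stages
reproduce bit-identical outputs under an identical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as atio
from .colocalization import pairwise_matrix
from .consistency import consistency_report
from .core import ChannelVolume, DataVolume, ROIMask
from .density import neuropil_mask, roi_density
from .errors import ArrayTomoError
from .preprocess import PSFModel, deconvolve, rolling_ball_subtract
from .puncta import SegmentationParams, segment_puncta
from .registration import align_stack, register_session, transforms_to_json, warp_volume
from .simulate import SceneSpec, apply_session_transform, generate_scene

log = logging.getLogger("arraytomo.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MisregisterConfig(_Strict):
    channels: list[str]
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    per_section_jitter: float = 0.0


class RegisterConfig(_Strict):
    reference_channel: str = "DAPI-1"
    section: int = 0
    iterations: int = 1000
    inlier_tolerance_px: float = 2.0


class PreprocessConfig(_Strict):
    channels: list[str] | None = None
    rolling_ball_radius: int = 20
    rl_iterations: int = 20
    psf_sigma_px: float = 1.5


class AlignConfig(_Strict):
    channel: str = "Synapsin1-1"


class SegmentConfig(_Strict):
    channels: list[str]
    maxima_radius: int = 3
    detection_floor: float | None = None
    mahalanobis_cut: float = 2.0
    min_mask_voxels: int = 4


class ColocConfig(_Strict):
    channels: list[str]
    max_shift: int = 10
    n_sections: int = 10


class ConsistencyConfig(_Strict):
    round1: str
    round3: str
    threshold: float = 1000.0


class DensityConfig(_Strict):
    puncta_channel: str
    synapsin_channel: str = "Synapsin1-1"
    dilation_radii: tuple[int, int, int] = (5, 5, 4)
    max_hole_voxels: int = 2000


class PipelineConfig(_Strict):
    """Full pipeline description; any unknown key raises a validation
    error before any computation starts."""

    stages: list[str]
    seed: int = 0
    input_volume: str | None = None  # HDF5 path; alternative to `scene`
    scene: dict | None = None  # SceneSpec fields for the simulate stage
    misregister: MisregisterConfig | None = None
    registration: RegisterConfig = Field(default_factory=RegisterConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    align: AlignConfig = Field(default_factory=AlignConfig)
    segment: SegmentConfig | None = None
    coloc: ColocConfig | None = None
    consistency: ConsistencyConfig | None = None
    density: DensityConfig | None = None

    _KNOWN_STAGES = (
        "simulate", "misregister", "register", "preprocess",
        "align", "segment", "coloc", "consistency", "density",
    )

    def model_post_init(self, __context) -> None:
        unknown = [s for s in self.stages if s not in self._KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    return PipelineConfig.model_validate(raw)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages in order; returns the artifact dir.

    Stage order is fixed (simulate/ingest → misregister → register →
    preprocess → align → segment → coloc/consistency/density) regardless
    of the order given in ``stages``. Every run writes
    ``effective_config.yaml`` and ``provenance.json`` next to its
    outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)

    (out / "effective_config.yaml").write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )

    volume: DataVolume | None = None
    scene = None
    if "simulate" in stages:
        if config.scene is None:
            raise ArrayTomoError("simulate stage requires a `scene` block")
        spec = SceneSpec.from_dict({**config.scene, "seed": config.seed})
        scene = generate_scene(spec)
        volume = scene.rendered
        scene.loci.to_csv(out / "truth_loci.csv", index=False)
        scene.puncta_truth.to_csv(out / "truth_puncta.csv", index=False)
        log.info("simulated scene: %d loci, %d channels", len(scene.loci), len(volume.channels))
    elif config.input_volume is not None:
        volume = atio.load_hdf5(config.input_volume)
    else:
        raise ArrayTomoError("either a simulate stage or input_volume is required")

    reference_volume = volume  # pre-misregistration copy for session recovery

    if "misregister" in stages:
        if scene is None:
            raise ArrayTomoError("misregister stage requires a simulated scene")
        if config.misregister is None:
            raise ArrayTomoError("misregister stage requires a `misregister` block")
        m = config.misregister
        scene = apply_session_transform(
            scene, m.channels, m.rotation, tuple(m.translation),
            m.per_section_jitter, seed=config.seed + 1,
        )
        volume = scene.rendered
        scene.jitter_truth.to_csv(out / "truth_jitter.csv", index=False)

    if "register" in stages:
        r = config.registration
        ref = reference_volume.get_channel(r.reference_channel).section(r.section)
        mov = volume.get_channel(r.reference_channel).section(r.section)
        fit = register_session(
            ref, mov, inlier_tolerance_px=r.inlier_tolerance_px,
            iterations=r.iterations, seed=config.seed,
        )
        transforms_to_json({"session": fit}, out / "session_transform.json")
        moved = config.misregister.channels if config.misregister else volume.channel_names
        inv = fit.inverse()
        volume = DataVolume(
            volume.token,
            [
                ChannelVolume(
                    c.name,
                    np.clip(
                        np.stack(
                            [inv.warp(c.section(z)) for z in range(c.n_sections)], axis=2
                        ),
                        0, 65535,
                    ),
                    c.voxel,
                )
                if c.name in moved
                else c
                for c in volume.channels
            ],
        )
        log.info("session registration: theta=%.3f dx=%.2f dy=%.2f", fit.theta, fit.dx, fit.dy)

    if "preprocess" in stages:
        p = config.preprocess
        psf = PSFModel.gaussian(p.psf_sigma_px, ndim=2)
        names = p.channels or volume.channel_names
        new_channels = []
        for c in volume.channels:
            if c.name in names:
                secs = []
                for z in range(c.n_sections):
                    s = rolling_ball_subtract(c.section(z), p.rolling_ball_radius)
                    secs.append(deconvolve(s, psf, p.rl_iterations))
                new_channels.append(
                    ChannelVolume(c.name, np.clip(np.stack(secs, axis=2), 0, 65535), c.voxel)
                )
            else:
                new_channels.append(c)
        volume = DataVolume(volume.token, new_channels)

    if "align" in stages:
        chain = align_stack(volume.get_channel(config.align.channel))
        transforms_to_json(chain, out / "stack_transforms.json")
        volume = DataVolume(
            volume.token, [warp_volume(c, chain) for c in volume.channels]
        )

    atio.save_hdf5(volume, out / "volume.h5")

    if "segment" in stages:
        if config.segment is None:
            raise ArrayTomoError("segment stage requires a `segment` block")
        s = config.segment
        params = SegmentationParams(
            maxima_radius=s.maxima_radius,
            detection_floor=s.detection_floor,
            mahalanobis_cut=s.mahalanobis_cut,
            min_mask_voxels=s.min_mask_voxels,
        )
        tables = []
        for name in s.channels:
            t = segment_puncta(volume.get_channel(name), params)
            tables.append(t)
            log.info("segmented %s: %d puncta", name, len(t))
        pd.concat(tables, ignore_index=True).to_csv(out / "puncta.csv", index=False)

    if "coloc" in stages:
        if config.coloc is None:
            raise ArrayTomoError("coloc stage requires a `coloc` block")
        cc = config.coloc
        mat = pairwise_matrix(volume, cc.channels, cc.max_shift, cc.n_sections)
        mat.to_csv(out / "colocalization.csv", index=False)

    if "consistency" in stages:
        if config.consistency is None:
            raise ArrayTomoError("consistency stage requires a `consistency` block")
        cf = config.consistency
        rep = consistency_report(
            volume.get_channel(cf.round1).section(0),
            volume.get_channel(cf.round3).section(0),
            cf.threshold,
        )
        pd.DataFrame(
            [
                {
                    "antibody": cf.round1.rsplit("-", 1)[0],
                    "R": rep.r,
                    "R_rotated": rep.r_rotated,
                    "pct_consistent": rep.pct_consistent,
                    "pct_consistent_rotated": rep.pct_consistent_rotated,
                    "bg_pct_consistent": rep.bg_pct_consistent,
                    "bg_pct_consistent_rotated": rep.bg_pct_consistent_rotated,
                }
            ]
        ).to_csv(out / "consistency.csv", index=False)

    if "density" in stages:
        if config.density is None:
            raise ArrayTomoError("density stage requires a `density` block")
        d = config.density
        puncta = pd.read_csv(out / "puncta.csv")
        puncta = puncta[puncta.channel == d.puncta_channel]
        npil = neuropil_mask(
            volume.get_channel(d.synapsin_channel),
            dilation_radii=tuple(d.dilation_radii),
            max_hole_voxels=d.max_hole_voxels,
        )
        roi = ROIMask("full", np.ones(volume.shape, dtype=bool))
        res = roi_density(puncta, roi, npil)
        (out / "density.json").write_text(
            json.dumps(
                {
                    "roi_label": res.roi_label,
                    "puncta_count": res.puncta_count,
                    "neuropil_volume_um3": res.neuropil_volume_um3,
                    "density_per_um3": res.density_per_um3,
                    "median_total_intensity": res.median_total_intensity,
                },
                indent=2,
            )
        )

    (out / "provenance.json").write_text(
        json.dumps(
            {
                "config_hash": _config_hash(config),
                "seed": config.seed,
                "package_version": _pkg_version("arraytomo"),
                "stages": sorted(stages),
            },
            indent=2,
        )
    )
    return out
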