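import numpy as np
import pytest

from arraytomo.core import ChannelVolume, DataVolume, VoxelSize
from arraytomo.simulate import ChannelModel, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def demo_scene():
    """A small multichannel scene shared by read-only tests."""
    spec = SceneSpec(
        shape=(96, 96, 12),
        synapse_density=1.5,
        channels={
            "Synapsin1-1": ChannelModel(participation=0.95),
            "PSD95-1": ChannelModel(participation=0.85, offset_mean_nm=150.0, offset_sd_nm=30.0),
            "vGluT2-1": ChannelModel(participation=0.5),
            "DAPI-1": ChannelModel(kind="nuclei", amplitude_mean=30000.0, amplitude_sd=0.0),
        },
        nucleus_count=8,
        nucleus_radius_nm=1200.0,
        noise_sd=2000.0,
        seed=7,
    )
    return generate_scene(spec)


@pytest.fixture()
def small_volume():
    """A tiny two-channel integer volume with known contents."""
    rng = np.random.default_rng(11)
    a = rng.integers(0, 5000, size=(24, 20, 6)).astype(np.float64)
    b = rng.integers(0, 5000, size=(24, 20, 6)).astype(np.float64)
    voxel = VoxelSize(100, 100, 70)
    return DataVolume(
        "TestVol",
        [ChannelVolume("Synapsin1-2", a, voxel), ChannelVolume("PSD95-1", b, voxel)],
    )
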