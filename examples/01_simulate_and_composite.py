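"""Render a synthetic multichannel scene and make a false-color view.

Builds a small scene (synaptic channels + DAPI nuclei), saves it as an
HDF5 data volume, extracts an xy cutout, and writes an RGB composite
with Synapsin red, vGluT2 green, DAPI blue.
"""

from pathlib import Path

from arraytomo import io as atio
from arraytomo.core import cutout, mcfc_composite, physical_volume
from arraytomo.simulate import demo_spec, generate_scene

out_dir = Path("scratch/examples")
out_dir.mkdir(parents=True, exist_ok=True)

scene = generate_scene(demo_spec(seed=1))
vol = scene.rendered
nx, ny, nz = vol.shape
exact, rounded = physical_volume(nx, ny, nz, vol.voxel)

atio.save_hdf5(vol, out_dir / "scene.h5")
plane = cutout(vol, "DAPI-1", "xy", resolution=0, z_range=10)
atio.save_png(plane, out_dir / "dapi_section.png")
rgb = mcfc_composite(vol, ["0", "0", "0", "Synapsin1-1", "vGluT2-1", "DAPI-1"], "xy", z_range=10)
atio.save_png(rgb, out_dir / "composite.png")

print(f"scene: {nx}x{ny}x{nz} voxels = {rounded} um^3 ({exact:.1f} exact)")
print(f"planted synapse loci: {len(scene.loci)}")
print(f"rendered channels: {vol.channel_names}")
print(f"wrote {out_dir}/scene.h5, dapi_section.png, composite.png")
# The locus count is a Poisson draw with mean density x neuropil volume;
# the composite shows presynaptic (red) and thalamocortical (green)
# puncta over blue nuclei.
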