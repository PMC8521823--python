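"""Generate a synthetic spheroid section and inspect its ground truth.

The phantom emulates an equatorial section of a tumour spheroid: nuclei
scattered through a disk, hypoxia staining rising toward the core, a
necrotic centre, FUCCI cell-cycle zonation and infiltrating immune cells.
Every random draw is recorded, so downstream analyses can be scored.
"""

import numpy as np

from spheroquant import SpheroidPhantomParams, generate_phantom

params = SpheroidPhantomParams(seed=1)  # 300 um radius, 300 nuclei, 1 um/px
image, truth = generate_phantom(params)

print(f"canvas: {image.shape[0]} x {image.shape[1]} px, "
      f"channels: {', '.join(image.channel_names)}")
print(f"nuclei: {len(truth.nuclei)}, PBMCs: {len(truth.pbmc)}")

n = truth.nuclei
print(f"necrotic nuclei:      {int(n['necrotic'].sum())} "
      "(core of the spheroid, dim in the nuclear stain)")
print(f"DRAQ7+ (dead):        {int(n['draq7_positive'].sum())}")
print(f"mAG+ (cycling):       {int(n['mag_positive'].sum())} "
      f"- mean depth {n.loc[n['mag_positive'], 'depth_um'].mean():.0f} um")
print(f"mKO2+ (G1-arrested):  {int(n['mko2_positive'].sum())} "
      f"- mean depth {n.loc[n['mko2_positive'], 'depth_um'].mean():.0f} um")
print("cycling cells sit shallower than arrested ones: the generator "
      "builds in the radial oxygen/proliferation gradient.")

# determinism: the same parameters and seed give bit-identical output
image2, _ = generate_phantom(params)
same = all(
    np.array_equal(a.pixels, b.pixels)
    for a, b in zip(image.channels, image2.channels)
)
print(f"bit-identical on re-run with the same seed: {same}")
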