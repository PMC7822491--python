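"""Generate a synthetic liver-CT phantom and preprocess it for the networks.

Builds one 16-slice phantom volume (512x512 Hounsfield-unit slices with
nested liver/tumor ground truth), then windows it to [-100, 200] HU,
rescales to [0, 1] and downsamples to the 256x256 network resolution.
"""

import numpy as np

from sedseg import PhantomConfig, generate_volume, volume_to_slices

cfg = PhantomConfig(seed=42)
ct, gt = generate_volume(cfg)

print(f"phantom volume: {ct.voxels.shape} voxels, spacing {ct.spacing} mm")
print(f"HU range: [{ct.voxels.min():.0f}, {ct.voxels.max():.0f}]")
print(f"liver voxels: {int(gt.liver_mask.sum())}, tumor voxels: {int(gt.tumor_mask.sum())}")

samples = volume_to_slices(ct, gt)
tumorous = [s for s in samples if s.tumor_mask.any()]
print(f"preprocessed {len(samples)} slices at {samples[0].image.shape}, "
      f"{len(tumorous)} contain tumor")

s = tumorous[0]
liver_only = s.liver_mask & ~s.tumor_mask
print(f"slice {s.provenance[1]}: mean normalized intensity "
      f"liver {s.image[liver_only].mean():.3f} vs tumor {s.image[s.tumor_mask].mean():.3f}")
print("(tumors are hypodense: darker than surrounding parenchyma, which is "
      "what the stage-2 network exploits)")
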