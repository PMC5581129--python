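"""ΔqT1 subtraction map and seeded segmentation of enhancing tumor.

Fits pre- and post-contrast qT1 maps of one phantom, rescales the post map
so normal-appearing white matter matches the pre map, computes the percent
T1-shortening (ΔqT1) map, and grows the >50%-shortening tumor region from a
single seed, excluding the vessel that also enhances.
"""

import numpy as np

from qt1map import (
    PhantomSpec, build_phantom, delta_map, fit_map, nawm_scale, segment_enhancing,
)

bundle = build_phantom(PhantomSpec(noise_sigma=0.01, rng_seed=42))
pre = fit_map(bundle.ir_pre, mask=bundle.masks["brain"])
post = fit_map(bundle.ir_post, mask=bundle.masks["brain"])

scaled_post, scaling = nawm_scale(pre, post, bundle.masks["wm"])
print(f"NAWM scale factor: {scaling.scale_factor:.4f} "
      f"(pre median {scaling.wm_median_pre_ms:.0f} ms, post {scaling.wm_median_post_ms:.0f} ms)")

delta = delta_map(pre, scaled_post)
rim = bundle.masks["enhancing_rim"]
print(f"median ΔqT1 inside the true rim: {np.nanmedian(delta.data[rim]):.1f}% "
      f"(>50% = solid enhancement)")
print(f"median ΔqT1 in white matter:    {np.nanmedian(delta.data[bundle.masks['wm']]):.1f}%")

seed = tuple(np.argwhere(rim)[len(np.argwhere(rim)) // 2])
seg = segment_enhancing(delta, pre, scaled_post, seeds=[seed],
                        vessel_mask=bundle.masks["vessels"])
inter = int((seg.tumor_mask & rim).sum())
dice = 2.0 * inter / (int(seg.tumor_mask.sum()) + int(rim.sum()))
print(f"\nsegmented tumor: {int(seg.tumor_mask.sum())} voxels "
      f"(truth {int(rim.sum())}), Dice vs truth = {dice:.3f}")
print(f"subtle sub-threshold enhancement: {int(seg.subtle_mask.sum())} voxels")
print("Dice near 1 means the >50% rule separates solid tumor from the subtle band.")
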