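"""Build a digital glioma phantom and fit quantitative T1 maps.

Generates the default 64-voxel phantom (enhancing rim around a necrotic
core, subtle-enhancement band, edema, vessel, ventricle), simulates the
pre-contrast IR acquisition at SNR 100, fits the qT1 map, and compares the
fit against the phantom's exact truth per tissue.
"""

import numpy as np

from qt1map import PhantomSpec, build_phantom, fit_map

bundle = build_phantom(PhantomSpec(noise_sigma=0.01, rng_seed=42))
print(f"grid {bundle.label_map.shape}, brain voxels: {int(bundle.masks['brain'].sum())}")

t1_map = fit_map(bundle.ir_pre, mask=bundle.masks["brain"])
print(f"unconverged fraction: {t1_map.meta['unconverged_fraction']:.5f}")

print("\nper-tissue pre-contrast qT1 (fitted vs truth, ms):")
for name in ("wm", "gm", "edema", "subtle_band", "enhancing_rim", "necrosis", "csf"):
    mask = bundle.masks[name]
    fitted = float(np.nanmedian(t1_map.t1[mask]))
    truth = float(np.nanmedian(bundle.true_t1_pre[mask]))
    print(f"  {name:14s} fitted {fitted:7.0f}  truth {truth:7.0f}  "
          f"(median error {100 * abs(fitted - truth) / truth:.2f}%)")
print("\nEnhancing tumor sits at ~2600 ms, far above white matter (~950 ms) —")
print("the contrast the pre-contrast cutoff analysis exploits.")
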