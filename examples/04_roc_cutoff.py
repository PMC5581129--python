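"""ROC analysis: an optimal pre-contrast qT1 cutoff for detecting tumor.

Labels pre-contrast qT1 voxels as enhancing tumor vs. a 10 mm surrounding
band on one phantom, then sweeps every observed value as a candidate
"qT1 > t => tumor" cutoff and reports the Youden-optimal one with exact
binomial confidence intervals and the Hanley–McNeil AUC standard error.
"""

from qt1map import (
    PhantomSpec, build_phantom, build_samples, delta_map, fit_map, nawm_scale,
    roc_analysis, segment_enhancing,
)
import numpy as np

bundle = build_phantom(PhantomSpec(noise_sigma=0.01, rng_seed=42))
pre = fit_map(bundle.ir_pre, mask=bundle.masks["brain"])
post = fit_map(bundle.ir_post, mask=bundle.masks["brain"])
scaled_post, _ = nawm_scale(pre, post, bundle.masks["wm"])
delta = delta_map(pre, scaled_post)
rim_voxels = np.argwhere(bundle.masks["enhancing_rim"])
seg = segment_enhancing(delta, pre, scaled_post,
                        seeds=[tuple(rim_voxels[len(rim_voxels) // 2])],
                        vessel_mask=bundle.masks["vessels"])

samples = build_samples(pre, seg.tumor_mask, bundle.masks["brain"],
                        vessel_mask=bundle.masks["vessels"], band_width_mm=10.0)
print(f"samples: {(samples['label'] == 'tumor').sum()} tumor, "
      f"{(samples['label'] == 'surround').sum()} surround voxels")

roc = roc_analysis(samples)
print(f"\noptimal cutoff:  qT1 > {roc.optimal_cutoff_ms:.0f} ms")
print(f"sensitivity:     {100 * roc.sens_at_cutoff:.1f}% "
      f"(95% CI {100 * roc.sens_ci[0]:.1f}–{100 * roc.sens_ci[1]:.1f}%)")
print(f"specificity:     {100 * roc.spec_at_cutoff:.1f}% "
      f"(95% CI {100 * roc.spec_ci[0]:.1f}–{100 * roc.spec_ci[1]:.1f}%)")
print(f"AUC:             {100 * roc.auc:.1f}% ± {100 * roc.auc_se:.1f}%  (p = {roc.p_value:.2e})")
print("\nThe cutoff lands in the gap between the surround ceiling (<2000 ms)")
print("and the tumor floor (2100 ms) built into the phantom truth.")
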