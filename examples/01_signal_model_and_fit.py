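"""The inversion-recovery signal model and voxel-wise T1 fitting.

Evaluates the steady-state magnitude IR model at the five-point clinical TI
schedule (150/350/750/1200/2300 ms, shot interval 3000 ms, perfect inversion
F=2), then refits noiseless and noisy signal vectors to show what the
estimator recovers.
"""

import numpy as np

from qt1map import AcquisitionParams, fit_voxel, ir_signal
from qt1map.phantom import rician

acq = AcquisitionParams()
print(f"TI schedule (ms): {acq.inversion_delays_ms}, SI={acq.shot_interval_ms}, F={acq.inversion_factor}")

print("\nSignal magnitudes for white-matter-like T1 = 950 ms (M0 = 1):")
for ti in acq.inversion_delays_ms:
    print(f"  TI {ti:6.0f} ms -> |S| = {ir_signal(ti, 950.0):.4f}")
print("The dip near TI = T1*ln2 is the inversion null the magnitude model folds upward.")

print("\nNoiseless round trips (generate at T1, refit):")
for t1 in (500.0, 950.0, 2051.0, 4000.0):
    fit = fit_voxel(ir_signal(acq.tis, t1, 1.0), acq)
    print(f"  true {t1:6.0f} ms -> fitted {fit.t1_ms:8.2f} ms (converged={fit.converged})")

rng = np.random.default_rng(0)
noisy = rician(ir_signal(acq.tis, 950.0, 1.0), 0.01, rng)
fit = fit_voxel(noisy, acq)
print(f"\nOne noisy voxel at SNR 100 (T1=950): fitted {fit.t1_ms:.1f} ms, rss {fit.rss:.2e}")
print("Single-voxel scatter at this SNR is ~1%; maps average this out spatially.")
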