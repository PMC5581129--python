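"""Shared fixtures: small, fast phantoms and their fitted maps.

The small geometry scales the default anatomy down to a 32-voxel grid so a
whole-brain fit takes under a second; geometry proportions (necrotic core
inside an enhancing rim, subtle band, edema shell, tangent vessel) are
preserved.
"""

import numpy as np
import pytest

from qt1map import (
    PhantomGeometry,
    PhantomSpec,
    build_phantom,
    fit_map,
    nawm_scale,
)


def small_geometry() -> PhantomGeometry:
    return PhantomGeometry(
        brain_radius=13.0,
        gm_thickness=2.0,
        ventricle_center=(-4.0, -1.0, 0.0),
        ventricle_radius=2.0,
        tumor_center=(4.0, 1.0, 0.0),
        necrosis_radius=2.0,
        rim_outer_radius=4.5,
        subtle_outer_radius=5.5,
        edema_outer_radius=7.0,
        vessel_axis_xy=(8.0, 1.0),
        vessel_radius=1.0,
        vessel_half_length=6.0,
    )


def small_spec(noise_sigma: float = 0.01, rng_seed: int = 7) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        geometry=small_geometry(),
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    return build_phantom(small_spec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_bundle():
    return build_phantom(small_spec(noise_sigma=0.01))


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_bundle):
    b = noiseless_bundle
    t1_pre = fit_map(b.ir_pre, mask=b.masks["brain"])
    t1_post = fit_map(b.ir_post, mask=b.masks["brain"])
    scaled_post, scaling = nawm_scale(t1_pre, t1_post, b.masks["wm"])
    return {"pre": t1_pre, "post": t1_post, "post_scaled": scaled_post, "scaling": scaling}


@pytest.fixture(scope="session")
def noisy_maps(noisy_bundle):
    b = noisy_bundle
    t1_pre = fit_map(b.ir_pre, mask=b.masks["brain"])
    t1_post = fit_map(b.ir_post, mask=b.masks["brain"])
    scaled_post, scaling = nawm_scale(t1_pre, t1_post, b.masks["wm"])
    return {"pre": t1_pre, "post": t1_post, "post_scaled": scaled_post, "scaling": scaling}


def rim_seed(bundle) -> tuple[int, int, int]:
    """A deterministic voxel near the centroid of the true enhancing rim."""
    idx = np.argwhere(bundle.masks["enhancing_rim"])
    center = idx.mean(axis=0)
    best = idx[np.argmin(((idx - center) ** 2).sum(axis=1))]
    return tuple(int(c) for c in best)
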