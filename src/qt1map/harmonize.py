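"""Cross-acquisition harmonization of qT1 maps.

Absolute qT1 values can drift between the pre- and post-contrast
acquisitions (scanner calibration, coil loading).  Normal-appearing white
matter (NAWM) does not enhance, so its qT1 should be identical before and
after contrast; the post map is rescaled so the NAWM median matches the pre
map.  The median is used rather than the mean so that stray enhancing or
vessel voxels inside the supplied WM mask cannot bias the factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, GridMismatchError, ParameterError
from .relaxometry import T1Map

__all__ = ["ScalingResult", "nawm_scale", "assert_coregistered"]


@dataclass(frozen=True)
class ScalingResult:
    """Outcome of matching post-contrast NAWM qT1 to the pre-contrast map."""

    scale_factor: float
    wm_median_pre_ms: float
    wm_median_post_ms: float
    n_wm_voxels: int

    def as_dict(self) -> dict:
        return {
            "scale_factor": self.scale_factor,
            "wm_median_pre_ms": self.wm_median_pre_ms,
            "wm_median_post_ms": self.wm_median_post_ms,
            "n_wm_voxels": self.n_wm_voxels,
        }


def _shape_affine(vol):
    """Duck-typed (shape, affine) of an ndarray, map object, or nibabel image."""
    affine = getattr(vol, "affine", None)
    if hasattr(vol, "shape"):
        return tuple(vol.shape), affine
    raise ParameterError(f"cannot interpret {type(vol).__name__} as a volume")


def assert_coregistered(*volumes, atol: float = 1e-4) -> None:
    """Verify that all volumes share a grid: identical shapes, matching affines.

    Registration itself is out of scope for this package — inputs are assumed
    already resampled to one grid; this guard enforces that assumption before
    any voxel-wise operation.
    """
    if len(volumes) < 2:
        raise ParameterError("assert_coregistered needs at least two volumes")
    shapes_affines = [_shape_affine(v) for v in volumes]
    ref_shape, ref_affine = shapes_affines[0]
    problems = []
    for i, (shape, affine) in enumerate(shapes_affines[1:], start=1):
        if shape != ref_shape:
            problems.append(f"volume {i}: shape {shape} != volume 0 shape {ref_shape}")
        if affine is not None and ref_affine is not None and not np.allclose(affine, ref_affine, atol=atol):
            diff = float(np.max(np.abs(np.asarray(affine) - np.asarray(ref_affine))))
            problems.append(f"volume {i}: affine differs from volume 0 (max abs diff {diff:.3g})")
    if problems:
        raise GridMismatchError("volumes are not coregistered: " + "; ".join(problems))


def nawm_scale(
    t1_pre: T1Map,
    t1_post: T1Map,
    wm_mask: np.ndarray,
    min_wm_voxels: int = 100,
) -> tuple[T1Map, ScalingResult]:
    """Rescale the post-contrast map so NAWM medians match the pre map.

    ``scale_factor = median(pre qT1 in WM) / median(post qT1 in WM)``; after
    scaling the two WM medians agree exactly.  Only voxels with converged
    fits in *both* maps contribute.
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    assert_coregistered(t1_pre, t1_post, wm_mask if wm_mask.ndim == 3 else wm_mask)
    if wm_mask.shape != t1_pre.shape:
        raise GridMismatchError(f"WM mask shape {wm_mask.shape} != map shape {t1_pre.shape}")

    usable = wm_mask & np.isfinite(t1_pre.t1) & np.isfinite(t1_post.t1)
    n = int(usable.sum())
    if n < min_wm_voxels:
        raise AnalysisError(
            f"only {n} usable NAWM voxels (minimum {min_wm_voxels}); "
            "supply a larger white-matter mask"
        )
    med_pre = float(np.median(t1_pre.t1[usable]))
    med_post = float(np.median(t1_post.t1[usable]))
    if med_post <= 0:
        raise AnalysisError("non-positive NAWM median in the post-contrast map")
    factor = med_pre / med_post
    scaled = t1_post.scaled(factor)
    return scaled, ScalingResult(factor, med_pre, med_post, n)
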