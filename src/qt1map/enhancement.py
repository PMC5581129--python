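"""ΔqT1 subtraction maps and segmentation of contrast-enhancing tumor.

Gadolinium shortens T1 wherever the blood-brain barrier leaks, so the
voxel-wise percent change between coregistered pre- and post-contrast qT1
maps,

    ΔqT1 = 100 * |T1_pre - T1_post| / T1_pre ,

lights up enhancing tissue.  Solid enhancing tumor is defined as the
connected region(s), grown from user-placed seeds, in which T1 shortened by
more than 50 % (strict inequality; the absolute value in the formula means a
T1 *increase* would also score high, so segmentation additionally requires
post < pre).  Vessels also enhance strongly and are removed with an explicit
vessel mask.  A surrounding band of "subtle" sub-threshold enhancement
(default 15-50 % shortening) is reported alongside.

Region growing is deterministic: the 26-connected components of the
threshold predicate that contain the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, ParameterError, SeedError
from .harmonize import assert_coregistered
from .relaxometry import T1Map

__all__ = ["DeltaMap", "EnhancementSegmentation", "delta_map", "segment_enhancing"]


@dataclass
class DeltaMap:
    """Voxel-wise percent T1 change pre -> post contrast (NaN where unfitted)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class EnhancementSegmentation:
    """Solid enhancing tumor plus the surrounding subtle-enhancement band."""

    tumor_mask: np.ndarray
    subtle_mask: np.ndarray
    seeds: list[tuple[int, int, int]]
    threshold_percent: float
    subtle_lower_percent: float
    vessel_mask: np.ndarray | None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def delta_map(t1_pre: T1Map, t1_post_scaled: T1Map) -> DeltaMap:
    """Compute the percent-change subtraction map from coregistered qT1 maps.

    NaN (unfitted) voxels in either parent propagate to the result; values
    are >= 0 by construction of the absolute-value formula.
    """
    assert_coregistered(t1_pre, t1_post_scaled)
    pre = t1_pre.t1
    post = t1_post_scaled.t1
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = 100.0 * np.abs(pre - post) / pre
    delta = np.where(np.isfinite(pre) & np.isfinite(post) & (pre > 0), delta, np.nan)
    return DeltaMap(
        data=delta,
        affine=t1_pre.affine.copy(),
        meta={
            "pre": t1_pre.meta.get("source", "pre"),
            "post": t1_post_scaled.meta.get("source", "post"),
            "post_scale_factor": t1_post_scaled.meta.get("scale_factor", 1.0),
        },
    )


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_enhancing(
    delta: DeltaMap,
    t1_pre: T1Map,
    t1_post_scaled: T1Map,
    seeds,
    threshold_percent: float = 50.0,
    vessel_mask: np.ndarray | None = None,
    subtle_lower_percent: float = 15.0,
) -> EnhancementSegmentation:
    """Grow the solid enhancing-tumor mask from seed voxels.

    A voxel belongs to the inclusion predicate iff ``ΔqT1 > threshold`` (strict)
    and ``post < pre`` (true shortening).  The tumor mask is the union of the
    26-connected components of that predicate containing the seeds, minus the
    vessel mask.  Every seed must itself satisfy the predicate.
    """
    if not (0.0 < threshold_percent < 100.0):
        raise ParameterError(f"threshold must lie in (0, 100) percent, got {threshold_percent}")
    if not (0.0 <= subtle_lower_percent < threshold_percent):
        raise ParameterError("subtle lower bound must lie in [0, threshold)")
    assert_coregistered(delta, t1_pre, t1_post_scaled)
    if vessel_mask is not None:
        vessel_mask = np.asarray(vessel_mask).astype(bool)
        if vessel_mask.shape != delta.shape:
            raise GridMismatchError(f"vessel mask shape {vessel_mask.shape} != map shape {delta.shape}")

    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ParameterError("at least one seed voxel is required")

    with np.errstate(invalid="ignore"):
        shortening = t1_post_scaled.t1 < t1_pre.t1
        predicate = (delta.data > threshold_percent) & shortening

    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, delta.shape)):
            raise SeedError(f"seed {s} lies outside the volume {delta.shape}")
        if not predicate[s]:
            raise SeedError(
                f"seed {s} fails the inclusion predicate "
                f"(ΔqT1 = {delta.data[s]:.1f}%, threshold {threshold_percent}%)"
            )

    labels, _ = ndimage.label(predicate, structure=_STRUCT_26)
    keep = {labels[s] for s in seeds}
    tumor = np.isin(labels, sorted(keep))
    if vessel_mask is not None:
        tumor &= ~vessel_mask

    with np.errstate(invalid="ignore"):
        subtle = (
            (delta.data > subtle_lower_percent)
            & (delta.data <= threshold_percent)
            & shortening
            & ~tumor
        )
    if vessel_mask is not None:
        subtle &= ~vessel_mask

    return EnhancementSegmentation(
        tumor_mask=tumor,
        subtle_mask=subtle,
        seeds=seeds,
        threshold_percent=threshold_percent,
        subtle_lower_percent=subtle_lower_percent,
        vessel_mask=vessel_mask,
        affine=delta.affine.copy(),
    )
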