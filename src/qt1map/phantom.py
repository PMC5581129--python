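"""Digital glioma phantoms with known ground truth.

The phantom emulates a recurrent high-grade glioma on an isotropic 3 T
acquisition grid: a spherical brain with a cortical grey-matter shell, a
ventricle (CSF), a tumor built from a necrotic core inside a solid
contrast-enhancing rim, a surrounding band of subtle (sub-threshold)
enhancement, a peritumoral edema shell, and a vessel tube running tangent to
the rim.  Every voxel's true pre- and post-contrast T1 is drawn from its
tissue's distribution, so the >50 % shortening rule separates the rim from
everything else *by construction* and downstream stages can be scored
against exact truth masks.

Contrast-agent uptake is modelled as a multiplicative T1 shortening factor
per tissue (rim 0.35, subtle band 0.75, vessels 0.2, all else ~1.0); the
acquisition itself is the single-excitation steady-state IR model of
:mod:`qt1map.relaxometry` with Rician magnitude noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigurationError, ParameterError
from .relaxometry import AcquisitionParams, IRSeries, T1Map, ir_signal

__all__ = [
    "TissueParams",
    "PhantomGeometry",
    "PhantomSpec",
    "PhantomBundle",
    "build_phantom",
    "simulate_ir_series",
    "apply_global_drift",
    "rician",
]

#: label-map integer codes; higher precedence tissues are painted last
TISSUE_LABELS = {
    "csf": 1,
    "wm": 2,
    "gm": 3,
    "edema": 4,
    "subtle_band": 5,
    "enhancing_rim": 6,
    "necrosis": 7,
    "vessels": 8,
}

#: painting order = precedence (later wins): vessels > necrosis > rim >
#: subtle band > edema > GM > WM > CSF
PRECEDENCE = ["csf", "wm", "gm", "edema", "subtle_band", "enhancing_rim", "necrosis", "vessels"]

ENHANCING_TISSUES = {"enhancing_rim", "subtle_band", "vessels"}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue generative parameters.

    ``pre_t1_dist`` is ``"normal"`` (mean/sd, truncated at > 50 ms) or
    ``"uniform"`` over [pre_t1_low_ms, pre_t1_high_ms].  The post-contrast T1
    is the pre value times a factor drawn from N(post_t1_factor_mean, sd),
    truncated to (0, 1.5].
    """

    label: str
    pre_t1_mean_ms: float
    pre_t1_sd_ms: float
    post_t1_factor_mean: float
    post_t1_factor_sd: float
    proton_density: float
    pre_t1_dist: str = "normal"
    pre_t1_low_ms: float | None = None
    pre_t1_high_ms: float | None = None


def _default_tissues() -> dict[str, TissueParams]:
    return {
        "wm": TissueParams("wm", 950.0, 50.0, 1.0, 0.01, 0.75),
        "gm": TissueParams("gm", 1450.0, 70.0, 1.0, 0.01, 0.85),
        "csf": TissueParams("csf", 4000.0, 200.0, 1.0, 0.01, 1.0),
        "edema": TissueParams("edema", 1750.0, 75.0, 1.0, 0.01, 0.90),
        # infiltrative margin: qT1 fills the range between edema and the
        # 2000 ms surroundings ceiling, just below the solid-tumor floor
        "subtle_band": TissueParams(
            "subtle_band", 1922.5, 0.0, 0.75, 0.02, 0.90,
            pre_t1_dist="uniform", pre_t1_low_ms=1850.0, pre_t1_high_ms=1995.0,
        ),
        "enhancing_rim": TissueParams(
            "enhancing_rim", 2600.0, 0.0, 0.35, 0.03, 0.90,
            pre_t1_dist="uniform", pre_t1_low_ms=2100.0, pre_t1_high_ms=3100.0,
        ),
        "necrosis": TissueParams("necrosis", 1300.0, 75.0, 1.0, 0.02, 0.80),
        "vessels": TissueParams("vessels", 1700.0, 50.0, 0.20, 0.02, 0.90),
    }


@dataclass(frozen=True)
class PhantomGeometry:
    """Centers (voxel units, relative to grid center) and radii (mm)."""

    brain_radius: float = 28.0
    gm_thickness: float = 3.0
    ventricle_center: tuple[float, float, float] = (-8.0, -2.0, 0.0)
    ventricle_radius: float = 4.0
    tumor_center: tuple[float, float, float] = (8.0, 2.0, 0.0)
    necrosis_radius: float = 4.0
    rim_outer_radius: float = 9.0
    subtle_outer_radius: float = 11.0
    edema_outer_radius: float = 16.0
    vessel_axis_xy: tuple[float, float] = (16.0, 2.0)
    vessel_radius: float = 1.6
    vessel_half_length: float = 14.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; validated on construction."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissues)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    noise_sigma: float = 0.01
    rng_seed: int = 0
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 axes of >= 8 voxels, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel size must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        for name, tp in self.tissue_params.items():
            if tp.pre_t1_dist == "normal" and tp.pre_t1_mean_ms <= 0:
                raise ConfigurationError(f"{name}: T1 mean must be positive")
            if tp.pre_t1_dist == "uniform" and (tp.pre_t1_low_ms is None or tp.pre_t1_high_ms is None):
                raise ConfigurationError(f"{name}: uniform T1 needs low/high bounds")
            if not (0.0 < tp.post_t1_factor_mean <= 1.5):
                raise ConfigurationError(f"{name}: post-contrast T1 factor must lie in (0, 1.5]")
            if name == "enhancing_rim" and tp.post_t1_factor_mean >= 0.5:
                raise ConfigurationError(
                    "enhancing rim factor mean must be < 0.5 so true shortening exceeds 50%"
                )
            if name not in ENHANCING_TISSUES and not (0.95 <= tp.post_t1_factor_mean <= 1.05):
                raise ConfigurationError(
                    f"{name}: non-enhancing tissue factor mean must lie in [0.95, 1.05]"
                )
        g = self.geometry
        half_extent = min(self.grid_shape) / 2.0 * self.voxel_size_mm
        if g.brain_radius >= half_extent:
            raise ConfigurationError("brain does not fit inside the grid")
        for label, c, r in [
            ("ventricle", g.ventricle_center, g.ventricle_radius),
            ("edema", g.tumor_center, g.edema_outer_radius),
        ]:
            if np.linalg.norm(c) + r > g.brain_radius:
                raise ConfigurationError(f"{label} region extends outside the brain")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["acq"] = {
            "inversion_delays_ms": list(self.acq.inversion_delays_ms),
            "shot_interval_ms": self.acq.shot_interval_ms,
            "inversion_factor": self.acq.inversion_factor,
        }
        return d


@dataclass
class PhantomBundle:
    """Everything a downstream stage may need, with exact ground truth."""

    label_map: np.ndarray
    true_t1_pre: np.ndarray
    true_t1_post: np.ndarray
    proton_density: np.ndarray
    masks: dict[str, np.ndarray]
    ir_pre: IRSeries
    ir_post: IRSeries
    affine: np.ndarray
    truth_manifest: dict

    def true_delta_percent(self) -> np.ndarray:
        """Ground-truth percent T1 change, NaN outside the brain."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.abs(self.true_t1_pre - self.true_t1_post) / self.true_t1_pre

    def truth_t1_map(self, which: str = "pre") -> T1Map:
        """Wrap a truth volume as a T1Map (for oracle-style tests)."""
        t1 = self.true_t1_pre if which == "pre" else self.true_t1_post
        conv = np.isfinite(t1)
        return T1Map(
            t1=t1.copy(), m0=self.proton_density.copy(),
            rss=np.zeros_like(t1), converged=conv, affine=self.affine.copy(),
            meta={"source": f"phantom-truth-{which}"},
        )


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    return aff


def _coords_mm(shape, voxel_mm: float):
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _paint_labels(spec: PhantomSpec) -> np.ndarray:
    g = spec.geometry
    x, y, z = _coords_mm(spec.grid_shape, spec.voxel_size_mm)

    def sphere(center, radius):
        cx, cy, cz = center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2

    brain = sphere((0, 0, 0), g.brain_radius)
    ventricle = sphere(g.ventricle_center, g.ventricle_radius)
    regions = {
        "csf": ventricle,
        # WM claims the deep brain *except* the ventricle (CSF has the lowest
        # paint precedence, so the ventricle must be carved out of WM here)
        "wm": sphere((0, 0, 0), g.brain_radius - g.gm_thickness) & ~ventricle,
        "gm": brain & ~sphere((0, 0, 0), g.brain_radius - g.gm_thickness),
        "edema": sphere(g.tumor_center, g.edema_outer_radius),
        "subtle_band": sphere(g.tumor_center, g.subtle_outer_radius),
        "enhancing_rim": sphere(g.tumor_center, g.rim_outer_radius),
        "necrosis": sphere(g.tumor_center, g.necrosis_radius),
        "vessels": (
            ((x - g.vessel_axis_xy[0]) ** 2 + (y - g.vessel_axis_xy[1]) ** 2 <= g.vessel_radius**2)
            & (np.abs(z) <= g.vessel_half_length)
        ),
    }
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for name in PRECEDENCE:
        region = regions[name] & brain
        labels[region] = TISSUE_LABELS[name]
    return labels


def _draw_pre_t1(tp: TissueParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if tp.pre_t1_dist == "uniform":
        return rng.uniform(tp.pre_t1_low_ms, tp.pre_t1_high_ms, size=n)
    if tp.pre_t1_sd_ms == 0:
        return np.full(n, tp.pre_t1_mean_ms)
    a = (50.0 - tp.pre_t1_mean_ms) / tp.pre_t1_sd_ms  # truncate at > 50 ms
    return truncnorm.rvs(a, np.inf, loc=tp.pre_t1_mean_ms, scale=tp.pre_t1_sd_ms, size=n, random_state=rng)


def _draw_factor(tp: TissueParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if tp.post_t1_factor_sd == 0:
        return np.full(n, tp.post_t1_factor_mean)
    a = (1e-6 - tp.post_t1_factor_mean) / tp.post_t1_factor_sd
    b = (1.5 - tp.post_t1_factor_mean) / tp.post_t1_factor_sd
    return truncnorm.rvs(a, b, loc=tp.post_t1_factor_mean, scale=tp.post_t1_factor_sd, size=n, random_state=rng)


def rician(amplitude: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex Gaussian measurement with true amplitude A.

    For A = 0 the mean magnitude is sigma * sqrt(pi/2) (Rayleigh floor).
    """
    if sigma == 0:
        return np.abs(amplitude)
    re = amplitude + rng.normal(0.0, sigma, size=amplitude.shape)
    im = rng.normal(0.0, sigma, size=amplitude.shape)
    return np.hypot(re, im)


def simulate_ir_series(
    true_t1: np.ndarray,
    proton_density: np.ndarray,
    acq: AcquisitionParams,
    noise_sigma: float,
    rng_seed: int,
    affine: np.ndarray | None = None,
) -> IRSeries:
    """Forward-simulate the magnitude IR acquisition of a truth T1 volume.

    Voxels with NaN T1 or zero proton density contribute zero true amplitude
    (pure noise floor).  ``noise_sigma`` is on the scale of M0 = 1.
    """
    if noise_sigma < 0:
        raise ParameterError("noise sigma must be non-negative")
    t1 = np.asarray(true_t1, dtype=float)
    pd = np.asarray(proton_density, dtype=float)
    rng = np.random.default_rng(rng_seed)
    valid = np.isfinite(t1) & (t1 > 0) & (pd > 0)
    t1_safe = np.where(valid, t1, 1000.0)

    vols = []
    for ti in acq.inversion_delays_ms:
        amp = ir_signal(ti, t1_safe, pd, acq.inversion_factor, acq.shot_interval_ms)
        amp = np.where(valid, amp, 0.0)
        vols.append(rician(amp, noise_sigma, rng))
    data = np.stack(vols, axis=-1)
    if affine is None:
        affine = np.eye(4)
    return IRSeries(data=data, acq=acq, affine=np.asarray(affine, dtype=float),
                    meta={"noise_sigma": noise_sigma, "rng_seed": rng_seed})


def build_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate truth maps, masks, and the pre/post IR acquisitions.

    Deterministic for a fixed ``spec.rng_seed``: one seed sequence is split
    into independent streams for the truth draw and the two noise
    realizations, and the seeds used are echoed in the truth manifest.
    """
    labels = _paint_labels(spec)
    affine = _centered_affine(spec.grid_shape, spec.voxel_size_mm)

    ss = np.random.SeedSequence(spec.rng_seed)
    truth_seed, pre_seed, post_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    rng = np.random.default_rng(truth_seed)

    t1_pre = np.full(spec.grid_shape, np.nan)
    t1_post = np.full(spec.grid_shape, np.nan)
    pd = np.zeros(spec.grid_shape)
    # tissue order fixed by PRECEDENCE so draws are reproducible
    for name in PRECEDENCE:
        tp = spec.tissue_params[name]
        sel = labels == TISSUE_LABELS[name]
        n = int(sel.sum())
        if n == 0:
            continue
        pre = _draw_pre_t1(tp, n, rng)
        factor = _draw_factor(tp, n, rng)
        t1_pre[sel] = pre
        t1_post[sel] = pre * factor
        pd[sel] = tp.proton_density

    masks = {name: labels == code for name, code in TISSUE_LABELS.items()}
    masks["brain"] = labels > 0

    ir_pre = simulate_ir_series(t1_pre, pd, spec.acq, spec.noise_sigma, pre_seed, affine)
    ir_post = simulate_ir_series(t1_post, pd, spec.acq, spec.noise_sigma, post_seed, affine)

    manifest = {
        "spec": spec.manifest(),
        "rng_seed": spec.rng_seed,
        "derived_seeds": {"truth": truth_seed, "ir_pre": pre_seed, "ir_post": post_seed},
        "tissue_labels": dict(TISSUE_LABELS),
    }
    return PhantomBundle(
        label_map=labels,
        true_t1_pre=t1_pre,
        true_t1_post=t1_post,
        proton_density=pd,
        masks=masks,
        ir_pre=ir_pre,
        ir_post=ir_post,
        affine=affine,
        truth_manifest=manifest,
    )


def apply_global_drift(obj, factor: float):
    """Multiply a volume, T1 map, or IR series by a global factor.

    Emulates scanner-level scale drift between the pre- and post-contrast
    acquisitions; the NAWM harmonization stage exists to undo exactly this.
    """
    if factor <= 0:
        raise ParameterError(f"drift factor must be positive, got {factor}")
    if isinstance(obj, T1Map):
        return obj.scaled(factor)
    if isinstance(obj, IRSeries):
        meta = dict(obj.meta)
        meta["drift_factor"] = factor * meta.get("drift_factor", 1.0)
        return dataclasses.replace(obj, data=obj.data * factor, meta=meta)
    return np.asarray(obj, dtype=float) * factor
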