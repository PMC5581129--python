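"""Voxel-wise quantitative T1 (qT1) mapping from magnitude inversion-recovery MRI.

The signal model is the steady-state inversion-recovery expression for a
magnitude readout with inversion factor ``F`` and a finite shot interval
``SI`` (incomplete longitudinal relaxation between shots):

    S(TI) = M0 * | 1 - F * exp(-TI/T1) + (F - 1) * exp(-SI/T1) |

``F = 2`` is a perfect inversion; ``F -> 1`` a saturation pulse.  Because the
magnitude is taken, the model is fitted directly in absolute value (no
polarity restoration), which is robust for the short five-point TI schedules
used clinically.

Two fitting routes are provided:

* :func:`fit_voxel` — multi-start bounded least squares on a single signal
  vector (the reference implementation).
* :func:`fit_map` — a vectorized solver for whole volumes.  For fixed T1 the
  model is linear in M0, so M0 is profiled out in closed form and T1 found by
  a dense log-grid search with iterative bracket refinement.  The two routes
  agree to well below the noise floor (tested).

Unfitted or unconverged voxels carry NaN, never 0: 0 ms would be a
plausible-looking relaxation time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import GridMismatchError, ParameterError

__all__ = [
    "AcquisitionParams",
    "IRSeries",
    "VoxelFit",
    "T1Map",
    "ir_signal",
    "fit_voxel",
    "fit_map",
]

#: Default inversion delays (ms) of the five-point 3 T IR-TFE protocol.
DEFAULT_TIS_MS = (150.0, 350.0, 750.0, 1200.0, 2300.0)

T1_BOUNDS_MS = (50.0, 8000.0)
T1_STARTS_MS = (300.0, 800.0, 1500.0, 2500.0, 4000.0)

#: a fit only counts as converged if the model explains >= 95% of the signal
#: energy; degenerate inputs (e.g. a constant vector) otherwise "succeed" at
#: interior local minima with enormous residuals
MAX_REL_RSS = 0.05


@dataclass(frozen=True)
class AcquisitionParams:
    """Constants of the inversion-recovery acquisition.

    Parameters
    ----------
    inversion_delays_ms:
        Strictly increasing inversion delays (TI), one per acquired volume.
    shot_interval_ms:
        Time between successive inversion shots (SI); every TI must be < SI.
    inversion_factor:
        Inversion-pulse efficiency F in (1, 2]; 2.0 is a perfect inversion.
    """

    inversion_delays_ms: tuple[float, ...] = DEFAULT_TIS_MS
    shot_interval_ms: float = 3000.0
    inversion_factor: float = 2.0

    def __post_init__(self) -> None:
        tis = tuple(float(t) for t in self.inversion_delays_ms)
        object.__setattr__(self, "inversion_delays_ms", tis)
        if len(tis) < 2:
            raise ParameterError("need at least two inversion delays")
        if any(t2 <= t1 for t1, t2 in zip(tis, tis[1:])):
            raise ParameterError(f"inversion delays must be strictly increasing, got {tis}")
        if tis[0] < 0:
            raise ParameterError("inversion delays must be non-negative")
        if any(t >= self.shot_interval_ms for t in tis):
            raise ParameterError(
                f"every TI must be < SI={self.shot_interval_ms} ms "
                f"(recovery interval would be negative), got TIs {tis}"
            )
        if not (1.0 < self.inversion_factor <= 2.0):
            raise ParameterError(f"inversion factor F must lie in (1, 2], got {self.inversion_factor}")

    @property
    def tis(self) -> np.ndarray:
        return np.asarray(self.inversion_delays_ms, dtype=float)


@dataclass
class IRSeries:
    """A 4-D stack of magnitude volumes, one per inversion delay.

    ``data`` has shape ``(*grid_shape, n_TI)`` with the last axis in the
    order of ``acq.inversion_delays_ms``.
    """

    data: np.ndarray
    acq: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError(f"IR series must be 4-D, got shape {self.data.shape}")
        if self.data.shape[-1] != len(self.acq.inversion_delays_ms):
            raise ParameterError(
                f"series has {self.data.shape[-1]} volumes but "
                f"{len(self.acq.inversion_delays_ms)} inversion delays"
            )
        if np.nanmin(self.data) < 0:
            raise ParameterError("magnitude data must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid_shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class VoxelFit:
    """Result of fitting one voxel's IR signal vector."""

    t1_ms: float
    m0: float
    rss: float
    converged: bool


@dataclass
class T1Map:
    """A fitted qT1 volume (ms) with companion maps.

    NaN marks voxels that were outside the fit mask or failed to converge.
    """

    t1: np.ndarray
    m0: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    acq: AcquisitionParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape

    @property
    def data(self) -> np.ndarray:
        return self.t1

    def scaled(self, factor: float) -> "T1Map":
        """Return a copy with T1 multiplied by ``factor`` (recorded in meta)."""
        if factor <= 0:
            raise ParameterError(f"scale factor must be positive, got {factor}")
        meta = dict(self.meta)
        meta["scale_factor"] = factor * meta.get("scale_factor", 1.0)
        return dataclasses.replace(self, t1=self.t1 * factor, meta=meta)


def ir_signal(ti_ms, t1_ms, m0=1.0, inversion_factor: float = 2.0, shot_interval_ms: float = 3000.0):
    """Magnitude IR steady-state signal; vectorized over all arguments.

    Returns ``M0 * |1 - F e^(-TI/T1) + (F-1) e^(-SI/T1)|``.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ParameterError("T1 must be positive")
    ti = np.asarray(ti_ms, dtype=float)
    f = inversion_factor
    mz = 1.0 - f * np.exp(-ti / t1) + (f - 1.0) * np.exp(-shot_interval_ms / t1)
    return np.asarray(m0, dtype=float) * np.abs(mz)


def _residuals(params: np.ndarray, signals: np.ndarray, tis: np.ndarray, f: float, si: float) -> np.ndarray:
    t1, m0 = params
    return ir_signal(tis, t1, m0, f, si) - signals


def fit_voxel(
    signals: Sequence[float],
    acq: AcquisitionParams,
    t1_starts: Sequence[float] = T1_STARTS_MS,
    t1_bounds: tuple[float, float] = T1_BOUNDS_MS,
) -> VoxelFit:
    """Fit (T1, M0) to one signal vector by multi-start bounded least squares.

    The absolute-value model has local minima near the null point, hence the
    multi-start over a coarse T1 grid.  All-zero signals yield an unconverged
    sentinel result rather than an exception.
    """
    s = np.asarray(signals, dtype=float)
    tis = acq.tis
    if s.shape != tis.shape:
        raise ParameterError(f"expected {tis.size} signals, got {s.size}")
    smax = float(np.max(s)) if s.size else 0.0
    if not np.all(np.isfinite(s)) or smax <= 0.0:
        return VoxelFit(np.nan, np.nan, 0.0, False)

    best = None
    m0_init = 1.2 * smax
    for t1_0 in t1_starts:
        try:
            res = least_squares(
                _residuals,
                x0=[t1_0, m0_init],
                bounds=([t1_bounds[0], 1e-12], [t1_bounds[1], np.inf]),
                args=(s, tis, acq.inversion_factor, acq.shot_interval_ms),
                xtol=1e-12,
                ftol=1e-10,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return VoxelFit(np.nan, np.nan, np.nan, False)

    t1_hat, m0_hat = best.x
    rss = 2.0 * best.cost
    at_bound = (
        t1_hat <= t1_bounds[0] * (1 + 1e-6)
        or t1_hat >= t1_bounds[1] * (1 - 1e-6)
        or m0_hat <= 1e-9 * smax
    )
    poor_fit = rss > MAX_REL_RSS * float(s @ s)
    converged = bool(best.success) and not at_bound and not poor_fit
    if not converged:
        return VoxelFit(np.nan, np.nan, float(rss), False)
    return VoxelFit(float(t1_hat), float(m0_hat), float(rss), True)


def _profiled_rss(signals: np.ndarray, gmag: np.ndarray):
    """RSS minimized over M0 >= 0 for each (voxel, T1-grid-point) pair.

    ``signals``: (n_vox, n_ti); ``gmag``: (n_grid, n_ti) magnitude of the
    unit-M0 model.  Returns (rss, m0) of shape (n_vox, n_grid).
    """
    g2 = np.einsum("gt,gt->g", gmag, gmag)
    cross = signals @ gmag.T
    np.clip(cross, 0.0, None, out=cross)
    m0 = cross / g2
    rss = np.einsum("vt,vt->v", signals, signals)[:, None] - cross**2 / g2
    return rss, m0


def _grid_magnitudes(t1_grid: np.ndarray, tis: np.ndarray, f: float, si: float) -> np.ndarray:
    """|unit-M0 model| for a grid of T1s; shape (*t1_grid.shape, n_ti)."""
    t1 = t1_grid[..., None]
    return np.abs(1.0 - f * np.exp(-tis / t1) + (f - 1.0) * np.exp(-si / t1))


def _fit_signals_grid(
    signals: np.ndarray,
    acq: AcquisitionParams,
    t1_bounds: tuple[float, float],
    n_coarse: int = 300,
    n_refine: int = 21,
    refine_rounds: int = 4,
):
    """Vectorized profiled-T1 fit for an (n_vox, n_ti) signal matrix."""
    tis = acq.tis
    f = acq.inversion_factor
    si = acq.shot_interval_ms
    lo, hi = t1_bounds

    coarse = np.geomspace(lo, hi, n_coarse)
    gmag = _grid_magnitudes(coarse, tis, f, si)
    rss, _ = _profiled_rss(signals, gmag)
    idx = np.argmin(rss, axis=1)
    t1_lo = coarse[np.maximum(idx - 1, 0)]
    t1_hi = coarse[np.minimum(idx + 1, n_coarse - 1)]

    for _ in range(refine_rounds):
        # per-voxel log-spaced grids spanning the current bracket
        grids = np.exp(
            np.linspace(0.0, 1.0, n_refine)[None, :]
            * (np.log(t1_hi) - np.log(t1_lo))[:, None]
            + np.log(t1_lo)[:, None]
        )
        gm = _grid_magnitudes(grids, tis, f, si)  # (n_vox, n_refine, n_ti)
        g2 = np.einsum("vrt,vrt->vr", gm, gm)
        cross = np.einsum("vt,vrt->vr", signals, gm)
        np.clip(cross, 0.0, None, out=cross)
        rss = -(cross**2) / g2  # constant Σs² omitted: same argmin
        j = np.argmin(rss, axis=1)
        rows = np.arange(grids.shape[0])
        t1_lo = grids[rows, np.maximum(j - 1, 0)]
        t1_hi = grids[rows, np.minimum(j + 1, n_refine - 1)]

    t1_hat = np.sqrt(t1_lo * t1_hi)  # log-midpoint of the final bracket
    gm = _grid_magnitudes(t1_hat, tis, f, si)
    g2 = np.einsum("vt,vt->v", gm, gm)
    cross = np.clip(np.einsum("vt,vt->v", signals, gm), 0.0, None)
    m0_hat = cross / g2
    rss = np.einsum("vt,vt->v", signals, signals) - cross**2 / g2
    at_bound = (t1_hat <= lo * (1 + 1e-4)) | (t1_hat >= hi * (1 - 1e-4))
    smax = signals.max(axis=1)
    energy = np.einsum("vt,vt->v", signals, signals)
    converged = (
        ~at_bound
        & (m0_hat > 1e-9 * np.maximum(smax, 1e-300))
        & (smax > 0)
        & (rss <= MAX_REL_RSS * energy)
    )
    return t1_hat, m0_hat, np.maximum(rss, 0.0), converged


def fit_map(
    series: IRSeries,
    mask: np.ndarray | None = None,
    t1_bounds: tuple[float, float] = T1_BOUNDS_MS,
    chunk_voxels: int = 50_000,
    noise_sigma: float | None = None,
) -> T1Map:
    """Fit a qT1 map over a volume (inside ``mask`` if given).

    Voxels outside the mask, with all-zero signals, or whose optimum sits on
    a T1 bound are marked unconverged and carry NaN.  The fraction of
    unconverged in-mask voxels is recorded in ``meta['unconverged_fraction']``.

    If the Rician noise scale is known, passing ``noise_sigma`` applies the
    second-moment noise-floor correction ``s -> sqrt(max(s^2 - 2 sigma^2, 0))``
    before fitting; this removes the magnitude-bias that otherwise inflates
    long T1 estimates whose signals pass near a null at one of the TIs.
    """
    grid_shape = series.grid_shape
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid_shape:
            raise GridMismatchError(f"mask shape {mask.shape} != series grid {grid_shape}")

    flat = series.data.reshape(-1, series.data.shape[-1])
    if noise_sigma is not None and noise_sigma > 0:
        flat = np.sqrt(np.clip(flat**2 - 2.0 * noise_sigma**2, 0.0, None))
    sel = np.flatnonzero(mask.ravel())
    n_ti = flat.shape[1]

    t1 = np.full(mask.size, np.nan)
    m0 = np.full(mask.size, np.nan)
    rss = np.full(mask.size, np.nan)
    conv = np.zeros(mask.size, dtype=bool)

    for start in range(0, sel.size, chunk_voxels):
        ids = sel[start : start + chunk_voxels]
        sig = flat[ids]
        ok = np.all(np.isfinite(sig), axis=1) & (sig.max(axis=1) > 0)
        if np.any(ok):
            t1_c, m0_c, rss_c, conv_c = _fit_signals_grid(sig[ok], series.acq, t1_bounds)
            sub = ids[ok]
            t1[sub] = np.where(conv_c, t1_c, np.nan)
            m0[sub] = np.where(conv_c, m0_c, np.nan)
            rss[sub] = rss_c
            conv[sub] = conv_c
        bad = ids[~ok]
        rss[bad] = 0.0

    n_in = sel.size
    unconv_frac = float((~conv[sel]).sum() / n_in) if n_in else 0.0
    return T1Map(
        t1=t1.reshape(grid_shape),
        m0=m0.reshape(grid_shape),
        rss=rss.reshape(grid_shape),
        converged=conv.reshape(grid_shape),
        affine=series.affine.copy(),
        acq=series.acq,
        meta={"unconverged_fraction": unconv_frac, "n_fitted": int(conv[sel].sum()),
              "n_ti": n_ti, "noise_floor_sigma": noise_sigma},
    )
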