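"""NIfTI and sidecar-metadata I/O.

Volumes travel as NIfTI-1 via nibabel: masks as uint8, quantitative maps as
32-bit float with NaN for unfitted voxels.  Acquisition constants (the TI
schedule, shot interval and inversion factor) ride in a YAML sidecar next to
each 4-D IR series, in volume order.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import NamedTuple

import nibabel as nib
import numpy as np
import yaml

from .errors import VolumeIOError
from .phantom import PhantomBundle
from .relaxometry import AcquisitionParams, IRSeries, T1Map

__all__ = [
    "Volume",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_ir_series",
    "save_ir_series",
    "load_t1_map",
    "save_t1_map",
    "read_acquisition_yaml",
    "write_acquisition_yaml",
    "save_phantom_bundle",
]


class Volume(NamedTuple):
    data: np.ndarray
    affine: np.ndarray


def _read_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        return nib.load(str(path))
    except Exception as exc:
        raise VolumeIOError(f"not a readable NIfTI payload: {path} ({exc})") from exc


def load_volume(path, expect_ndim: int | None = None) -> Volume:
    """Load a NIfTI volume as float data plus its affine."""
    img = _read_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise VolumeIOError(f"{path}: expected {expect_ndim}-D data, got {data.ndim}-D {data.shape}")
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def save_volume(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_mask(path) -> Volume:
    """Load a binary mask; non-{0,1} payloads are normalized with a warning."""
    vol = load_volume(path, expect_ndim=3)
    values = np.unique(vol.data[np.isfinite(vol.data)])
    if not np.all(np.isin(values, [0.0, 1.0])):
        warnings.warn(
            f"{path}: mask values {values[:6]}... normalized to {{0,1}} (nonzero -> 1)",
            stacklevel=2,
        )
    return Volume(data=(vol.data != 0) & np.isfinite(vol.data), affine=vol.affine)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    save_volume(np.asarray(mask).astype(np.uint8), affine, path, dtype=np.uint8)


def write_acquisition_yaml(acq: AcquisitionParams, path, extra: dict | None = None) -> None:
    doc = {
        "inversion_delays_ms": list(acq.inversion_delays_ms),
        "shot_interval_ms": float(acq.shot_interval_ms),
        "inversion_factor": float(acq.inversion_factor),
    }
    if extra:
        doc.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_acquisition_yaml(path) -> tuple[AcquisitionParams, dict]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"acquisition sidecar not found: {path}")
    doc = yaml.safe_load(path.read_text())
    acq = AcquisitionParams(
        inversion_delays_ms=tuple(doc["inversion_delays_ms"]),
        shot_interval_ms=float(doc["shot_interval_ms"]),
        inversion_factor=float(doc.get("inversion_factor", 2.0)),
    )
    extra = {k: v for k, v in doc.items()
             if k not in {"inversion_delays_ms", "shot_interval_ms", "inversion_factor"}}
    return acq, extra


def save_ir_series(series: IRSeries, nifti_path, yaml_path=None, extra: dict | None = None) -> None:
    save_volume(series.data, series.affine, nifti_path)
    if yaml_path is not None:
        write_acquisition_yaml(series.acq, yaml_path, extra=extra)


def load_ir_series(nifti_path, yaml_path) -> IRSeries:
    vol = load_volume(nifti_path, expect_ndim=4)
    acq, extra = read_acquisition_yaml(yaml_path)
    return IRSeries(data=vol.data, acq=acq, affine=vol.affine, meta=extra)


def save_t1_map(t1_map: T1Map, path, companions: bool = False) -> None:
    """Write the T1 volume; with ``companions`` also M0/rss/converged maps."""
    path = Path(path)
    save_volume(t1_map.t1, t1_map.affine, path)
    if companions:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        save_volume(t1_map.m0, t1_map.affine, path.parent / f"{stem}_m0.nii.gz")
        save_volume(t1_map.rss, t1_map.affine, path.parent / f"{stem}_rss.nii.gz")
        save_mask(t1_map.converged, t1_map.affine, path.parent / f"{stem}_converged.nii.gz")


def load_t1_map(path, acq: AcquisitionParams | None = None) -> T1Map:
    vol = load_volume(path, expect_ndim=3)
    finite = np.isfinite(vol.data)
    return T1Map(
        t1=vol.data,
        m0=np.full_like(vol.data, np.nan),
        rss=np.full_like(vol.data, np.nan),
        converged=finite,
        affine=vol.affine,
        acq=acq,
        meta={"source": str(path)},
    )


def save_phantom_bundle(bundle: PhantomBundle, out_dir) -> dict:
    """Write a phantom's series, truth maps and masks; return the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    save_ir_series(bundle.ir_pre, out / "ir_pre.nii.gz", out / "acquisition.yaml",
                   extra={"noise_sigma": bundle.ir_pre.meta.get("noise_sigma")})
    save_ir_series(bundle.ir_post, out / "ir_post.nii.gz")
    paths["ir_pre"], paths["ir_post"] = str(out / "ir_pre.nii.gz"), str(out / "ir_post.nii.gz")
    paths["acquisition"] = str(out / "acquisition.yaml")
    save_volume(bundle.true_t1_pre, bundle.affine, out / "true_t1_pre.nii.gz")
    save_volume(bundle.true_t1_post, bundle.affine, out / "true_t1_post.nii.gz")
    save_volume(bundle.label_map, bundle.affine, out / "labels.nii.gz", dtype=np.int16)
    for name, mask in bundle.masks.items():
        save_mask(mask, bundle.affine, out / f"mask_{name}.nii.gz")
        paths[f"mask_{name}"] = str(out / f"mask_{name}.nii.gz")
    (out / "truth_manifest.yaml").write_text(yaml.safe_dump(bundle.truth_manifest, sort_keys=False))
    paths["truth_manifest"] = str(out / "truth_manifest.yaml")
    return paths
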