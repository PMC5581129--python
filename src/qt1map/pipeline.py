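"""End-to-end study runner: fit -> harmonize -> ΔqT1 -> segment -> ROC -> overlap.

A *study* is a directory tree of per-patient, per-time-point inputs (IR
series pre/post contrast, masks, a seed file) described by a YAML manifest.
:func:`run_all` executes the full analysis on such a study and writes every
intermediate map plus machine-readable reports; :func:`make_phantom_study`
materializes a synthetic cohort in that layout so the whole pipeline can be
exercised without patient data.

All randomness is seeded and every report carries the configuration hash, so
re-running a study with the same manifest reproduces all numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .cutoff import build_samples, roc_analysis
from .enhancement import delta_map, segment_enhancing
from .errors import ConfigurationError, VolumeIOError
from .harmonize import assert_coregistered, nawm_scale
from .overlap import cohort_report, overlap_percent, threshold_map, transformation
from .phantom import PhantomGeometry, PhantomSpec, build_phantom
from .relaxometry import fit_map

__all__ = [
    "TimepointEntry",
    "PatientEntry",
    "StudyManifest",
    "RunConfig",
    "run_all",
    "make_phantom_study",
]


@dataclass(frozen=True)
class TimepointEntry:
    timepoint_id: str
    ir_pre: str
    ir_post: str
    acquisition: str
    brain_mask: str
    wm_mask: str
    seeds: str
    vessel_mask: str | None = None
    pseudoprogression_guard_passed: bool = True


@dataclass(frozen=True)
class PatientEntry:
    patient_id: str
    timepoints: tuple[TimepointEntry, ...]


@dataclass(frozen=True)
class StudyManifest:
    patients: tuple[PatientEntry, ...]
    root: Path

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        root = path.parent
        patients = []
        for p in doc["patients"]:
            tps = []
            for t in p["timepoints"]:
                entry = TimepointEntry(
                    timepoint_id=str(t["id"]),
                    ir_pre=t["ir_pre"],
                    ir_post=t["ir_post"],
                    acquisition=t["acquisition"],
                    brain_mask=t["brain_mask"],
                    wm_mask=t["wm_mask"],
                    seeds=t["seeds"],
                    vessel_mask=t.get("vessel_mask"),
                    pseudoprogression_guard_passed=bool(
                        t.get("pseudoprogression_guard_passed", True)
                    ),
                )
                tps.append(entry)
            patients.append(PatientEntry(patient_id=str(p["id"]), timepoints=tuple(tps)))
        manifest = cls(patients=tuple(patients), root=root)
        manifest.validate()
        return manifest

    def validate(self) -> None:
        for p in self.patients:
            if not p.timepoints:
                raise ConfigurationError(f"patient {p.patient_id} has no time points")
            for t in p.timepoints:
                for key in ("ir_pre", "ir_post", "acquisition", "brain_mask", "wm_mask", "seeds"):
                    rel = getattr(t, key)
                    if not (self.root / rel).exists():
                        raise VolumeIOError(
                            f"patient {p.patient_id} / {t.timepoint_id}: missing {key} file {rel}"
                        )
                if t.vessel_mask is not None and not (self.root / t.vessel_mask).exists():
                    raise VolumeIOError(
                        f"patient {p.patient_id} / {t.timepoint_id}: missing vessel mask {t.vessel_mask}"
                    )


@dataclass(frozen=True)
class RunConfig:
    """One knob surface for the whole pipeline; defaults mirror the method."""

    enhancement_threshold_percent: float = 50.0
    subtle_lower_percent: float = 15.0
    surround_band_mm: float = 10.0
    max_voxels_per_class: int | None = None
    min_wm_voxels: int = 100
    cutoff_ms: float | None = None  # None -> use the cohort ROC cutoff
    apply_pseudoprogression_guard: bool = True
    rng_seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log(handle, **event) -> None:
    event["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    handle.write(json.dumps(event) + "\n")
    handle.flush()


def _load_seeds(path) -> list[tuple[int, int, int]]:
    doc = json.loads(Path(path).read_text())
    return [tuple(int(c) for c in s) for s in doc]


def run_all(manifest: StudyManifest | str | Path, out_dir, config: RunConfig | None = None) -> dict:
    """Run the complete analysis on a study and write a report bundle.

    Per case: fit pre/post qT1, NAWM-scale the post map, compute the ΔqT1
    map, grow the enhancing-tumor segmentation from the seed file, and pool
    labeled voxel samples.  Cohort-level: ROC analysis of pooled samples for
    the optimal pre-contrast cutoff, per-case overlap of the supra-cutoff
    area with the enhancing tumor, and transformation of earlier
    non-overlapping areas at each patient's later time points.

    Fails fast: any stage error propagates annotated with patient/time-point
    context.  Returns the report bundle as a dict (also written as JSON).
    """
    if not isinstance(manifest, StudyManifest):
        manifest = StudyManifest.load(manifest)
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"

    cases = []  # (patient, tp, t1_pre, seg, supra placeholder)
    sample_frames = []
    with open(log_path, "w") as log:
        _log(log, stage="start", config_hash=config.config_hash(),
             config=dataclasses.asdict(config))
        for patient in manifest.patients:
            for tp in patient.timepoints:
                ctx = {"patient": patient.patient_id, "timepoint": tp.timepoint_id}
                if config.apply_pseudoprogression_guard and not tp.pseudoprogression_guard_passed:
                    _log(log, stage="skip-pseudoprogression-guard", **ctx)
                    continue
                try:
                    case_dir = out / patient.patient_id / tp.timepoint_id
                    series_pre = qio.load_ir_series(manifest.root / tp.ir_pre,
                                                    manifest.root / tp.acquisition)
                    series_post = qio.load_ir_series(manifest.root / tp.ir_post,
                                                     manifest.root / tp.acquisition)
                    brain = qio.load_mask(manifest.root / tp.brain_mask)
                    wm = qio.load_mask(manifest.root / tp.wm_mask)
                    vessels = (qio.load_mask(manifest.root / tp.vessel_mask).data
                               if tp.vessel_mask else None)
                    assert_coregistered(series_pre, series_post, brain.data)

                    _log(log, stage="fit", **ctx)
                    t1_pre = fit_map(series_pre, mask=brain.data)
                    t1_post = fit_map(series_post, mask=brain.data)
                    qio.save_t1_map(t1_pre, case_dir / "t1_pre.nii.gz")

                    scaled_post, scaling = nawm_scale(
                        t1_pre, t1_post, wm.data, min_wm_voxels=config.min_wm_voxels)
                    _log(log, stage="nawm-scale", scale_factor=scaling.scale_factor, **ctx)
                    qio.save_t1_map(scaled_post, case_dir / "t1_post_scaled.nii.gz")

                    delta = delta_map(t1_pre, scaled_post)
                    qio.save_volume(delta.data, delta.affine, case_dir / "delta_qt1.nii.gz")

                    seg = segment_enhancing(
                        delta, t1_pre, scaled_post,
                        seeds=_load_seeds(manifest.root / tp.seeds),
                        threshold_percent=config.enhancement_threshold_percent,
                        vessel_mask=vessels,
                        subtle_lower_percent=config.subtle_lower_percent,
                    )
                    qio.save_mask(seg.tumor_mask, delta.affine, case_dir / "tumor_mask.nii.gz")
                    qio.save_mask(seg.subtle_mask, delta.affine, case_dir / "subtle_mask.nii.gz")
                    _log(log, stage="segment", n_tumor=int(seg.tumor_mask.sum()), **ctx)

                    samples = build_samples(
                        t1_pre, seg.tumor_mask, brain.data, vessel_mask=vessels,
                        band_width_mm=config.surround_band_mm,
                        rng_seed=config.rng_seed,
                        max_per_class=config.max_voxels_per_class,
                        patient_id=patient.patient_id, timepoint_id=tp.timepoint_id,
                    )
                    sample_frames.append(samples)
                    cases.append((patient.patient_id, tp.timepoint_id, t1_pre, seg, brain.data))
                except Exception as exc:
                    _log(log, stage="error", error=str(exc), **ctx)
                    raise type(exc)(
                        f"[patient {patient.patient_id} / {tp.timepoint_id}] {exc}"
                    ) from exc

        if not cases:
            raise ConfigurationError("no evaluable cases in the study")

        all_samples = pd.concat(sample_frames, ignore_index=True)
        all_samples.to_csv(out / "samples.csv", index=False)
        roc = roc_analysis(all_samples)
        cutoff = config.cutoff_ms if config.cutoff_ms is not None else roc.optimal_cutoff_ms
        _log(log, stage="roc", optimal_cutoff_ms=roc.optimal_cutoff_ms, auc=roc.auc)

        overlap_reports = []
        supra_by_case = {}
        for patient_id, tp_id, t1_pre, seg, _brain in cases:
            supra = threshold_map(t1_pre, cutoff_ms=cutoff)
            supra_by_case[(patient_id, tp_id)] = (supra, seg.tumor_mask)
            rep = overlap_percent(supra, seg.tumor_mask, t1_pre=t1_pre,
                                  patient_id=patient_id, timepoint_id=tp_id)
            overlap_reports.append(rep)
            _log(log, stage="overlap", patient=patient_id, timepoint=tp_id,
                 overlap_percent=rep.overlap_percent, overlap_class=rep.overlap_class)

        transformation_reports = []
        for patient in manifest.patients:
            tps = [t.timepoint_id for t in patient.timepoints
                   if (patient.patient_id, t.timepoint_id) in supra_by_case]
            for earlier, later in zip(tps, tps[1:]):
                supra_e, tumor_e = supra_by_case[(patient.patient_id, earlier)]
                _supra_l, tumor_l = supra_by_case[(patient.patient_id, later)]
                rep = transformation(supra_e & ~tumor_e, tumor_l,
                                     patient_id=patient.patient_id,
                                     earlier_timepoint_id=earlier, later_timepoint_id=later)
                transformation_reports.append(rep)

        summary = cohort_report(overlap_reports)
        bundle = {
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config),
            "roc": roc.as_dict(),
            "cutoff_ms_used": cutoff,
            "overlap": [r.as_dict() for r in overlap_reports],
            "transformation": [r.as_dict() for r in transformation_reports],
            "cohort_summary": summary.as_dict(),
        }
        (out / "report.json").write_text(json.dumps(bundle, indent=2))
        pd.DataFrame([r.as_dict() for r in overlap_reports]).to_csv(
            out / "overlap.csv", index=False)
        if transformation_reports:
            pd.DataFrame([r.as_dict() for r in transformation_reports]).to_csv(
                out / "transformation.csv", index=False)
        _log(log, stage="done", cohort=summary.as_dict())
    return bundle


def _rim_seed_voxel(bundle) -> tuple[int, int, int]:
    """A deterministic seed voxel well inside the true enhancing rim."""
    idx = np.argwhere(bundle.masks["enhancing_rim"])
    center = idx.mean(axis=0)
    best = idx[np.argmin(((idx - center) ** 2).sum(axis=1))]
    return tuple(int(c) for c in best)


def make_phantom_study(
    out_dir,
    n_patients: int = 3,
    timepoints_per_patient: int = 1,
    base_seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    noise_sigma: float = 0.01,
    rim_growth_mm: float = 0.0,
    geometry: PhantomGeometry | None = None,
) -> Path:
    """Write a synthetic cohort in the study-directory layout; returns the manifest path.

    Patients differ in RNG seed and a small tumor-center shift; successive
    time points of a patient reuse its geometry (optionally with the rim
    grown by ``rim_growth_mm`` per step, so earlier supra-cutoff areas can
    transform into later enhancing tumor) under fresh noise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shifts = [(0.0, 0.0, 0.0), (1.0, -1.0, 0.0), (-1.0, 1.0, 1.0), (0.0, 2.0, -1.0)]
    doc = {"patients": []}
    for i in range(n_patients):
        patient_id = f"p{i + 1}"
        shift = shifts[i % len(shifts)]
        tps = []
        for j in range(timepoints_per_patient):
            tp_id = f"tp{j + 1}"
            geom = geometry if geometry is not None else PhantomGeometry()
            grown = j * rim_growth_mm
            geom = dataclasses.replace(
                geom,
                tumor_center=tuple(c + s for c, s in zip(geom.tumor_center, shift)),
                rim_outer_radius=geom.rim_outer_radius + grown,
                subtle_outer_radius=geom.subtle_outer_radius + grown,
                edema_outer_radius=geom.edema_outer_radius + grown,
            )
            spec = PhantomSpec(grid_shape=grid_shape, geometry=geom,
                               noise_sigma=noise_sigma,
                               rng_seed=(base_seed + 1000 * i + j) % (2**31))
            bundle = build_phantom(spec)
            case_dir = out / patient_id / tp_id
            qio.save_phantom_bundle(bundle, case_dir)
            seed_path = case_dir / "seeds.json"
            seed_path.write_text(json.dumps([list(_rim_seed_voxel(bundle))]))
            rel = f"{patient_id}/{tp_id}"
            tps.append({
                "id": tp_id,
                "ir_pre": f"{rel}/ir_pre.nii.gz",
                "ir_post": f"{rel}/ir_post.nii.gz",
                "acquisition": f"{rel}/acquisition.yaml",
                "brain_mask": f"{rel}/mask_brain.nii.gz",
                "wm_mask": f"{rel}/mask_wm.nii.gz",
                "vessel_mask": f"{rel}/mask_vessels.nii.gz",
                "seeds": f"{rel}/seeds.json",
                "pseudoprogression_guard_passed": True,
            })
        doc["patients"].append({"id": patient_id, "timepoints": tps})
    manifest_path = out / "study.yaml"
    manifest_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest_path
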