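"""Overlap between qT1-prolonged areas and enhancing tumor, and its fate.

The contrast-agent-free tumor surrogate is the set of voxels whose
pre-contrast qT1 strictly exceeds a cutoff (2051 ms by default).  Each
case's surrogate is scored against the gold-standard enhancing-tumor mask as
the percentage of the gold standard it covers, documented in 10 % steps and
classified as excellent (>= 90 %), moderate (50-89 %) or poor (0-49 %).
Supra-cutoff voxels *outside* the enhancing tumor are followed up: the
fraction that has become enhancing tumor at a later time point is the
transformation report (none < 5 %, completely >= 95 %, otherwise partial).

Cohort aggregation counts patients by their best/recurrent overlap classes,
mirroring how longitudinal relaxometry cohorts are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError

__all__ = [
    "OverlapReport",
    "TransformationReport",
    "CohortSummary",
    "threshold_map",
    "overlap_percent",
    "classify_overlap",
    "transformation",
    "cohort_report",
    "load_reference_cohort",
]

DEFAULT_CUTOFF_MS = 2051.0
OVERLAP_CLASSES = ("excellent", "moderate", "poor")


@dataclass(frozen=True)
class OverlapReport:
    patient_id: str
    timepoint_id: str
    overlap_percent: float
    overlap_percent_binned: int
    overlap_class: str
    n_tumor_voxels: int
    n_supra_cutoff_voxels: int
    mean_qt1_tumor_ms: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class TransformationReport:
    patient_id: str
    earlier_timepoint_id: str
    later_timepoint_id: str
    n_nonoverlap_voxels: int
    transformed_fraction_percent: float
    transformed_fraction_binned: int
    transformation_class: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_cases: int
    patients_excellent_ge1: int
    patients_excellent_ge2: int
    patients_moderate_ge1: int
    patients_predominantly_moderate: int
    patients_poor_ge1: int
    mean_overlap_percent: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _bin10(percent: float) -> int:
    """Document a percentage in steps of 10 % (half-up rounding: 65 -> 70)."""
    return int(np.floor(percent / 10.0 + 0.5)) * 10


def threshold_map(t1_pre, cutoff_ms: float = DEFAULT_CUTOFF_MS) -> np.ndarray:
    """Binary mask of voxels with fitted pre-contrast qT1 strictly > cutoff."""
    if cutoff_ms <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff_ms}")
    t1 = np.asarray(getattr(t1_pre, "t1", t1_pre), dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(t1) & (t1 > cutoff_ms)


def classify_overlap(percent: float) -> str:
    """excellent (>= 90), moderate (50-89) or poor (0-49) overlap."""
    if not (0.0 <= percent <= 100.0):
        raise ParameterError(f"overlap percent must lie in [0, 100], got {percent}")
    if percent >= 90.0:
        return "excellent"
    if percent >= 50.0:
        return "moderate"
    return "poor"


def overlap_percent(
    supra_mask: np.ndarray,
    tumor_mask: np.ndarray,
    t1_pre=None,
    patient_id: str = "p0",
    timepoint_id: str = "tp0",
) -> OverlapReport:
    """Score a qT1-prolonged area against the gold-standard enhancing tumor.

    The headline number is coverage of the gold standard,
    ``100 * |supra ∩ tumor| / |tumor|``; Dice and Jaccard are attached as
    supplementary symmetric measures.  If ``t1_pre`` is given, the mean
    pre-contrast qT1 inside the tumor is reported for table-style summaries.
    """
    supra = np.asarray(supra_mask).astype(bool)
    tumor = np.asarray(tumor_mask).astype(bool)
    if supra.shape != tumor.shape:
        raise ParameterError(f"mask shapes differ: {supra.shape} vs {tumor.shape}")
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise AnalysisError("gold-standard tumor mask is empty")
    inter = int((supra & tumor).sum())
    n_supra = int(supra.sum())
    pct = 100.0 * inter / n_tumor
    union = n_supra + n_tumor - inter
    mean_qt1 = np.nan
    if t1_pre is not None:
        vals = np.asarray(getattr(t1_pre, "t1", t1_pre), dtype=float)[tumor]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean_qt1 = float(vals.mean())
    return OverlapReport(
        patient_id=patient_id,
        timepoint_id=timepoint_id,
        overlap_percent=pct,
        overlap_percent_binned=_bin10(pct),
        overlap_class=classify_overlap(pct),
        n_tumor_voxels=n_tumor,
        n_supra_cutoff_voxels=n_supra,
        mean_qt1_tumor_ms=mean_qt1,
        dice=2.0 * inter / (n_supra + n_tumor),
        jaccard=inter / union if union else 0.0,
    )


def transformation(
    nonoverlap_mask_earlier: np.ndarray,
    tumor_mask_later: np.ndarray,
    patient_id: str = "p0",
    earlier_timepoint_id: str = "tp0",
    later_timepoint_id: str = "tp1",
) -> TransformationReport:
    """How much of an earlier non-overlapping supra-cutoff area became tumor.

    ``nonoverlap_mask_earlier`` is the earlier supra-cutoff area minus the
    earlier enhancing tumor.  Classes: < 5 % none, >= 95 % completely,
    otherwise partially (fraction documented in 10 % steps); an empty
    non-overlap area yields class ``not-applicable``.
    """
    nonov = np.asarray(nonoverlap_mask_earlier).astype(bool)
    later = np.asarray(tumor_mask_later).astype(bool)
    if nonov.shape != later.shape:
        raise ParameterError(f"mask shapes differ: {nonov.shape} vs {later.shape}")
    n = int(nonov.sum())
    if n == 0:
        return TransformationReport(patient_id, earlier_timepoint_id, later_timepoint_id,
                                    0, 0.0, 0, "not-applicable")
    frac = 100.0 * int((nonov & later).sum()) / n
    if frac < 5.0:
        cls = "none"
    elif frac >= 95.0:
        cls = "completely"
    else:
        cls = "partially"
    return TransformationReport(
        patient_id=patient_id,
        earlier_timepoint_id=earlier_timepoint_id,
        later_timepoint_id=later_timepoint_id,
        n_nonoverlap_voxels=n,
        transformed_fraction_percent=frac,
        transformed_fraction_binned=_bin10(frac),
        transformation_class=cls,
    )


def _to_frame(per_case_reports) -> pd.DataFrame:
    if isinstance(per_case_reports, pd.DataFrame):
        df = per_case_reports.copy()
    else:
        df = pd.DataFrame([r.as_dict() for r in per_case_reports])
    if "overlap_class" not in df.columns or "patient_id" not in df.columns:
        raise ParameterError("reports need at least patient_id and overlap_class")
    return df


def cohort_report(per_case_reports) -> CohortSummary:
    """Aggregate per-case overlap reports into patient-level counts.

    Accepts a list of :class:`OverlapReport` or a DataFrame with at least
    ``patient_id`` and ``overlap_class`` columns (an ``overlap_percent``
    column, if present, feeds the grand mean).  Rows whose class is not one
    of excellent/moderate/poor (e.g. unevaluable acquisitions) are ignored.
    "Predominantly moderate" counts patients moderate at >= 2 time points.
    """
    df = _to_frame(per_case_reports)
    df = df[df["overlap_class"].isin(OVERLAP_CLASSES)]
    if df.empty:
        raise AnalysisError("no evaluable cases in the cohort")
    counts = df.groupby("patient_id")["overlap_class"].value_counts().unstack(fill_value=0)
    for cls in OVERLAP_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    mean_pct = float(df["overlap_percent"].mean()) if "overlap_percent" in df.columns else float("nan")
    return CohortSummary(
        n_patients=int(counts.shape[0]),
        n_cases=int(df.shape[0]),
        patients_excellent_ge1=int((counts["excellent"] >= 1).sum()),
        patients_excellent_ge2=int((counts["excellent"] >= 2).sum()),
        patients_moderate_ge1=int((counts["moderate"] >= 1).sum()),
        patients_predominantly_moderate=int((counts["moderate"] >= 2).sum()),
        patients_poor_ge1=int((counts["poor"] >= 1).sum()),
        mean_overlap_percent=mean_pct,
    )


def load_reference_cohort() -> pd.DataFrame:
    """Published 10-patient recurrent-glioblastoma worked example.

    Per-patient, per-time-point overlap and transformation categories plus
    mean tumor qT1 from a published relaxometry cohort; used to exercise
    :func:`cohort_report` against externally tabulated counts.
    """
    with resources.files("qt1map.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh, dtype={"patient_id": str, "timepoint_id": str})
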