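"""Supra-cutoff thresholding, overlap scoring/classing, transformation, cohort counts.

Oracles: brute-force set counting on random masks and an externally
tabulated 10-patient reference cohort with known patient-level counts.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qt1map import (
    AnalysisError,
    ParameterError,
    classify_overlap,
    cohort_report,
    load_reference_cohort,
    overlap_percent,
    threshold_map,
    transformation,
)


class TestThresholdMap:
    def test_strict_inequality_at_cutoff(self):
        t1 = np.array([[[2051.0, 2051.001], [2050.999, 3000.0]]])
        mask = threshold_map(t1, cutoff_ms=2051.0)
        assert not mask[0, 0, 0]          # exactly at the cutoff: excluded
        assert mask[0, 0, 1] and mask[0, 1, 1]
        assert not mask[0, 1, 0]

    def test_sentinels_never_included(self):
        mask = threshold_map(np.full((3, 3, 3), np.nan), cutoff_ms=2051.0)
        assert not mask.any()

    def test_noiseless_phantom_truth_map_thresholds_exactly(self, noiseless_bundle):
        b = noiseless_bundle
        truth = b.true_t1_pre
        expected = np.isfinite(truth) & (truth > 2051.0)
        np.testing.assert_array_equal(threshold_map(b.truth_t1_map("pre"), 2051.0), expected)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            threshold_map(np.ones((2, 2, 2)), cutoff_ms=0.0)


class TestClassifyOverlap:
    @pytest.mark.parametrize(
        "pct, expected",
        [(100.0, "excellent"), (90.0, "excellent"), (89.99, "moderate"),
         (50.0, "moderate"), (49.9, "poor"), (0.0, "poor")],
    )
    def test_class_bins(self, pct, expected):
        assert classify_overlap(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            classify_overlap(101.0)

    @settings(max_examples=100, deadline=None)
    @given(pct=st.floats(0.0, 100.0))
    def test_class_always_consistent_with_bin_rule(self, pct):
        cls = classify_overlap(pct)
        assert cls == ("excellent" if pct >= 90 else "moderate" if pct >= 50 else "poor")


class TestOverlapPercent:
    def test_identical_masks_are_excellent(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        rep = overlap_percent(m, m)
        assert rep.overlap_percent == 100.0
        assert rep.overlap_class == "excellent"
        assert rep.dice == 1.0 and rep.jaccard == 1.0

    def test_disjoint_masks_are_poor(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        rep = overlap_percent(a, b)
        assert rep.overlap_percent == 0.0 and rep.overlap_class == "poor"

    def test_partial_coverage_counted_binned_and_classed(self):
        """130 of 200 tumor voxels covered: 65%, binned 70, moderate."""
        tumor = np.zeros((10, 10, 10), dtype=bool)
        tumor.ravel()[:200] = True
        supra = np.zeros_like(tumor)
        supra.ravel()[:130] = True
        rep = overlap_percent(supra, tumor)
        assert rep.overlap_percent == 65.0
        assert rep.overlap_percent_binned == 70
        assert rep.overlap_class == "moderate"
        assert rep.n_tumor_voxels == 200 and rep.n_supra_cutoff_voxels == 130

    def test_empty_tumor_rejected(self):
        with pytest.raises(AnalysisError):
            overlap_percent(np.ones((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool))

    def test_mean_tumor_qt1_attached(self):
        tumor = np.zeros((4, 4, 4), dtype=bool)
        tumor[:2] = True
        t1 = np.full((4, 4, 4), 2500.0)
        rep = overlap_percent(tumor, tumor, t1_pre=t1)
        assert rep.mean_qt1_tumor_ms == 2500.0

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_brute_force_counting_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        supra = rng.random((6, 6, 6)) < 0.4
        tumor = rng.random((6, 6, 6)) < 0.4
        if not tumor.any():
            tumor[0, 0, 0] = True
        rep = overlap_percent(supra, tumor)
        # brute force: iterate voxels explicitly
        inter = sum(bool(supra[i] and tumor[i]) for i in np.ndindex(supra.shape))
        expected = 100.0 * inter / tumor.sum()
        assert rep.overlap_percent == pytest.approx(expected, abs=1e-12)
        assert rep.overlap_class == classify_overlap(expected)


class TestTransformation:
    def test_fully_absorbed_is_completely(self):
        non = np.zeros((6, 6, 6), dtype=bool)
        non[1:3] = True
        rep = transformation(non, np.ones_like(non))
        assert rep.transformed_fraction_percent == 100.0
        assert rep.transformation_class == "completely"

    def test_disjoint_is_none(self):
        non = np.zeros((6, 6, 6), dtype=bool)
        later = np.zeros_like(non)
        non[0] = True
        later[5] = True
        rep = transformation(non, later)
        assert rep.transformed_fraction_percent == 0.0
        assert rep.transformation_class == "none"

    def test_partial_with_binned_fraction(self):
        """80 of 100 voxels transformed: partially, documented as 80%."""
        non = np.zeros((10, 10, 10), dtype=bool)
        non.ravel()[:100] = True
        later = np.zeros_like(non)
        later.ravel()[:80] = True
        rep = transformation(non, later)
        assert rep.transformation_class == "partially"
        assert rep.transformed_fraction_percent == 80.0
        assert rep.transformed_fraction_binned == 80

    def test_empty_nonoverlap_is_not_applicable(self):
        rep = transformation(np.zeros((3, 3, 3), dtype=bool), np.ones((3, 3, 3), dtype=bool))
        assert rep.n_nonoverlap_voxels == 0
        assert rep.transformation_class == "not-applicable"


class TestCohortReport:
    def test_reference_cohort_patient_counts(self):
        """The tabulated 10-patient cohort reproduces its published counts:
        8 patients excellent at >= 1 time point, 7 at >= 2, 4 with >= 1
        moderate, 2 predominantly moderate, 2 with >= 1 poor."""
        summary = cohort_report(load_reference_cohort())
        assert summary.n_patients == 10
        assert summary.patients_excellent_ge1 == 8
        assert summary.patients_excellent_ge2 == 7
        assert summary.patients_moderate_ge1 == 4
        assert summary.patients_predominantly_moderate == 2
        assert summary.patients_poor_ge1 == 2

    def test_unevaluable_rows_are_ignored(self):
        df = load_reference_cohort()
        assert (df["overlap_class"] == "unevaluable").sum() == 1
        assert cohort_report(df).n_cases == len(df) - 1

    def test_single_patient_all_poor(self):
        import pandas as pd

        df = pd.DataFrame({
            "patient_id": ["p1"] * 3,
            "timepoint_id": ["t1", "t2", "t3"],
            "overlap_class": ["poor"] * 3,
        })
        s = cohort_report(df)
        assert s.patients_excellent_ge1 == 0
        assert s.patients_moderate_ge1 == 0
        assert s.patients_poor_ge1 == 1

    def test_mean_overlap_uses_percent_column_when_present(self):
        import pandas as pd

        df = pd.DataFrame({
            "patient_id": ["p1", "p1", "p2"],
            "timepoint_id": ["t1", "t2", "t1"],
            "overlap_class": ["excellent", "moderate", "poor"],
            "overlap_percent": [95.0, 65.0, 20.0],
        })
        assert cohort_report(df).mean_overlap_percent == pytest.approx(60.0)
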