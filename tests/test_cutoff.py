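"""ROC analysis: curve conventions, AUC oracles, cutoff selection, CIs.

Independent oracles: brute-force tie-aware Mann-Whitney pairwise counting,
sklearn's roc_auc_score, the closed-form binormal AUC, statsmodels'
Clopper-Pearson implementation, and exhaustive threshold enumeration.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from qt1map import (
    AnalysisError,
    build_samples,
    optimal_cutoff,
    roc_analysis,
    roc_curve,
    samples_from_arrays,
)
from qt1map.cutoff import clopper_pearson, stratified_bootstrap_cis

from conftest import rim_seed


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Brute-force tie-aware AUC: pairwise wins + half credit for ties."""
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestRocCurve:
    def test_perfect_separation(self):
        s = samples_from_arrays(np.full(5, 3000.0), np.full(7, 1000.0))
        roc = roc_analysis(s)
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0
        assert 1000.0 <= roc.optimal_cutoff_ms < 3000.0

    def test_exhaustive_enumeration_two_per_class(self):
        """Values 1,2 vs 3,4: every threshold enumerated by hand gives cutoff 2."""
        s = samples_from_arrays([3.0, 4.0], [1.0, 2.0])
        roc = roc_analysis(s)
        assert roc.optimal_cutoff_ms == 2.0
        assert roc.youden_j == pytest.approx(1.0)

    def test_trapezoid_auc_equals_brute_force_mann_whitney(self):
        """50 random tables with heavy ties: agreement to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_pos = int(rng.integers(2, 100))
            n_neg = int(rng.integers(2, 100))
            # integer-valued samples force ties within and across classes
            pos = rng.integers(1000, 1040, n_pos).astype(float)
            neg = rng.integers(990, 1030, n_neg).astype(float)
            roc = roc_curve(samples_from_arrays(pos, neg))
            assert roc.auc == pytest.approx(_mann_whitney_auc(pos, neg), abs=1e-12)

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(2600.0, 300.0, 500)
        neg = rng.normal(1600.0, 300.0, 700)
        roc = roc_curve(samples_from_arrays(pos, neg))
        y = np.r_[np.ones(500), np.zeros(700)]
        assert roc.auc == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-10)

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2000.0, 400.0, 300)
        b = rng.normal(1700.0, 350.0, 400)
        auc = roc_curve(samples_from_arrays(a, b)).auc
        swapped = roc_curve(samples_from_arrays(b, a)).auc
        assert swapped == pytest.approx(1.0 - auc, abs=1e-12)

    def test_sensitivity_specificity_monotone_in_threshold(self):
        rng = np.random.default_rng(17)
        roc = roc_curve(samples_from_arrays(rng.normal(2600, 300, 200),
                                            rng.normal(1600, 300, 200)))
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)
        assert np.all(np.diff(roc.specificity) >= -1e-12)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(23)
        values = rng.normal(2000.0, 400.0, 20_000)
        half = rng.permutation(20_000) < 10_000
        roc = roc_curve(samples_from_arrays(values[half], values[~half]))
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_one_class_input_rejected(self):
        df = pd.DataFrame({"patient_id": "p", "timepoint_id": "t",
                           "qT1_pre_ms": [1.0, 2.0], "label": "tumor"})
        with pytest.raises(AnalysisError):
            roc_curve(df)


class TestBinormalClosedForm:
    def test_auc_and_cutoff_match_theory(self):
        """N(2600,300^2) vs N(1600,300^2): AUC -> Phi(1000/(300 sqrt 2)),
        Youden cutoff -> the equal-variance midpoint 2100."""
        rng = np.random.default_rng(123)
        s = samples_from_arrays(rng.normal(2600.0, 300.0, 10_000),
                                rng.normal(1600.0, 300.0, 10_000))
        roc = roc_analysis(s)
        assert roc.auc == pytest.approx(norm.cdf(1000.0 / (300.0 * np.sqrt(2))), abs=0.01)
        assert roc.optimal_cutoff_ms == pytest.approx(2100.0, abs=50.0)


class TestIntervalEstimates:
    @pytest.mark.parametrize("k, n", [(0, 20), (20, 20), (86, 100), (7, 9), (50, 100)])
    def test_clopper_pearson_matches_statsmodels(self, k, n):
        lo, hi = clopper_pearson(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(sm_lo, abs=1e-10)
        assert hi == pytest.approx(sm_hi, abs=1e-10)

    def test_perfect_separation_cis_degenerate_at_one(self):
        s = samples_from_arrays(np.full(50, 3000.0), np.full(60, 1000.0))
        roc = roc_analysis(s)
        lo, hi = roc.sens_ci
        assert hi == 1.0 and lo == pytest.approx(clopper_pearson(50, 50)[0])
        assert roc.p_value < 1e-4

    def test_auc_se_and_p_value_attached(self):
        rng = np.random.default_rng(2)
        s = samples_from_arrays(rng.normal(2600, 300, 200), rng.normal(1600, 300, 200))
        roc = roc_analysis(s)
        assert 0.0 < roc.auc_se < 0.05
        assert roc.auc_ci[0] < roc.auc < roc.auc_ci[1]
        assert roc.p_value < 1e-6

    def test_stratified_bootstrap_brackets_point_estimates(self):
        rng = np.random.default_rng(31)
        frames = [
            samples_from_arrays(rng.normal(2600, 300, 300), rng.normal(1600, 300, 300),
                                patient_id=f"p{i}")
            for i in range(4)
        ]
        samples = pd.concat(frames, ignore_index=True)
        point = roc_analysis(samples)
        cis = stratified_bootstrap_cis(samples, n_boot=100, rng_seed=8)
        lo, hi = cis["auc"]["ci95"]
        assert lo <= point.auc <= hi


@settings(max_examples=30, deadline=None)
@given(
    pos=st.lists(st.integers(1, 50), min_size=2, max_size=40),
    neg=st.lists(st.integers(1, 50), min_size=2, max_size=40),
)
def test_auc_always_equals_mann_whitney(pos, neg):
    """Property: trapezoidal AUC == tie-aware pairwise counting, any table."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    roc = roc_curve(samples_from_arrays(pos, neg))
    assert roc.auc == pytest.approx(_mann_whitney_auc(pos, neg), abs=1e-12)


class TestBuildSamples:
    def test_phantom_bookkeeping(self, noiseless_bundle, noiseless_maps):
        """Tumor rows = converged rim voxels; surround drawn from the 10 mm band."""
        b = noiseless_bundle
        pre = noiseless_maps["pre"]
        rim = b.masks["enhancing_rim"]
        df = build_samples(pre, rim, b.masks["brain"], vessel_mask=b.masks["vessels"])
        n_rim_fitted = int((rim & np.isfinite(pre.t1)).sum())
        assert (df["label"] == "tumor").sum() == n_rim_fitted
        assert (df["label"] == "surround").sum() > 0

    def test_band_covering_whole_brain_is_brain_minus_tumor_minus_vessels(
        self, noiseless_bundle, noiseless_maps
    ):
        b = noiseless_bundle
        pre = noiseless_maps["pre"]
        rim = b.masks["enhancing_rim"]
        df = build_samples(pre, rim, b.masks["brain"], vessel_mask=b.masks["vessels"],
                           band_width_mm=1000.0)
        expected = b.masks["brain"] & ~rim & ~b.masks["vessels"] & np.isfinite(pre.t1)
        assert (df["label"] == "surround").sum() == int(expected.sum())

    def test_subsampling_is_reproducible(self, noiseless_bundle, noiseless_maps):
        b = noiseless_bundle
        kwargs = dict(
            tumor_mask=b.masks["enhancing_rim"], brain_mask=b.masks["brain"],
            max_per_class=100, rng_seed=4,
        )
        a = build_samples(noiseless_maps["pre"], **kwargs)
        c = build_samples(noiseless_maps["pre"], **kwargs)
        assert (a["label"] == "tumor").sum() == 100
        pd.testing.assert_frame_equal(a, c)

    def test_empty_tumor_mask_rejected(self, noiseless_bundle, noiseless_maps):
        with pytest.raises(AnalysisError):
            build_samples(noiseless_maps["pre"],
                          np.zeros((32, 32, 32), dtype=bool),
                          noiseless_bundle.masks["brain"])


class TestPipelineLevelRecovery:
    def test_phantom_cutoff_falls_in_truth_gap(self, noisy_bundle, noisy_maps):
        """Tumor qT1 in [2100, 3100], surroundings < 2000: the recovered
        cutoff must land in the (2000, 2100) gap with sens/spec >= 0.95."""
        b = noisy_bundle
        df = build_samples(noisy_maps["pre"], b.masks["enhancing_rim"],
                           b.masks["brain"], vessel_mask=b.masks["vessels"])
        roc = roc_analysis(df)
        assert 2000.0 < roc.optimal_cutoff_ms < 2100.0
        assert roc.sens_at_cutoff >= 0.95
        assert roc.spec_at_cutoff >= 0.95
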