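"""Evaluation statistics and survival machinery: exact self-consistency
checks and recovery of planted generative parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiodl.survival import (SurvivalTable, concordance_index, cox_stratified,
                              median_stratified, responder_auc, seg_metrics,
                              spearman_corr, three_class_stratified,
                              threshold_scan)
from angiodl.synth import make_survival_cohort


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self, rng):
        x = rng.normal(0, 1, 30)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, p = spearman_corr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_invariance_under_strictly_monotone_maps(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        base = spearman_corr(x, y)[0]
        assert spearman_corr(np.exp(2 * x), y)[0] == pytest.approx(base)
        assert spearman_corr(x, y**3 + 5 * y)[0] == pytest.approx(base)


class TestSegMetrics:
    def test_identical_masks_are_perfect(self, rng):
        m = rng.integers(0, 2, (16, 16))
        assert seg_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((4, 4), int)
        a[:2] = 1
        b = 1 - a
        assert seg_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_halo_overlap_arithmetic(self):
        truth = np.zeros((10, 10), int)
        truth[:, :2] = 1              # 20 positive pixels
        pred = np.zeros((10, 10), int)
        pred[:, :4] = 1               # covers truth plus equal-area halo
        p, r, f1 = seg_metrics(pred, truth)
        assert (p, r, f1) == (0.5, 1.0, pytest.approx(2 / 3))

    def test_f1_is_harmonic_mean(self, rng):
        pred = rng.integers(0, 2, (20, 20))
        truth = rng.integers(0, 2, (20, 20))
        p, r, f1 = seg_metrics(pred, truth)
        assert f1 == pytest.approx(2 * p * r / (p + r))

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            seg_metrics(np.ones((4, 4), int), np.zeros((4, 4), int))


class TestResponderAuc:
    def test_perfect_separation(self):
        auc, ci = responder_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                n_boot=200, seed=0)
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(0, 1, 1000)
        labels = rng.integers(0, 2, 1000)
        auc, _ = responder_auc(scores, labels, n_boot=50, seed=1)
        assert 0.45 <= auc <= 0.55

    def test_sign_symmetry(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        a1, _ = responder_auc(scores, labels, n_boot=50, seed=2)
        a2, _ = responder_auc(-scores, labels, n_boot=50, seed=2)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            responder_auc([1, 2, 3], [1, 1, 1])


class TestConcordance:
    def test_perfect_ranking_no_censoring(self):
        t = SurvivalTable.from_arrays([f"p{i}" for i in range(10)],
                                      np.arange(1.0, 11.0), np.ones(10, int),
                                      np.arange(10.0))
        assert concordance_index(t.df["score"], t) == 1.0

    def test_null_scores_near_half(self):
        t = make_survival_cohort(1000, beta=0.0, seed=7)
        assert abs(concordance_index(t.df["score"], t) - 0.5) <= 0.03

    def test_score_reversal_complements(self):
        t = make_survival_cohort(200, beta=1.0, seed=8)
        c = concordance_index(t.df["score"], t)
        assert concordance_index(-t.df["score"], t) == pytest.approx(1 - c)


class TestCoxStratified:
    def test_recovers_planted_group_hazard_ratio(self):
        scores = np.repeat([0.0, 1.0], 250)
        t = make_survival_cohort(500, beta=-np.log(2.0), censor_rate=0.2,
                                 score_source=scores, seed=5)
        res = cox_stratified(t, threshold=0.5)
        assert 1.6 <= res.hazard_ratio <= 2.5
        assert res.hr_ci[0] <= res.hazard_ratio <= res.hr_ci[1]
        assert res.logrank_p < 0.01

    def test_null_cohort_gives_unit_hazard_ratio(self):
        t = make_survival_cohort(600, beta=0.0, seed=6)
        res = cox_stratified(t, threshold=float(t.df["score"].median()))
        assert 0.8 <= res.hazard_ratio <= 1.25
        assert res.logrank_p > 0.05

    def test_empty_group_is_error(self):
        t = make_survival_cohort(50, beta=0.0, seed=1)
        with pytest.raises(ValueError):
            cox_stratified(t, threshold=t.df["score"].max() + 10)

    def test_km_curves_exported_per_group(self):
        t = make_survival_cohort(100, beta=0.5, seed=2)
        res = median_stratified(t)
        assert set(res.km_curves) == {"low", "high"}
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)   # KM is non-increasing

    def test_three_class_uses_external_cutoffs(self):
        scores = np.concatenate([np.full(80, 0.0), np.full(80, 1.0), np.full(80, 2.0)])
        t = make_survival_cohort(240, beta=-0.8, censor_rate=0.1,
                                 score_source=scores, seed=3)
        res = three_class_stratified(t, low_threshold=0.5, high_threshold=1.5)
        assert set(res.groups.unique()) == {"low", "medium", "high"}
        assert res.hazard_ratio > 1.0   # high-score group has higher hazard here


class TestThresholdScan:
    def test_planted_boundary_recovered_within_one_step(self):
        rng = np.random.default_rng(1)
        low = rng.uniform(-2.5, -1.0, 150)
        high = rng.uniform(1.0, 2.5, 150)
        t = make_survival_cohort(300, beta=0.6, censor_rate=0.1,
                                 score_source=np.concatenate([low, high]),
                                 seed=6)
        scan = threshold_scan(t.df["score"], t, n_grid=25)
        step = scan.thresholds[1] - scan.thresholds[0]
        assert len(scan.peak_thresholds) >= 1
        # a detected p-minimum must sit within one step of the thresholds
        # that split the two planted populations exactly
        assert min(max(low.max() - th, th - high.min(), 0.0)
                   for th in scan.peak_thresholds) <= step

    def test_null_cohort_rarely_significant(self):
        hits = 0
        for seed in range(8):
            t = make_survival_cohort(200, beta=0.0, seed=100 + seed)
            scan = threshold_scan(t.df["score"], t, n_grid=20)
            if np.nanmin(scan.logrank_p) < 0.01:
                hits += 1
        assert hits <= 1

    def test_three_planted_strata_give_two_minima(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(-3, 0.5, 120), rng.normal(0, 0.5, 120),
                                 rng.normal(3, 0.5, 120)])
        t = make_survival_cohort(360, beta=0.7, censor_rate=0.1,
                                 score_source=scores, seed=9)
        scan = threshold_scan(t.df["score"], t, n_grid=30)
        assert len(scan.peak_indices) >= 2
        peaks = np.sort(scan.peak_thresholds[:2] if len(scan.peak_thresholds) == 2
                        else scan.peak_thresholds)
        assert peaks.min() < 0 < peaks.max()

    def test_degenerate_grid_rejected(self):
        t = make_survival_cohort(50, beta=0.0, seed=4)
        with pytest.raises(ValueError):
            threshold_scan(t.df["score"], t, n_grid=1)


def test_survival_table_invariants():
    with pytest.raises(ValueError, match="positive"):
        SurvivalTable.from_arrays(["a", "b"], [0.0, 1.0], [1, 1], [0.1, 0.2])
    with pytest.raises(ValueError, match="duplicate"):
        SurvivalTable.from_arrays(["a", "a"], [1.0, 1.0], [1, 1], [0.1, 0.2])
    with pytest.raises(ValueError, match="event"):
        SurvivalTable.from_arrays(["a", "b"], [1.0, 1.0], [1, 2], [0.1, 0.2])
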