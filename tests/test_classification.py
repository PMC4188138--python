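"""ROC/AUC via ranks, DeLong confidence intervals and the paired AUC test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import icvnorm as iv


class TestRocAuc:
    def test_complete_separation(self):
        res = iv.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        res = iv.roc_auc(scores, labels, orientation="as_is")
        assert res.auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize(
        "scores, expected",
        [((1, 2, 3, 4), 1.0), ((1, 3, 2, 4), 0.75)],
    )
    def test_brute_force_pair_count(self, scores, expected):
        # exhaustive over the 4 case-control pairs
        assert iv.roc_auc(scores, (0, 0, 1, 1)).auc == expected

    def test_auto_orientation_flips_atrophy_marker(self):
        # cases (label 1) have *smaller* scores, as atrophied volumes do
        res = iv.roc_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.flipped
        assert res.auc == 1.0
        as_is = iv.roc_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1], orientation="as_is")
        assert as_is.auc == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            iv.roc_auc([1.0, 2.0], [1, 1])

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(21)
        scores = rng.integers(0, 20, 500).astype(float)  # plenty of ties
        labels = rng.integers(0, 2, 500)
        ours = iv.roc_auc(scores, labels, orientation="as_is").auc
        theirs = sklearn_metrics.roc_auc_score(labels, scores)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_mann_whitney_u_equivalence_random_instances(self):
        """AUC == U/(n_pos*n_neg) exactly, including ties (shared convention)."""
        rng = np.random.default_rng(22)
        for _ in range(300):
            n_pos, n_neg = rng.integers(2, 12, size=2)
            scores = rng.integers(0, 6, size=n_pos + n_neg).astype(float)
            labels = np.r_[np.zeros(n_neg, int), np.ones(n_pos, int)]
            auc = iv.roc_auc(scores, labels, orientation="as_is").auc
            u = iv.mann_whitney(scores[labels == 1], scores[labels == 0]).u
            assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_ci_coverage_calibration(self):
        """95% DeLong CI covers the true AUC in 93-97% of 500 simulations."""
        rng = np.random.default_rng(23)
        true_auc = norm.cdf(1 / np.sqrt(2))  # unit normal shift of 1
        covered = 0
        for _ in range(500):
            scores = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
            labels = np.repeat([0, 1], 100)
            res = iv.roc_auc(scores, labels)
            covered += res.ci_low <= true_auc <= res.ci_high
        assert 0.93 <= covered / 500 <= 0.97


class TestComparePaired:
    def test_self_comparison_null(self):
        rng = np.random.default_rng(24)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        res = iv.compare_auc_paired(scores, scores, labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        transformed = np.exp(scores / 3.0) + 5.0  # strictly increasing map
        res = iv.compare_auc_paired(scores, transformed, labels)
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """No true AUC gap between correlated markers: rejections in [0.02, 0.08]."""
        rng = np.random.default_rng(25)
        rejections = 0
        for _ in range(200):
            base = rng.normal(size=200)
            labels = np.repeat([0, 1], 100)
            s1 = base + rng.normal(size=200)
            s2 = base + rng.normal(size=200)
            rejections += iv.compare_auc_paired(s1, s2, labels).p < 0.05
        assert 0.02 <= rejections / 200 <= 0.08

    def test_planted_gap_has_power(self):
        """AUC gap of ~0.10 at n=300/group: majority rejection across 100 seeds."""
        rejections = 0
        n = 300
        for seed in range(100):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], n)
            signal = np.r_[np.zeros(n), np.full(n, 1.2)]
            s1 = signal + rng.normal(size=2 * n)  # stronger marker
            s2 = 0.4 * signal + rng.normal(size=2 * n)
            rejections += iv.compare_auc_paired(s1, s2, labels).p < 0.05
        assert rejections / 100 > 0.5

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            iv.compare_auc_paired([1, 2], [1, 2, 3], [0, 1])


class TestDiagnosticTable:
    def test_three_contrasts_three_modes(self, adni_adjusted):
        out = iv.diagnostic_auc_table(adni_adjusted, "hippocampus")
        assert len(out) == 3
        for cmp_ in out:
            assert list(cmp_.per_mode["mode"]) == ["raw", "proportion", "residual"]
            assert (cmp_.per_mode["ci_low"] <= cmp_.per_mode["auc"]).all()
            assert (cmp_.per_mode["auc"] <= cmp_.per_mode["ci_high"]).all()
            assert len(cmp_.pairwise) == 3
            assert cmp_.pairwise["p"].between(0, 1).all()

    def test_atrophy_marker_is_informative_and_oriented(self, adni_adjusted):
        out = iv.diagnostic_auc_table(adni_adjusted, "hippocampus", [("CTL", "AD")])
        per_mode = out[0].per_mode
        assert per_mode["flipped"].all()  # smaller hippocampus marks disease
        assert (per_mode["auc"] > 0.7).all()

    def test_empty_contrast_label_errors(self, adni_adjusted):
        with pytest.raises(ValueError, match="empty label"):
            iv.diagnostic_auc_table(adni_adjusted, "hippocampus", [("CTL", "")])
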