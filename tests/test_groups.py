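"""Welch comparisons, Bonferroni direction calls, ICV matching, Mann-Whitney,
and the bootstrap-t sampling distribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

import icvnorm as iv
from icvnorm.groups import round_half_away, welch_t_from_summary

from conftest import single_region_cohort


class TestWelch:
    def test_zero_numerator(self):
        assert welch_t_from_summary(10, 2, 30, 10, 3, 30).t == 0.0

    def test_sign_convention_second_group_positive(self):
        assert welch_t_from_summary(10, 2, 30, 12, 2, 30).t > 0

    def test_satterthwaite_df_bounded(self):
        res = welch_t_from_summary(10, 2, 30, 12, 5, 40)
        assert res.df <= 30 + 40 - 2

    def test_agrees_with_scipy_on_raw_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 25), rng.normal(0.5, 2, 35)
        ours = iv.welch_t(x, y)
        from scipy import stats
        ref = stats.ttest_ind(y, x, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic)
        assert ours.p_raw == pytest.approx(ref.pvalue)

    def test_both_sds_zero_errors(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0, 10, 2, 0, 10)


class TestCompareGroups:
    @staticmethod
    def _two_group_cohort(rng, n=60, shift=0.0):
        vals = np.concatenate([rng.normal(3000, 100, n), rng.normal(3000 + shift, 100, n)])
        icv = rng.normal(1.5e6, 1e5, 2 * n)
        return single_region_cohort(vals, icv, genders=["F"] * n + ["M"] * n)

    def test_bonferroni_cap_and_identity(self):
        rng = np.random.default_rng(1)
        cohort = self._two_group_cohort(rng)
        adj = iv.apply_raw(cohort)
        table_1 = iv.compare_groups(adj, family=["vol"]).table
        assert table_1["p_adj"].iloc[0] == pytest.approx(table_1["p_raw"].iloc[0])
        big = iv.compare_groups(adj, family=["vol"] * 1)  # family of 1: identity
        assert big.family_size == 1

    def test_bonferroni_monotone_and_order_invariant(self, pivus_small):
        adj = iv.apply_raw(pivus_small)
        fam = list(pivus_small.regions)
        fwd = iv.compare_groups(adj, family=fam).table.set_index("region")
        rev = iv.compare_groups(adj, family=fam[::-1]).table.set_index("region")
        assert (fwd["p_adj"] >= fwd["p_raw"]).all()
        pd.testing.assert_series_equal(fwd["p_adj"].sort_index(), rev["p_adj"].sort_index())

    def test_planted_male_effect_direction(self):
        rng = np.random.default_rng(2)
        cohort = self._two_group_cohort(rng, n=200, shift=400.0)
        table = iv.compare_groups(iv.apply_raw(cohort), family=["vol"]).table
        assert table["direction"].iloc[0] == "M>F"

    def test_requires_exactly_two_levels(self, adni_small):
        with pytest.raises(ValueError, match="2 levels"):
            iv.compare_groups(iv.apply_raw(adni_small), group_col="diagnosis")

    def test_alpha_one_edge(self):
        rng = np.random.default_rng(3)
        cohort = self._two_group_cohort(rng)
        table = iv.compare_groups(iv.apply_raw(cohort), family=["vol"], alpha=1.0).table
        assert table["direction"].iloc[0] != "none"  # any t != 0 gets a call


def test_direction_table_mismatched_regions_error(pivus_small):
    adj = iv.apply_raw(pivus_small)
    full = iv.compare_groups(adj, family=list(pivus_small.regions))
    partial = iv.compare_groups(adj, family=["hippocampus"])
    with pytest.raises(ValueError, match="region set"):
        iv.direction_table({"raw": full, "proportion": partial})


class TestMatchByICV:
    def test_identical_groups_full_selection(self):
        icv = [1.4e6, 1.45e6, 1.41e6, 1.44e6]
        cohort = single_region_cohort(
            [100] * 8, list(icv) + list(icv), genders=["F"] * 4 + ["M"] * 4
        )
        sub = iv.match_by_icv(cohort, k=4, rel_sd_max=0.05)
        stats = sub.stats.set_index("level")
        assert stats.loc["F", "icv_mean"] == pytest.approx(stats.loc["M", "icv_mean"])

    def test_matched_subset_much_tighter_than_raw_gap(self, pivus_small):
        sub = iv.match_by_icv(pivus_small, k=21, rel_sd_max=0.01)
        stats = sub.stats.set_index("level")
        assert (stats["icv_rel_sd"] < 0.01).all()
        raw_gap = (
            pivus_small.data.groupby("gender")["icv"].mean().diff().abs().iloc[-1]
        )
        matched_gap = abs(stats.loc["F", "icv_mean"] - stats.loc["M", "icv_mean"])
        assert matched_gap < raw_gap / 20
        # exhaustive check of the emitted subset's statistics
        for level in ("F", "M"):
            icv = pivus_small.data.set_index("subject_id").loc[sub.ids[level], "icv"]
            assert len(icv) == 21
            assert icv.std(ddof=1) / icv.mean() == pytest.approx(
                stats.loc[level, "icv_rel_sd"]
            )

    def test_k_zero_errors(self, pivus_small):
        with pytest.raises(ValueError):
            iv.match_by_icv(pivus_small, k=0)

    def test_infeasible_bound_reports_best(self):
        rng = np.random.default_rng(4)
        cohort = single_region_cohort(
            [100] * 40, rng.normal(1.5e6, 3e5, 40), genders=["F"] * 20 + ["M"] * 20
        )
        with pytest.raises(ValueError, match="best achievable"):
            iv.match_by_icv(cohort, k=15, rel_sd_max=1e-5)


class TestMannWhitney:
    def test_complete_separation(self):
        assert iv.mann_whitney([1, 2], [3, 4]).u == 0.0
        assert iv.mann_whitney([3, 4], [1, 2]).u == 4.0

    def test_enumeration_oracle_small(self):
        """U equals the pair count #(x > y) + half ties, enumerated directly."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 8, size=rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(2, 6)).astype(float)
            expected = sum(
                1.0 if xi > yi else 0.5 if xi == yi else 0.0
                for xi, yi in itertools.product(x, y)
            )
            assert iv.mann_whitney(x, y).u == pytest.approx(expected)

    def test_identical_samples_p_near_one(self):
        res = iv.mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p > 0.9

    def test_exact_vs_asymptotic_agreement(self):
        """No-ties n=20 per arm: the two p-value paths agree within 0.01."""
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.3, 1, 20)
        exact = iv.mann_whitney(x, y)  # 400 products -> exact path
        assert exact.method == "exact"
        from scipy import stats
        asym = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert exact.p == pytest.approx(asym.pvalue, abs=0.01)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            iv.mann_whitney([], [1.0])


class TestBootstrapT:
    @staticmethod
    def _matched(rng, k=21, shift=0.0):
        vals = np.concatenate([rng.normal(3000, 300, k), rng.normal(3000 + shift, 300, k)])
        icv = rng.normal(1.5e6, 5e3, 2 * k)
        cohort = single_region_cohort(vals, icv, genders=["F"] * k + ["M"] * k)
        sub = iv.match_by_icv(cohort, k=k, rel_sd_max=0.05)
        return cohort, sub

    def test_same_seed_identical_replicates(self):
        rng = np.random.default_rng(7)
        cohort, sub = self._matched(rng)
        a = iv.bootstrap_t(sub, cohort, "vol", n_boot=500, seed=42)
        b = iv.bootstrap_t(sub, cohort, "vol", n_boot=500, seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        assert a.p_sim == b.p_sim

    def test_large_planted_effect_rejects(self):
        rng = np.random.default_rng(8)
        cohort, sub = self._matched(rng, shift=600.0)
        res = iv.bootstrap_t(sub, cohort, "vol", n_boot=2000, seed=1)
        assert res.p_sim * 17 < 0.05  # survives a subcortical-family Bonferroni

    def test_null_type_one_calibration(self):
        """Identical group distributions: rejection rate at 0.05 stays in [0.02, 0.08]."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cohort, sub = self._matched(rng)
            res = iv.bootstrap_t(sub, cohort, "vol", n_boot=2000, seed=rep)
            rejections += res.p_sim < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_n_boot_minimum(self):
        rng = np.random.default_rng(10)
        cohort, sub = self._matched(rng)
        with pytest.raises(ValueError):
            iv.bootstrap_t(sub, cohort, "vol", n_boot=50)


@pytest.mark.parametrize(
    "x, decimals, expected",
    [
        (7.046, 1, 7.0),
        (8.91, 1, 8.9),
        (-5.44, 1, -5.4),
        (2.5, 0, 3.0),  # half away from zero, unlike banker's rounding
        (-2.5, 0, -3.0),
        (0.066, 2, 0.07),
    ],
)
def test_round_half_away(x, decimals, expected):
    assert round_half_away(x, decimals) == expected
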