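"""Score~volume regressions, volume~ICV+age fits, ANOVA with Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import icvnorm as iv
from icvnorm.cognition import RankDeficientError

from conftest import single_region_cohort


def _raw_like(cohort):
    from icvnorm.normalization import AdjustedCohort
    return AdjustedCohort(cohort, "raw")


def _with_score(cohort, score):
    """Attach a score column and wrap as a raw-mode adjusted cohort."""
    from icvnorm.normalization import _wrap_unvalidated
    df = cohort.data.copy()
    df["score"] = np.asarray(score, dtype=float)
    return _raw_like(_wrap_unvalidated(df, cohort.regions, ("score",)))


class TestScoreModel:
    def test_perfect_linear_score_r2_one(self, pivus_small):
        adj = _with_score(pivus_small, 2.0 + 0.001 * pivus_small.data["hippocampus"])
        fit = iv.fit_score_model(adj, "score", "hippocampus")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["hippocampus"] == pytest.approx(0.001)

    def test_null_score_r2_near_zero(self):
        rng = np.random.default_rng(12)
        n = 5000
        cohort = single_region_cohort(
            rng.normal(3000, 300, n), rng.normal(1.5e6, 1e5, n)
        )
        adj = _with_score(cohort, rng.normal(size=n))
        fit = iv.fit_score_model(adj, "score", "vol")
        assert fit.r_squared < 0.01

    def test_planted_interaction_improves_r2(self):
        """Score built from volume*(1 + c*ICV): the interaction model must win."""
        rng = np.random.default_rng(13)
        n = 2000
        icv = rng.normal(1.5e6, 1.5e5, n)
        vol = 1000 + 1.5e-3 * icv + rng.normal(0, 300, n)
        cohort = single_region_cohort(vol, icv)
        score = 1e-3 * vol * (1 + 2e-6 * (icv - icv.mean())) + rng.normal(0, 0.3, n)
        adj = _with_score(cohort, score)
        plain = iv.fit_score_model(adj, "score", "vol")
        inter = iv.fit_score_model(adj, "score", "vol", with_interaction=True)
        assert inter.r_squared > plain.r_squared

    def test_nested_model_r2_never_decreases(self, adni_adjusted):
        plain = iv.fit_score_model(adni_adjusted["raw"], "adas_word_recall", "hippocampus")
        inter = iv.fit_score_model(
            adni_adjusted["raw"], "adas_word_recall", "hippocampus", with_interaction=True
        )
        assert inter.r_squared >= plain.r_squared

    def test_rank_deficiency_named(self):
        cohort = single_region_cohort([100.0] * 30, [1.5e6] * 30)
        adj = _with_score(cohort, np.arange(30.0))
        with pytest.raises(RankDeficientError, match="vol"):
            iv.fit_score_model(adj, "score", "vol")

    def test_missing_column_errors(self, adni_adjusted):
        with pytest.raises(KeyError):
            iv.fit_score_model(adni_adjusted["raw"], "no_such_score", "hippocampus")


class TestVoiOnIcvAge:
    def test_exact_linear_fit(self):
        icv = np.linspace(1.2e6, 1.8e6, 50)
        cohort = single_region_cohort(200.0 + 2e-3 * icv, icv)
        fit = iv.fit_voi_on_icv_age(cohort, "vol")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["icv"] == pytest.approx(2e-3)

    def test_constant_age_drops_age_term(self, pivus_small):
        fit = iv.fit_voi_on_icv_age(pivus_small, "hippocampus")
        assert "age" not in fit.terms

    def test_variable_age_keeps_age_term(self, adni_small):
        fit = iv.fit_voi_on_icv_age(adni_small, "hippocampus", group="CTL")
        assert "age" in fit.terms

    def test_volume_independent_of_predictors(self):
        rng = np.random.default_rng(14)
        n = 5000
        cohort = single_region_cohort(
            rng.normal(3000, 300, n), rng.normal(1.5e6, 1e5, n)
        )
        fit = iv.fit_voi_on_icv_age(cohort, "vol")
        assert fit.r_squared < 0.01


class TestAnovaTukey:
    @staticmethod
    def _three_group_cohort(offsets=(0.0, -300.0, -600.0), n=200, noise=150.0, seed=15):
        rng = np.random.default_rng(seed)
        frames = []
        for dx, off in zip(("CTL", "MCI", "AD"), offsets):
            frames.append(pd.DataFrame({
                "subject_id": [f"{dx}{i}" for i in range(n)],
                "gender": "F", "age": 75.0, "diagnosis": dx,
                "icv": rng.normal(1.5e6, 1e5, n),
                "vol": rng.normal(3400 + off, noise, n),
            }))
        from icvnorm.normalization import _wrap_unvalidated
        return _raw_like(_wrap_unvalidated(pd.concat(frames, ignore_index=True), ("vol",), ()))

    def test_identical_groups_f_zero(self):
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(9)],
            "gender": "F", "age": 75.0,
            "diagnosis": ["CTL"] * 3 + ["MCI"] * 3 + ["AD"] * 3,
            "icv": 1.5e6,
            "vol": [3000.0, 3100.0, 3200.0] * 3,
        })
        from icvnorm.normalization import _wrap_unvalidated
        res = iv.anova_tukey(_raw_like(_wrap_unvalidated(df, ("vol",), ())), "vol")
        assert res.f == pytest.approx(0.0)

    def test_planted_separation_all_pairs_significant(self):
        res = iv.anova_tukey(self._three_group_cohort(), "vol")
        assert res.p < 1e-6
        assert len(res.pairwise) == 3  # g(g-1)/2 for g=3
        assert (res.pairwise["p_adj"] < 0.05).all()
        assert (res.pairwise["p_adj"] >= 0.0).all()

    def test_two_groups_tukey_equals_pooled_t(self):
        """At g=2 the studentized-range q collapses to sqrt(2)*t, so the Tukey
        adjusted p equals the pooled two-sample t p."""
        rng = np.random.default_rng(16)
        adj = self._three_group_cohort(offsets=(0.0, -80.0), n=40, seed=16)
        two = adj.data[adj.data.diagnosis.isin(["CTL", "MCI"])]
        from icvnorm.normalization import _wrap_unvalidated
        res = iv.anova_tukey(
            _raw_like(_wrap_unvalidated(two.reset_index(drop=True), ("vol",), ())), "vol"
        )
        x = two.loc[two.diagnosis == "CTL", "vol"]
        y = two.loc[two.diagnosis == "MCI", "vol"]
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert float(res.pairwise["p_adj"].iloc[0]) == pytest.approx(pooled.pvalue, abs=1e-3)

    def test_single_group_errors(self, pivus_small):
        with pytest.raises(ValueError):
            iv.anova_tukey(iv.apply_raw(pivus_small), "hippocampus")
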