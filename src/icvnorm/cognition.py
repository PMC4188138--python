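"""Volume-cognition regressions and across-diagnosis ANOVA.

Three model families:

* score ~ adjusted regional volume (optionally + ICV + volume x ICV for raw
  volumes), compared across normalization modes by R^2;
* volume ~ ICV + age within a diagnostic group (ICV slope recovery);
* one-way ANOVA of a region across diagnoses with Tukey HSD post-hoc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

DEFAULT_SCORE = "adas_word_recall"


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; the message names the terms."""


@dataclass
class RegressionFit:
    formula: str
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    n: int
    resid_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "p": self.pvalues.to_numpy(),
        })


def _ols(y: np.ndarray, design: pd.DataFrame, formula: str) -> RegressionFit:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficientError(
            f"rank-deficient design for {formula!r}; collinear terms among {list(design.columns)}"
        )
    if len(y) <= x.shape[1] + 1:
        raise ValueError(f"need n > number of terms + 1 for {formula!r}")
    fit = sm.OLS(y, x).fit()
    terms = tuple(design.columns)
    idx = pd.Index(terms)
    return RegressionFit(
        formula=formula,
        terms=terms,
        params=pd.Series(fit.params, index=idx),
        bse=pd.Series(fit.bse, index=idx),
        pvalues=pd.Series(fit.pvalues, index=idx),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        resid_sd=float(np.sqrt(fit.mse_resid)),
    )


def fit_score_model(
    adjusted,
    score: str = DEFAULT_SCORE,
    region: str = "hippocampus",
    with_interaction: bool = False,
) -> RegressionFit:
    """OLS of a cognitive score on one (adjusted) regional volume.

    With ``with_interaction`` (meant for raw volumes) the design gains ICV
    and the volume x ICV product, probing whether the volume-cognition slope
    scales with head size.
    """
    df = adjusted.data
    for col in (score, region):
        if col not in df.columns:
            raise KeyError(f"column {col!r} absent from cohort")
    y = df[score].to_numpy(dtype=float)
    vol = df[region].to_numpy(dtype=float)
    design = pd.DataFrame({"intercept": np.ones_like(y), region: vol})
    formula = f"{score} ~ {region}"
    if with_interaction:
        icv = df["icv"].to_numpy(dtype=float)
        design["icv"] = icv
        design[f"{region}:icv"] = vol * icv
        formula = f"{score} ~ {region} + icv + {region}:icv"
    return _ols(y, design, formula)


def fit_voi_on_icv_age(cohort, region: str, group=None) -> RegressionFit:
    """OLS of a regional volume on ICV and age within one diagnostic group.

    Cohorts with constant age (single-age designs) drop the age term with a
    logged notice, since it carries no information there.
    """
    sub = cohort if group is None else cohort.subset(group)
    df = sub.data
    if len(df) == 0:
        raise ValueError("selected group is empty")
    y = df[region].to_numpy(dtype=float)
    icv = df["icv"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    design = pd.DataFrame({"intercept": np.ones_like(y), "icv": icv})
    formula = f"{region} ~ icv"
    if np.ptp(age) > 0:
        design["age"] = age
        formula = f"{region} ~ icv + age"
    else:
        logger.info("age is constant in the selected group; fitting %s ~ icv only", region)
    return _ols(y, design, formula)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject


def anova_tukey(adjusted, region: str, group_col: str = "diagnosis", alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across groups with Tukey HSD pairwise post-hoc tests."""
    df = adjusted.data
    levels = list(pd.unique(df[group_col]))
    if len(levels) < 2:
        raise ValueError(f"{group_col!r} must have >= 2 levels, found {levels}")
    samples = [df.loc[df[group_col] == lvl, region].to_numpy(dtype=float) for lvl in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if np.ptp(np.concatenate(samples)) == 0:
        f_stat, p = 0.0, 1.0  # all values identical: no variance anywhere
    else:
        f_stat, p = stats.f_oneway(*samples)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
    tukey = pairwise_tukeyhsd(
        endog=df[region].to_numpy(dtype=float),
        groups=df[group_col].to_numpy(),
        alpha=alpha,
    )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    ).rename(columns={
        "group1": "group_a", "group2": "group_b",
        "meandiff": "mean_diff", "p-adj": "p_adj",
    })[["group_a", "group_b", "mean_diff", "p_adj", "reject"]]
    n = sum(s.size for s in samples)
    return AnovaResult(
        f=float(f_stat),
        df_between=len(levels) - 1,
        df_within=n - len(levels),
        p=float(p),
        pairwise=pairwise,
    )
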