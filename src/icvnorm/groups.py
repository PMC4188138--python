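"""Two-group regional comparisons and the ICV-matched subsampling battery.

Welch's unequal-variance t-test is used throughout, with Bonferroni
correction over the report family (by default the 17 subcortical and the 34
cortical regions form separate families).  The matched-subsample path
removes head-size variability by construction: select k subjects per group
whose ICV relative SD is below a bound (1% by default), compare with a
Mann-Whitney U-test, and calibrate the Welch t against a bootstrap null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention of printed report tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_raw: float


def welch_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> WelchResult:
    """Welch two-sample t from summary statistics.

    Sign convention: positive t when group B (second) exceeds group A.
    Degrees of freedom by Welch-Satterthwaite; two-sided p.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_b - mean_a) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_raw=p)


def welch_t(x, y) -> WelchResult:
    """Welch t from raw samples; positive when the second sample is larger."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


# ---------------------------------------------------------------------------
# per-region comparison tables
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonTable:
    """Per-region Welch comparisons with Bonferroni adjustment."""

    table: pd.DataFrame  # region, mean/sd/n per level, t, df, p_raw, p_adj, direction
    levels: tuple[str, str]  # (A, B); t > 0 means B > A
    family_size: int
    alpha: float

    def directions(self) -> pd.Series:
        return self.table.set_index("region")["direction"]


def compare_groups(
    adjusted,
    group_col: str = "gender",
    family: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparisonTable:
    """Welch-compare the two levels of ``group_col`` for every family region.

    ``family`` is the Bonferroni family (defaults to every region of the
    cohort); the adjusted p is min(1, p_raw * family_size) and the direction
    call is made on the adjusted p at ``alpha``.
    """
    df = adjusted.data
    levels = sorted(pd.unique(df[group_col]))
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, found {levels}")
    a_lab, b_lab = levels
    regions = tuple(family) if family is not None else tuple(adjusted.regions)
    missing = [r for r in regions if r not in df.columns]
    if missing:
        raise KeyError(f"family regions absent from cohort: {missing}")
    m = len(regions)
    mask_a = (df[group_col] == a_lab).to_numpy()
    mask_b = ~mask_a
    rows = []
    for region in regions:
        v = df[region].to_numpy(dtype=float)
        xa, xb = v[mask_a], v[mask_b]
        res = welch_t(xa, xb)
        p_adj = min(1.0, res.p_raw * m)
        if p_adj < alpha:
            direction = f"{b_lab}>{a_lab}" if res.t > 0 else f"{a_lab}>{b_lab}"
        else:
            direction = "none"
        rows.append({
            "region": region,
            f"mean_{a_lab}": xa.mean(), f"sd_{a_lab}": xa.std(ddof=1), f"n_{a_lab}": xa.size,
            f"mean_{b_lab}": xb.mean(), f"sd_{b_lab}": xb.std(ddof=1), f"n_{b_lab}": xb.size,
            "t": res.t, "df": res.df, "p_raw": res.p_raw, "p_adj": p_adj,
            "direction": direction,
        })
    return GroupComparisonTable(
        table=pd.DataFrame(rows), levels=(a_lab, b_lab), family_size=m, alpha=alpha
    )


def direction_table(tables: dict[str, GroupComparisonTable]) -> pd.DataFrame:
    """Region x mode grid of direction calls, one column per mode."""
    region_sets = {mode: tuple(t.table["region"]) for mode, t in tables.items()}
    reference = next(iter(region_sets.values()))
    for mode, regions in region_sets.items():
        if set(regions) != set(reference):
            raise ValueError(f"mode {mode!r} covers a different region set")
    out = pd.DataFrame(index=pd.Index(reference, name="region"))
    for mode, t in tables.items():
        out[mode] = t.directions().reindex(reference)
    return out


# ---------------------------------------------------------------------------
# ICV matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedSubsample:
    """k-per-group selection with near-identical within-group ICVs."""

    group_col: str
    levels: tuple[str, str]
    ids: dict[str, list]  # level -> subject ids
    stats: pd.DataFrame  # level, n, icv_mean, icv_sd, icv_rel_sd
    rel_sd_max: float


def match_by_icv(
    cohort,
    group_col: str = "gender",
    k: int = 21,
    rel_sd_max: float = 0.01,
) -> MatchedSubsample:
    """Select k subjects per group, tightly matched on ICV.

    Both groups are sorted by ICV; among all contiguous k-windows whose
    within-group relative SD is below ``rel_sd_max``, the pair of windows
    with the closest group means is chosen.  Deterministic for a fixed input
    order (ties broken by position).  Raises if no window pair satisfies the
    bound, reporting the best achievable relative SDs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = cohort.data
    levels = sorted(pd.unique(df[group_col]))
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, found {levels}")
    windows = {}
    for level in levels:
        sub = df.loc[df[group_col] == level, ["subject_id", "icv"]]
        if len(sub) < k:
            raise ValueError(f"group {level!r} has {len(sub)} members; need >= {k}")
        order = np.argsort(sub["icv"].to_numpy(), kind="stable")
        icv = sub["icv"].to_numpy(dtype=float)[order]
        ids = sub["subject_id"].to_numpy()[order]
        n_win = len(icv) - k + 1
        csum = np.concatenate([[0.0], np.cumsum(icv)])
        csq = np.concatenate([[0.0], np.cumsum(icv**2)])
        means = (csum[k:] - csum[:-k]) / k
        # sample variance of each window
        var = (csq[k:] - csq[:-k] - k * means**2) / (k - 1) if k > 1 else np.zeros(n_win)
        rel_sd = np.sqrt(np.maximum(var, 0.0)) / means
        windows[level] = {"icv": icv, "ids": ids, "means": means, "rel_sd": rel_sd}
    wa, wb = windows[levels[0]], windows[levels[1]]
    feas_a = np.flatnonzero(wa["rel_sd"] < rel_sd_max)
    feas_b = np.flatnonzero(wb["rel_sd"] < rel_sd_max)
    if feas_a.size == 0 or feas_b.size == 0:
        raise ValueError(
            f"no k={k} window meets relative-SD bound {rel_sd_max}; best achievable: "
            f"{levels[0]}={wa['rel_sd'].min():.4f}, {levels[1]}={wb['rel_sd'].min():.4f}"
        )
    gap = np.abs(wa["means"][feas_a][:, None] - wb["means"][feas_b][None, :])
    ia, ib = np.unravel_index(np.argmin(gap), gap.shape)
    start_a, start_b = int(feas_a[ia]), int(feas_b[ib])
    ids = {
        levels[0]: list(wa["ids"][start_a:start_a + k]),
        levels[1]: list(wb["ids"][start_b:start_b + k]),
    }
    rows = []
    for level, start, w in ((levels[0], start_a, wa), (levels[1], start_b, wb)):
        sel = w["icv"][start:start + k]
        rows.append({
            "level": level, "n": k, "icv_mean": sel.mean(),
            "icv_sd": sel.std(ddof=1) if k > 1 else 0.0,
            "icv_rel_sd": (sel.std(ddof=1) / sel.mean()) if k > 1 else 0.0,
        })
    return MatchedSubsample(
        group_col=group_col, levels=(levels[0], levels[1]), ids=ids,
        stats=pd.DataFrame(rows), rel_sd_max=rel_sd_max,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U for the first sample.

    Exact enumeration when n_x * n_y <= 400 and there are no ties (exact
    enumeration does not accommodate ties); tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size * y.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method=method)


# ---------------------------------------------------------------------------
# bootstrap t
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Bootstrap sampling distribution of the Welch t for one region."""

    region: str
    t_observed: float
    replicates: np.ndarray
    p_sim: float
    n_boot: int
    seed: int | None
    redraws: int


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    return (mb - ma) / np.sqrt(va + vb)


def bootstrap_t(
    sub: MatchedSubsample,
    cohort,
    region: str,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> BootstrapDistribution:
    """Bootstrap null distribution of the Welch t within a matched subsample.

    Subjects are resampled with replacement within each matched group and
    the Welch t recomputed per replicate.  The null is constructed by
    centering the replicates at the observed t; the simulation p is the
    smoothed fraction (count+1)/(n_boot+1) of null draws at least as extreme
    as the observed statistic.  Zero-variance replicates are redrawn (and
    counted).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    df = cohort.data.set_index("subject_id")
    a_lab, b_lab = sub.levels
    xa = df.loc[sub.ids[a_lab], region].to_numpy(dtype=float)
    xb = df.loc[sub.ids[b_lab], region].to_numpy(dtype=float)
    t_obs = welch_t(xa, xb).t
    rng = np.random.default_rng(seed)
    ka, kb = xa.size, xb.size
    ra = xa[rng.integers(0, ka, size=(n_boot, ka))]
    rb = xb[rng.integers(0, kb, size=(n_boot, kb))]
    t_rep = _welch_t_rows(ra, rb)
    redraws = 0
    bad = ~np.isfinite(t_rep)
    while bad.any():
        redraws += int(bad.sum())
        idx = np.flatnonzero(bad)
        ra = xa[rng.integers(0, ka, size=(idx.size, ka))]
        rb = xb[rng.integers(0, kb, size=(idx.size, kb))]
        t_rep[idx] = _welch_t_rows(ra, rb)
        bad = ~np.isfinite(t_rep)
    if redraws:
        logger.warning("bootstrap_t(%s): redrew %d degenerate replicates", region, redraws)
    null = t_rep - t_obs  # center the bootstrap distribution at zero
    p_sim = (np.sum(np.abs(null) >= abs(t_obs)) + 1.0) / (n_boot + 1.0)
    return BootstrapDistribution(
        region=region, t_observed=t_obs, replicates=t_rep,
        p_sim=float(p_sim), n_boot=n_boot, seed=seed, redraws=redraws,
    )
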