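"""Volume-ICV correlation patterns, optionally partialing out age.

For cohorts with age variation, each region's correlation with ICV is
computed as a first-order partial correlation controlling for age whenever
age itself correlates significantly with that region's volume (per-region
gate at uncorrected two-sided alpha, 0.05 by default); otherwise the plain
Pearson coefficient is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConstantSeriesError(ValueError):
    """Correlation is undefined for a zero-variance series."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> None:
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y, 3)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def partial_pearson(x, y, z) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    Computed as the Pearson correlation of the OLS residuals of x ~ z and
    y ~ z, with the two-sided p from a t distribution on n - 3 degrees of
    freedom.  A constant z removes nothing, so the coefficient then equals
    the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_pair(x, y, 4)
    if z.shape != x.shape:
        raise ValueError("z must match x and y in length")
    zc = z - z.mean()
    ss = float(zc @ zc)
    if ss == 0.0:
        rx, ry = x - x.mean(), y - y.mean()
    else:
        rx = x - x.mean() - (zc @ (x - x.mean())) / ss * zc
        ry = y - y.mean() - (zc @ (y - y.mean())) / ss * zc
    if np.allclose(rx, 0.0) or np.allclose(ry, 0.0):
        raise ConstantSeriesError("residual series is constant after removing z")
    r = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
    n = x.size
    df = n - 3
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        p = 0.0
    else:
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r_clipped, p=p, n=n)


@dataclass
class CorrelationPattern:
    """Per-region correlation of (adjusted) volume with ICV for one group."""

    mode: str
    group: tuple[str, ...]
    table: pd.DataFrame  # region, r, p, n, partialed_on, note
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(1, "mode", self.mode)
        out.insert(2, "group", "+".join(self.group))
        return out


def correlation_pattern(
    adjusted,
    group: str | Sequence[str] | None = None,
    age_gate_alpha: float = 0.05,
) -> CorrelationPattern:
    """Correlate every region's adjusted volume with ICV within one group.

    ``adjusted`` is an :class:`~icvnorm.normalization.AdjustedCohort` (or any
    object with ``data``/``regions`` and a ``mode``).  The age gate follows
    the per-region convention: partial out age only where corr(age, volume)
    is significant at ``age_gate_alpha`` and age actually varies.  Regions
    with degenerate series are flagged in the output, not fatal.
    """
    sub = adjusted if group is None else adjusted.subset(group)
    df = sub.data
    if len(df) == 0:
        raise ValueError("selected group is empty")
    labels = tuple(pd.unique(df["diagnosis"]))
    icv = df["icv"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    age_varies = np.ptp(age) > 0
    rows = []
    for region in sub.regions:
        vol = df[region].to_numpy(dtype=float)
        row = {"region": region, "r": np.nan, "p": np.nan, "n": len(df),
               "partialed_on": "", "note": ""}
        try:
            gate = age_varies and pearson(age, vol).p < age_gate_alpha
            if gate:
                res = partial_pearson(vol, icv, age)
                row["partialed_on"] = "age"
            else:
                res = pearson(vol, icv)
            row.update(r=res.r, p=res.p, n=res.n)
        except (ConstantSeriesError, ValueError) as exc:
            row["note"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["r"].notna()
    summary = {
        "mean_r": float(table.loc[ok, "r"].mean()) if ok.any() else np.nan,
        "sd_r": float(table.loc[ok, "r"].std(ddof=1)) if ok.sum() > 1 else np.nan,
        "n_regions": int(ok.sum()),
        "age_gate_alpha": age_gate_alpha,
    }
    mode = getattr(adjusted, "mode", "raw")
    return CorrelationPattern(mode=mode, group=labels, table=table, summary=summary)
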