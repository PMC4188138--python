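"""ROC/AUC evaluation of volumetric markers and paired AUC comparison.

The AUC is computed through its rank (Mann-Whitney) formulation with
half-credit for ties.  Confidence intervals and the paired two-marker test
use the DeLong placement-value machinery: for each case the fraction of
controls it exceeds, and vice versa; the empirical variance/covariance of
those placements gives an asymptotic normal test for correlated AUCs
measured on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    flipped: bool  # scores were negated by auto orientation


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    ``v_pos[i]`` = fraction of controls scored below case i (ties half);
    ``v_neg[j]`` = fraction of cases scored above control j (ties half).
    """
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties = np.searchsorted(neg_sorted, pos, side="right") - below
    v_pos = (below + 0.5 * ties) / neg.size
    pos_sorted = np.sort(pos)
    below_p = np.searchsorted(pos_sorted, neg, side="left")
    ties_p = np.searchsorted(pos_sorted, neg, side="right") - below_p
    v_neg = (pos_sorted.size - below_p - 0.5 * ties_p) / pos.size
    return v_pos, v_neg


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"labels must contain exactly 2 classes, found {classes.tolist()}")
    # positive class: the larger label under natural ordering (1 for 0/1 labels)
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    return pos, neg


def roc_auc(scores, labels, orientation: str = "auto") -> AucResult:
    """AUC of ``scores`` for the binary ``labels``, with a DeLong-style CI.

    ``orientation='auto'`` negates the scores when the raw AUC falls below
    0.5 (e.g. atrophy markers, where cases have *smaller* volumes) and
    records the flip; ``'as_is'`` reports the AUC unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = _split(scores, labels)
    flipped = False
    v_pos, v_neg = _placements(pos, neg)
    auc = float(v_pos.mean())
    if orientation == "auto" and auc < 0.5:
        flipped = True
        v_pos, v_neg = _placements(-pos, -neg)
        auc = float(v_pos.mean())
    elif orientation not in ("auto", "as_is"):
        raise ValueError("orientation must be 'auto' or 'as_is'")
    var = 0.0
    if pos.size > 1 and neg.size > 1:
        var = v_pos.var(ddof=1) / pos.size + v_neg.var(ddof=1) / neg.size
    half = 1.959963984540054 * np.sqrt(var)
    return AucResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=pos.size,
        n_neg=neg.size,
        flipped=flipped,
    )


@dataclass(frozen=True)
class PairedAucTest:
    auc_1: float
    auc_2: float
    delta: float
    p: float
    z: float


def compare_auc_paired(scores_1, scores_2, labels) -> PairedAucTest:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same subjects in the same
    order.  The variance of the AUC difference comes from the placement
    differences, which cancels the subject-level correlation between the
    two markers.  AUC is rank-based, so any strictly monotone transform of
    one marker yields delta = 0 exactly.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("scores_1, scores_2 and labels must have equal length")
    pos1, neg1 = _split(s1, labels)
    pos2, neg2 = _split(s2, labels)
    v_pos1, v_neg1 = _placements(pos1, neg1)
    v_pos2, v_neg2 = _placements(pos2, neg2)
    auc1, auc2 = float(v_pos1.mean()), float(v_pos2.mean())
    delta = auc1 - auc2
    d_pos = v_pos1 - v_pos2
    d_neg = v_neg1 - v_neg2
    var = 0.0
    if pos1.size > 1 and neg1.size > 1:
        var = d_pos.var(ddof=1) / pos1.size + d_neg.var(ddof=1) / neg1.size
    if var <= 0.0:
        return PairedAucTest(auc1, auc2, delta, p=1.0 if delta == 0.0 else 0.0, z=0.0 if delta == 0.0 else np.inf)
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PairedAucTest(auc_1=auc1, auc_2=auc2, delta=float(delta), p=p, z=float(z))


@dataclass
class AUCComparison:
    """Per-contrast AUCs for each normalization mode plus pairwise tests."""

    contrast: tuple[str, str]
    per_mode: pd.DataFrame  # mode, auc, ci_low, ci_high, flipped
    pairwise: pd.DataFrame  # mode_a, mode_b, delta, p


def diagnostic_auc_table(
    adjusted_by_mode: dict[str, object],
    region: str = "hippocampus",
    contrasts: Sequence[tuple[str, str]] = (("CTL", "MCI"), ("CTL", "AD"), ("MCI", "AD")),
) -> list[AUCComparison]:
    """AUC of one region for each diagnostic contrast under each mode.

    For every contrast the second label is treated as the positive (more
    affected) class.  Orientation is decided once per contrast, from the
    first mode's raw AUC, and applied to every mode so the pairwise DeLong
    tests compare identically oriented markers.
    """
    modes = list(adjusted_by_mode)
    results = []
    for contrast in contrasts:
        a_lab, b_lab = contrast
        if not a_lab or not b_lab:
            raise ValueError(f"empty label in contrast {contrast}")
        scores_per_mode: dict[str, np.ndarray] = {}
        labels_ref: np.ndarray | None = None
        for mode in modes:
            adj = adjusted_by_mode[mode]
            sub = adj.subset([a_lab, b_lab])
            df = sub.data.sort_values("subject_id")
            labels = (df["diagnosis"] == b_lab).astype(int).to_numpy()
            if labels_ref is None:
                labels_ref = labels
            elif not np.array_equal(labels, labels_ref):
                raise ValueError("modes disagree on subject sets; cannot pair AUCs")
            scores_per_mode[mode] = df[region].to_numpy(dtype=float)
        first = roc_auc(scores_per_mode[modes[0]], labels_ref, orientation="as_is")
        sign = -1.0 if first.auc < 0.5 else 1.0
        per_mode_rows = []
        for mode in modes:
            res = roc_auc(sign * scores_per_mode[mode], labels_ref, orientation="as_is")
            per_mode_rows.append({
                "mode": mode, "auc": res.auc, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "flipped": sign < 0,
            })
        pair_rows = []
        for i in range(len(modes)):
            for j in range(i + 1, len(modes)):
                test = compare_auc_paired(
                    sign * scores_per_mode[modes[i]],
                    sign * scores_per_mode[modes[j]],
                    labels_ref,
                )
                pair_rows.append({
                    "mode_a": modes[i], "mode_b": modes[j],
                    "delta": test.delta, "p": test.p,
                })
        results.append(AUCComparison(
            contrast=contrast,
            per_mode=pd.DataFrame(per_mode_rows),
            pairwise=pd.DataFrame(pair_rows),
        ))
    return results
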