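"""Per-subject cohort tables: the common currency of the pipeline.

A cohort table holds one row per subject with demographics (gender, age,
diagnosis), the intracranial volume (ICV, mm^3), optional cognitive scores,
and one column per regional brain volume (mm^3, hemisphere-averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: columns every cohort table must carry, in canonical order
META_COLUMNS = ("subject_id", "gender", "age", "diagnosis", "icv")

#: score columns recognized automatically when reading a file
KNOWN_SCORE_COLUMNS = ("mmse", "adas_word_recall")

VALID_GENDERS = ("F", "M")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass
class Cohort:
    """A validated per-subject table.

    Parameters
    ----------
    data
        DataFrame with the :data:`META_COLUMNS`, the score columns and one
        numeric column per region.
    regions
        Names of the regional-volume columns (mm^3), in canonical order.
    scores
        Names of the cognitive-score columns.
    """

    data: pd.DataFrame
    regions: tuple[str, ...]
    scores: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        self.scores = tuple(self.scores)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        for col in self.regions + self.scores:
            if col not in df.columns:
                raise CohortValidationError(f"declared column absent from table: {col!r}")
        if len(set(self.regions)) != len(self.regions):
            raise CohortValidationError("region names are not unique")
        bad_gender = set(df["gender"].unique()) - set(VALID_GENDERS)
        if bad_gender:
            raise CohortValidationError(
                f"gender values must be in {VALID_GENDERS}, found {sorted(bad_gender)}"
            )
        icv = df["icv"].to_numpy(dtype=float)
        if not np.all(np.isfinite(icv)) or np.any(icv <= 0):
            bad = df.loc[~(np.isfinite(icv) & (icv > 0)), "subject_id"].tolist()
            raise CohortValidationError(f"non-positive or non-finite ICV for subjects {bad[:5]}")
        for region in self.regions:
            vol = df[region].to_numpy(dtype=float)
            if np.any(~np.isfinite(vol)) or np.any(vol <= 0):
                bad = df.loc[~(np.isfinite(vol) & (vol > 0)), "subject_id"].tolist()
                raise CohortValidationError(
                    f"non-positive volume in region {region!r} for subjects {bad[:5]}"
                )
            if np.any(vol > icv):
                bad = df.loc[vol > icv, "subject_id"].tolist()
                raise CohortValidationError(
                    f"volume exceeds ICV in region {region!r} for subjects {bad[:5]}"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def diagnoses(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["diagnosis"]))

    def subset(self, diagnosis: str | Sequence[str]) -> "Cohort":
        """Rows whose diagnosis is in ``diagnosis`` (label or list of labels)."""
        labels = [diagnosis] if isinstance(diagnosis, str) else list(diagnosis)
        unknown = set(labels) - set(self.data["diagnosis"].unique())
        if unknown:
            raise KeyError(f"diagnosis labels not present in cohort: {sorted(unknown)}")
        mask = self.data["diagnosis"].isin(labels)
        return Cohort(self.data.loc[mask].reset_index(drop=True), self.regions, self.scores)

    def column_order(self) -> list[str]:
        return list(META_COLUMNS) + list(self.scores) + list(self.regions)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write a UTF-8 comma-separated file in canonical column order."""
        self.data.loc[:, self.column_order()].to_csv(path, index=False, encoding="utf-8")


def read_cohort(
    path: str | Path,
    score_columns: Iterable[str] | None = None,
    average_hemispheres_flag: bool = False,
) -> Cohort:
    """Read a cohort CSV.

    Any column outside :data:`META_COLUMNS` that is not a score column is
    treated as a regional volume.  Score columns are taken from
    ``score_columns`` when given, otherwise from :data:`KNOWN_SCORE_COLUMNS`.
    With ``average_hemispheres_flag`` set, ``lh_<name>``/``rh_<name>`` column
    pairs are collapsed to their mean under the bare ``<name>``.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")
    if average_hemispheres_flag:
        df = average_hemispheres(df)
    if score_columns is None:
        scores = tuple(c for c in KNOWN_SCORE_COLUMNS if c in df.columns)
    else:
        scores = tuple(score_columns)
    regions = tuple(c for c in df.columns if c not in META_COLUMNS and c not in scores)
    for col in ("icv",) + regions:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise CohortValidationError(f"{path}: non-numeric value in column {col!r} at line {line}")
    return Cohort(df, regions, scores)


def average_hemispheres(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse ``lh_X``/``rh_X`` column pairs to hemisphere means named ``X``.

    Columns without a matching contralateral partner are left untouched.
    """
    out = df.copy()
    lh = {c[3:]: c for c in df.columns if c.startswith("lh_")}
    rh = {c[3:]: c for c in df.columns if c.startswith("rh_")}
    for name in lh.keys() & rh.keys():
        out[name] = (df[lh[name]] + df[rh[name]]) / 2.0
        out = out.drop(columns=[lh[name], rh[name]])
    return out
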