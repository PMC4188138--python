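"""Head-size normalization: raw passthrough, proportion, residual adjustment.

The residual method fits, per region, the ordinary-least-squares slope beta
of volume on ICV within a *reference* group (controls, by convention) and
adjusts every subject as

    V_adj = V_raw - beta * (ICV - ICV_mean)

which equals the regression residual plus the reference mean volume.  Within
the fitting sample the adjusted volumes are exactly uncorrelated with ICV
and keep the raw mean; applied to a different group (patients) the residual
ICV correlation is only zero in expectation.

The proportion method simply divides by ICV, yielding a unitless fraction in
(0, 1).  When a volume has a positive intercept against ICV this division
over-corrects: the fraction correlates *negatively* with ICV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, read_cohort

MODES = ("raw", "proportion", "residual")


class DegenerateFitError(ValueError):
    """Reference subset too small or without ICV variance."""


@dataclass(frozen=True)
class NormalizationModel:
    """Per-region ICV slopes plus the reference-group mean ICV."""

    betas: Mapping[str, float]  # region -> mm^3 per mm^3
    icv_mean: float  # mm^3, mean ICV of the fitting sample
    reference_group: tuple[str, ...]  # diagnosis labels used for fitting
    fit_n: int
    covariates: tuple[str, ...] = ()  # extra regressors used in the fit

    def __post_init__(self) -> None:
        if self.icv_mean <= 0:
            raise ValueError("icv_mean must be > 0")
        if self.fit_n < 3:
            raise ValueError("fit_n must be >= 3")

    def require_regions(self, regions: Sequence[str]) -> None:
        missing = [r for r in regions if r not in self.betas]
        if missing:
            raise KeyError(f"regions missing from normalization model: {missing}")


@dataclass
class AdjustedCohort:
    """A cohort whose region columns hold adjusted values under one mode."""

    cohort: Cohort
    mode: str
    model: NormalizationModel | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "proportion":
            vols = self.cohort.data[list(self.cohort.regions)].to_numpy()
            if not ((vols > 0) & (vols < 1)).all():
                raise ValueError("proportion-mode adjusted values must lie in (0, 1)")

    @property
    def data(self) -> pd.DataFrame:
        return self.cohort.data

    @property
    def regions(self) -> tuple[str, ...]:
        return self.cohort.regions

    def subset(self, diagnosis) -> "AdjustedCohort":
        labels = [diagnosis] if isinstance(diagnosis, str) else list(diagnosis)
        mask = self.data["diagnosis"].isin(labels)
        sub = _wrap_unvalidated(
            self.data.loc[mask].reset_index(drop=True), self.regions, self.cohort.scores
        )
        return AdjustedCohort(sub, self.mode, self.model)

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the adjusted table plus a JSON sidecar with the provenance."""
        path = Path(path)
        self.cohort.data.loc[:, self.cohort.column_order()].to_csv(
            path, index=False, encoding="utf-8"
        )
        meta: dict = {"mode": self.mode}
        if self.model is not None:
            meta["model"] = {
                "betas": {k: float(v) for k, v in self.model.betas.items()},
                "icv_mean": float(self.model.icv_mean),
                "reference_group": list(self.model.reference_group),
                "fit_n": int(self.model.fit_n),
                "covariates": list(self.model.covariates),
            }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
        )


def adjusted_from_csv(path: str | Path, **read_kwargs) -> AdjustedCohort:
    """Read an adjusted table written by :meth:`AdjustedCohort.to_csv`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text(encoding="utf-8"))
    model = None
    if "model" in meta:
        m = meta["model"]
        model = NormalizationModel(
            betas=m["betas"], icv_mean=m["icv_mean"],
            reference_group=tuple(m["reference_group"]), fit_n=m["fit_n"],
            covariates=tuple(m.get("covariates", ())),
        )
    if meta["mode"] == "raw":
        return AdjustedCohort(read_cohort(path, **read_kwargs), "raw", model)
    # adjusted values (fractions, residuals) may violate raw-volume invariants
    from .cohort import KNOWN_SCORE_COLUMNS, META_COLUMNS
    df = pd.read_csv(path, encoding="utf-8")
    scores = tuple(
        read_kwargs.get("score_columns")
        or (c for c in KNOWN_SCORE_COLUMNS if c in df.columns)
    )
    regions = tuple(c for c in df.columns if c not in META_COLUMNS and c not in scores)
    return AdjustedCohort(_wrap_unvalidated(df, regions, scores), meta["mode"], model)


def _wrap_unvalidated(df: pd.DataFrame, regions, scores) -> Cohort:
    """Build a Cohort without the mm^3 invariant checks.

    Adjusted values (fractions, residuals) are no longer raw volumes, so the
    positivity/ICV-bound invariants of :class:`Cohort` do not apply to them.
    """
    c = Cohort.__new__(Cohort)
    c.data, c.regions, c.scores = df, tuple(regions), tuple(scores)
    return c


# ---------------------------------------------------------------------------
# fitting and application
# ---------------------------------------------------------------------------

def fit_reference_model(
    cohort: Cohort,
    reference_group: str | Sequence[str] | None = None,
    include_age: bool = False,
) -> NormalizationModel:
    """OLS slope of each region on ICV within the reference subset.

    ``reference_group`` may be omitted only for single-diagnosis cohorts:
    with several diagnosis strata present, silently pooling patients into
    the reference fit would defeat the control-slope convention, so the
    function refuses instead.

    With ``include_age`` the fit adds age as a second regressor and stores
    the partial ICV slope (volumes still get adjusted by beta*(ICV - mean)).
    """
    diagnoses = cohort.diagnoses
    if reference_group is None:
        if len(diagnoses) > 1:
            raise ValueError(
                "cohort has multiple diagnosis groups "
                f"{diagnoses}; an explicit reference_group is required"
            )
        reference = cohort
        labels = diagnoses
    else:
        labels = (reference_group,) if isinstance(reference_group, str) else tuple(reference_group)
        reference = cohort.subset(list(labels))
    n = reference.n
    if n < 3:
        raise DegenerateFitError(f"reference subset has {n} subjects; need >= 3")
    icv = reference.data["icv"].to_numpy(dtype=float)
    icv_c = icv - icv.mean()
    ss_icv = float(icv_c @ icv_c)
    if ss_icv == 0.0:
        raise DegenerateFitError("reference subset has zero ICV variance")
    covariates: tuple[str, ...] = ()
    if include_age:
        age = reference.data["age"].to_numpy(dtype=float)
        if np.ptp(age) == 0:
            raise DegenerateFitError("include_age requested but age is constant in the reference")
        design = np.column_stack([np.ones(n), icv, age])
        covariates = ("age",)
    betas: dict[str, float] = {}
    for region in reference.regions:
        v = reference.data[region].to_numpy(dtype=float)
        if include_age:
            coef, *_ = np.linalg.lstsq(design, v, rcond=None)
            betas[region] = float(coef[1])
        else:
            # centered closed form keeps precision with mm^3-scale ICVs
            betas[region] = float((icv_c @ (v - v.mean())) / ss_icv)
    return NormalizationModel(
        betas=betas,
        icv_mean=float(icv.mean()),
        reference_group=tuple(labels),
        fit_n=n,
        covariates=covariates,
    )


def apply_raw(cohort: Cohort) -> AdjustedCohort:
    """Identity mode: adjusted values equal the input volumes."""
    return AdjustedCohort(Cohort(cohort.data.copy(), cohort.regions, cohort.scores), "raw")


def apply_proportion(cohort: Cohort) -> AdjustedCohort:
    """Divide every regional volume by the subject's ICV."""
    icv = cohort.data["icv"].to_numpy(dtype=float)
    if np.any(icv <= 0):
        bad = cohort.data.loc[icv <= 0, "subject_id"].tolist()
        raise ValueError(f"non-positive ICV for subjects {bad[:5]}")
    df = cohort.data.copy()
    for region in cohort.regions:
        df[region] = df[region].to_numpy(dtype=float) / icv
    return AdjustedCohort(_wrap_unvalidated(df, cohort.regions, cohort.scores), "proportion")


def apply_residual(cohort: Cohort, model: NormalizationModel) -> AdjustedCohort:
    """Subtract beta*(ICV - reference mean ICV) from every regional volume."""
    model.require_regions(cohort.regions)
    icv_dev = cohort.data["icv"].to_numpy(dtype=float) - model.icv_mean
    df = cohort.data.copy()
    for region in cohort.regions:
        df[region] = df[region].to_numpy(dtype=float) - model.betas[region] * icv_dev
    return AdjustedCohort(_wrap_unvalidated(df, cohort.regions, cohort.scores), "residual", model)


def adjust(
    cohort: Cohort,
    mode: str,
    model: NormalizationModel | None = None,
    reference_group=None,
) -> AdjustedCohort:
    """Dispatch on ``mode``; fits the reference model if needed for residual."""
    if mode == "raw":
        return apply_raw(cohort)
    if mode == "proportion":
        return apply_proportion(cohort)
    if mode == "residual":
        if model is None:
            model = fit_reference_model(cohort, reference_group)
        return apply_residual(cohort, model)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
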