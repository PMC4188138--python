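"""Synthetic cohort generation.

Volumes follow the linear head-size model the whole package revolves around:

    V_ij = a_j + beta_j * ICV_i + gender_j(g_i) + age_j * age_i + atrophy_j(dx_i) + eps_ij

with a per-region nonzero intercept ``a_j``.  The nonzero intercept is the
load-bearing feature: it is what makes volume-to-ICV fractions negatively
correlated with ICV (over-correction) even though raw volumes correlate
positively.  Default parameters are calibrated against normative summary
statistics for an elderly population (see ``_catalog``): cell means are
matched exactly, SDs approximately, and the raw volume-ICV correlation is
about 0.5 for most regions.

Cognitive scores are linearly coupled to an anchor region (hippocampus by
default), with optional per-diagnosis offsets for the part of the score gap
that is not volume-mediated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._catalog import (
    ALL_REGIONS,
    CORTICAL,
    NORMATIVE_ICV,
    NORMATIVE_N,
    SUBCORTICAL,
    tissue_class,
)
from .cohort import Cohort, META_COLUMNS

logger = logging.getLogger(__name__)

#: ADNI-style demographics per diagnosis: per-gender ICV (mean, sd) of the
#: control stratum, cell sizes and age (mean, sd) per (gender, diagnosis)
ADNI_ICV = {"F": (1444626.0, 130830.0), "M": (1617014.0, 134231.0)}
ADNI_N = {
    ("F", "CTL"): 107, ("M", "CTL"): 116,
    ("F", "MCI"): 124, ("M", "MCI"): 201,
    ("F", "AD"): 86, ("M", "AD"): 90,
}
ADNI_AGE = {
    ("F", "CTL"): (76.1, 4.8), ("M", "CTL"): (75.8, 5.3),
    ("F", "MCI"): (73.4, 7.2), ("M", "MCI"): (75.2, 7.0),
    ("F", "AD"): (74.7, 7.6), ("M", "AD"): (75.5, 7.1),
}

VOLUME_FLOOR = 1.0  # mm^3; non-physical negatives are truncated here


class SpecValidationError(ValueError):
    """A cohort spec violates its invariants; the message names the field."""


@dataclass(frozen=True)
class RegionSpec:
    """Generating parameters of one regional volume."""

    name: str
    intercept_a: float  # mm^3
    slope_beta_true: float  # mm^3 per mm^3 ICV (dimensionless)
    gender_effect: float = 0.0  # additive mm^3 applied to males
    age_slope: float = 0.0  # mm^3 per year
    atrophy: Mapping[str, float] = field(default_factory=dict)  # diagnosis -> mm^3
    noise_sd: float = 1.0  # mm^3

    def validate(self) -> None:
        if not self.noise_sd > 0:
            raise SpecValidationError(f"region {self.name!r}: noise_sd must be > 0")


@dataclass(frozen=True)
class CognitionSpec:
    """A cognitive score linearly coupled to an anchor region."""

    name: str
    anchor_region: str = "hippocampus"
    intercept: float = 0.0  # score units
    slope: float = 0.0  # score units per mm^3
    noise_sd: float = 1.0  # score units
    floor: float | None = None
    ceiling: float | None = None
    #: score shift per diagnosis not mediated by the anchor volume
    diagnosis_offsets: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise SpecValidationError(f"score {self.name!r}: noise_sd must be >= 0")
        if self.floor is not None and self.ceiling is not None and not self.floor < self.ceiling:
            raise SpecValidationError(f"score {self.name!r}: floor must be < ceiling")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one synthetic cohort."""

    n_per_cell: Mapping[tuple[str, str], int]  # (gender, diagnosis) -> count
    icv_params: Mapping[str, tuple[float, float]]  # gender -> (mean, sd) mm^3
    age_model: float | Mapping[tuple[str, str], tuple[float, float]]  # fixed or per-cell (mean, sd)
    regions: tuple[RegionSpec, ...]
    cognition: tuple[CognitionSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_cell:
            raise SpecValidationError("n_per_cell: at least one (gender, diagnosis) cell required")
        for cell, n in self.n_per_cell.items():
            if n < 2:
                raise SpecValidationError(f"n_per_cell[{cell}]: counts must be >= 2")
            gender = cell[0]
            if gender not in self.icv_params:
                raise SpecValidationError(f"icv_params: missing gender {gender!r}")
        for gender, (mean, sd) in self.icv_params.items():
            if sd <= 0:
                raise SpecValidationError(f"icv_params[{gender!r}]: SD must be > 0")
            if mean <= 0:
                raise SpecValidationError(f"icv_params[{gender!r}]: mean must be > 0")
        if not isinstance(self.age_model, (int, float)):
            for cell in self.n_per_cell:
                if cell not in self.age_model:
                    raise SpecValidationError(f"age_model: missing cell {cell}")
                if self.age_model[cell][1] <= 0:
                    raise SpecValidationError(f"age_model[{cell}]: SD must be > 0")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise SpecValidationError("regions: region names must be unique")
        for r in self.regions:
            r.validate()
            self._warn_if_negativity_likely(r)
        anchor_names = set(names)
        for c in self.cognition:
            c.validate()
            if c.anchor_region not in anchor_names:
                raise SpecValidationError(
                    f"cognition[{c.name!r}]: anchor_region {c.anchor_region!r} not in regions"
                )

    def _warn_if_negativity_likely(self, r: RegionSpec) -> None:
        # crude 4-sigma check that generated volumes stay positive
        ages = [self.age_model] if isinstance(self.age_model, (int, float)) else [
            m for m, _ in self.age_model.values()
        ]
        for gender, (mu, sd) in self.icv_params.items():
            low_icv = mu - 4 * sd
            worst = (
                r.intercept_a
                + r.slope_beta_true * low_icv
                + min(0.0, r.gender_effect)
                + min([0.0, *r.atrophy.values()])
                + min([r.age_slope * a for a in ages] + [0.0])
                - 4 * r.noise_sd
            )
            if worst <= 0:
                logger.warning(
                    "region %r may generate non-positive volumes for gender %s "
                    "(4-sigma lower bound %.1f mm^3); values will be floored at %.0f",
                    r.name, gender, worst, VOLUME_FLOOR,
                )

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    @property
    def diagnoses(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, dx in self.n_per_cell:
            if dx not in seen:
                seen.append(dx)
        return tuple(seen)


# ---------------------------------------------------------------------------
# default calibration
# ---------------------------------------------------------------------------

#: target raw volume-ICV correlation used by the default calibration
DEFAULT_R_TARGET = 0.5
#: non-CSF regions keep an intercept of at least this fraction of the female
#: mean, encoding that tissue volumes are not proportional to head size
MIN_INTERCEPT_FRACTION = 0.25

#: default atrophy offsets as fractions of the female normative mean
ATROPHY_FRACTIONS = {
    "gm": {"MCI": -0.05, "AD": -0.12},
    "wm": {"MCI": 0.0, "AD": 0.0},
    "csf": {"MCI": 0.15, "AD": 0.35},
}
#: medial-temporal regions atrophy harder under AD pathology
MEDIAL_TEMPORAL = ("hippocampus", "amygdala", "entorhinal")
MEDIAL_TEMPORAL_ATROPHY = {"MCI": -0.10, "AD": -0.20}

REFERENCE_AGE = 75.0
#: fractional gray-matter loss per year when age effects are enabled
AGE_SLOPE_FRACTION = -0.003


def build_default_regions(
    with_atrophy: bool = False,
    with_age_slopes: bool = False,
    gender_effects: bool = True,
) -> tuple[RegionSpec, ...]:
    """Calibrate the 51-region default catalog.

    The slope is set for a volume-ICV correlation of ``DEFAULT_R_TARGET``
    given the normative female SDs, capped for tissue regions so the
    intercept stays at or above ``MIN_INTERCEPT_FRACTION`` of the female
    mean.  Ventricular/CSF regions fall out with negative intercepts (their
    SD-to-mean ratios are large), so their fractions keep a positive ICV
    correlation — mirroring real cohorts.
    """
    mu_f, sd_f = NORMATIVE_ICV["F"]
    mu_m, _ = NORMATIVE_ICV["M"]
    specs = []
    for name in ALL_REGIONS:
        m_f, s_f, m_m, _s_m, tissue = (SUBCORTICAL | CORTICAL)[name]
        beta = DEFAULT_R_TARGET * s_f / sd_f
        if tissue != "csf":
            beta = min(beta, (1.0 - MIN_INTERCEPT_FRACTION) * m_f / mu_f)
        intercept = m_f - beta * mu_f
        g_eff = (m_m - m_f) - beta * (mu_m - mu_f) if gender_effects else 0.0
        noise_sd = float(np.sqrt(max(s_f**2 - (beta * sd_f) ** 2, (0.2 * s_f) ** 2)))
        age_slope = 0.0
        if with_age_slopes and tissue == "gm":
            age_slope = AGE_SLOPE_FRACTION * m_f
            intercept -= age_slope * REFERENCE_AGE  # keep the mean anchored at age 75
        atrophy: dict[str, float] = {}
        if with_atrophy:
            fractions = MEDIAL_TEMPORAL_ATROPHY if name in MEDIAL_TEMPORAL else ATROPHY_FRACTIONS[tissue]
            atrophy = {dx: frac * m_f for dx, frac in fractions.items() if frac != 0.0}
        specs.append(
            RegionSpec(
                name=name,
                intercept_a=intercept,
                slope_beta_true=beta,
                gender_effect=g_eff,
                age_slope=age_slope,
                atrophy=atrophy,
                noise_sd=noise_sd,
            )
        )
    return tuple(specs)


def expected_region_mean(spec: CohortSpec, region: str, gender: str, diagnosis: str) -> float:
    """Analytic expectation of one region's volume in one cell."""
    r = {s.name: s for s in spec.regions}[region]
    icv_mean = spec.icv_params[gender][0]
    if isinstance(spec.age_model, (int, float)):
        age_mean = float(spec.age_model)
    else:
        age_mean = spec.age_model[(gender, diagnosis)][0]
    return (
        r.intercept_a
        + r.slope_beta_true * icv_mean
        + (r.gender_effect if gender == "M" else 0.0)
        + r.age_slope * age_mean
        + r.atrophy.get(diagnosis, 0.0)
    )


def _expected_pooled_mean(spec: CohortSpec, region: str, diagnosis: str) -> float:
    cells = [(g, dx) for (g, dx) in spec.n_per_cell if dx == diagnosis]
    total = sum(spec.n_per_cell[c] for c in cells)
    return sum(
        spec.n_per_cell[(g, dx)] * expected_region_mean(spec, region, g, dx) for g, dx in cells
    ) / total


def pivus_like_spec(
    n_per_cell: Mapping[tuple[str, str], int] | int | None = None,
    gender_effects: bool = True,
    seed: int = 0,
) -> CohortSpec:
    """Single-diagnosis cohort of 75-year-olds with normative ICV parameters.

    Defaults: 193 females and 213 males, all labelled CTL, age fixed at 75,
    an MMSE-like score anchored to the hippocampus.  With
    ``gender_effects=False`` every male-female volume difference is mediated
    purely by the ICV difference.
    """
    if n_per_cell is None:
        counts = {("F", "CTL"): NORMATIVE_N["F"], ("M", "CTL"): NORMATIVE_N["M"]}
    elif isinstance(n_per_cell, int):
        counts = {("F", "CTL"): n_per_cell, ("M", "CTL"): n_per_cell}
    else:
        counts = dict(n_per_cell)
    regions = build_default_regions(gender_effects=gender_effects)
    spec = CohortSpec(
        n_per_cell=counts,
        icv_params=dict(NORMATIVE_ICV),
        age_model=REFERENCE_AGE,
        regions=regions,
        cognition=(),
        seed=seed,
    )
    hipp = _expected_pooled_mean(spec, "hippocampus", "CTL")
    mmse = CognitionSpec(
        name="mmse", anchor_region="hippocampus",
        slope=1.0e-3, intercept=28.7 - 1.0e-3 * hipp,
        noise_sd=1.3, floor=0.0, ceiling=30.0,
    )
    return dataclasses.replace(spec, cognition=(mmse,))


def adni_like_spec(
    n_per_cell: Mapping[tuple[str, str], int] | int | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Three-stratum (CTL/MCI/AD) cohort with age variation and atrophy.

    Gray matter shrinks under MCI/AD (medial-temporal regions hardest),
    ventricles expand, age effects on gray matter are on, and ADAS word
    recall plus MMSE are coupled to the hippocampus with diagnosis offsets
    sized so cell score means land near their normative targets.
    """
    if n_per_cell is None:
        counts = dict(ADNI_N)
    elif isinstance(n_per_cell, int):
        counts = {cell: n_per_cell for cell in ADNI_N}
    else:
        counts = dict(n_per_cell)
    regions = build_default_regions(with_atrophy=True, with_age_slopes=True)
    spec = CohortSpec(
        n_per_cell=counts,
        icv_params=dict(ADNI_ICV),
        age_model=dict(ADNI_AGE),
        regions=regions,
        cognition=(),
        seed=seed,
    )
    hipp = {dx: _expected_pooled_mean(spec, "hippocampus", dx) for dx in spec.diagnoses}
    adas_targets = {"CTL": 2.9, "MCI": 4.5, "AD": 6.1}
    adas_slope = -1.5e-3
    adas_intercept = adas_targets["CTL"] - adas_slope * hipp["CTL"]
    adas = CognitionSpec(
        name="adas_word_recall", anchor_region="hippocampus",
        slope=adas_slope, intercept=adas_intercept, noise_sd=1.2,
        floor=0.0, ceiling=10.0,
        diagnosis_offsets={
            dx: adas_targets[dx] - (adas_intercept + adas_slope * hipp[dx])
            for dx in ("MCI", "AD")
        },
    )
    mmse_targets = {"CTL": 29.1, "MCI": 27.1, "AD": 23.3}
    mmse_slope = 1.0e-3
    mmse_intercept = mmse_targets["CTL"] - mmse_slope * hipp["CTL"]
    mmse = CognitionSpec(
        name="mmse", anchor_region="hippocampus",
        slope=mmse_slope, intercept=mmse_intercept, noise_sd=1.0,
        floor=0.0, ceiling=30.0,
        diagnosis_offsets={
            dx: mmse_targets[dx] - (mmse_intercept + mmse_slope * hipp[dx])
            for dx in ("MCI", "AD")
        },
    )
    return dataclasses.replace(spec, cognition=(adas, mmse))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort table from ``spec``; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    subject_counter = 0
    truncated = 0
    # fixed iteration order (spec insertion order) => reproducibility
    for (gender, diagnosis), n in spec.n_per_cell.items():
        icv = rng.normal(*spec.icv_params[gender], size=n)
        icv = np.maximum(icv, VOLUME_FLOOR)
        if isinstance(spec.age_model, (int, float)):
            age = np.full(n, float(spec.age_model))
        else:
            age = rng.normal(*spec.age_model[(gender, diagnosis)], size=n)
        cell = {
            "subject_id": [f"S{subject_counter + i:05d}" for i in range(n)],
            "gender": gender,
            "age": age,
            "diagnosis": diagnosis,
            "icv": icv,
        }
        subject_counter += n
        volumes: dict[str, np.ndarray] = {}
        for r in spec.regions:
            v = (
                r.intercept_a
                + r.slope_beta_true * icv
                + (r.gender_effect if gender == "M" else 0.0)
                + r.age_slope * age
                + r.atrophy.get(diagnosis, 0.0)
                + rng.normal(0.0, r.noise_sd, size=n)
            )
            truncated += int(np.sum(v < VOLUME_FLOOR))
            volumes[r.name] = np.maximum(v, VOLUME_FLOOR)
        for c in spec.cognition:
            score = (
                c.intercept
                + c.slope * volumes[c.anchor_region]
                + c.diagnosis_offsets.get(diagnosis, 0.0)
                + (rng.normal(0.0, c.noise_sd, size=n) if c.noise_sd > 0 else 0.0)
            )
            if c.floor is not None:
                score = np.maximum(score, c.floor)
            if c.ceiling is not None:
                score = np.minimum(score, c.ceiling)
            cell[c.name] = score
        cell.update(volumes)
        frames.append(pd.DataFrame(cell))
    if truncated:
        logger.warning("floored %d non-positive generated volumes at %.0f mm^3", truncated, VOLUME_FLOOR)
    data = pd.concat(frames, ignore_index=True)
    scores = tuple(c.name for c in spec.cognition)
    order = list(META_COLUMNS) + list(scores) + list(spec.region_names)
    return Cohort(data.loc[:, order], spec.region_names, scores)


# ---------------------------------------------------------------------------
# spec serialization
# ---------------------------------------------------------------------------

def _cell_key(cell: tuple[str, str]) -> str:
    return f"{cell[0]}|{cell[1]}"


def _parse_cell(key: str) -> tuple[str, str]:
    gender, _, dx = key.partition("|")
    return gender, dx


def spec_to_dict(spec: CohortSpec) -> dict:
    age = spec.age_model
    return {
        "n_per_cell": {_cell_key(c): int(n) for c, n in spec.n_per_cell.items()},
        "icv_params": {g: [float(m), float(s)] for g, (m, s) in spec.icv_params.items()},
        "age_model": float(age) if isinstance(age, (int, float))
        else {_cell_key(c): [float(m), float(s)] for c, (m, s) in age.items()},
        "regions": [
            {**dataclasses.asdict(r), "atrophy": dict(r.atrophy)} for r in spec.regions
        ],
        "cognition": [
            {**dataclasses.asdict(c), "diagnosis_offsets": dict(c.diagnosis_offsets)}
            for c in spec.cognition
        ],
        "seed": int(spec.seed),
    }


def spec_from_dict(d: dict) -> CohortSpec:
    age = d["age_model"]
    return CohortSpec(
        n_per_cell={_parse_cell(k): int(v) for k, v in d["n_per_cell"].items()},
        icv_params={g: (float(m), float(s)) for g, (m, s) in d["icv_params"].items()},
        age_model=float(age) if isinstance(age, (int, float))
        else {_parse_cell(k): (float(m), float(s)) for k, (m, s) in age.items()},
        regions=tuple(RegionSpec(**r) for r in d["regions"]),
        cognition=tuple(CognitionSpec(**c) for c in d.get("cognition", [])),
        seed=int(d.get("seed", 0)),
    )


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False), encoding="utf-8")


def spec_from_yaml(path: str | Path) -> CohortSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
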