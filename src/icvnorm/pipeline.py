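"""End-to-end orchestration: cohort in, full report bundle out.

A run reads (or generates) a cohort, applies all three normalization modes,
and executes the analysis battery: correlation patterns per mode and
diagnosis group, gender comparison tables with direction grid, ICV-matched
subsample with Mann-Whitney and bootstrap-t, cognition regressions, ANOVA
across diagnoses, and the diagnostic AUC table.  Every under-specified
choice taken along the way is recorded in the bundle manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from ._catalog import DEFAULT_FAMILIES
from .association import correlation_pattern
from .classification import diagnostic_auc_table
from .cognition import anova_tukey, fit_score_model, fit_voi_on_icv_age
from .cohort import Cohort, read_cohort
from .groups import bootstrap_t, compare_groups, direction_table, mann_whitney, match_by_icv
from .normalization import MODES, adjust, fit_reference_model
from .synthetic import CohortSpec, generate_cohort

ALL_ANALYSES = ("correlation", "gender", "matched", "cognition", "auc")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the context."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    source: str | Path | CohortSpec  # cohort CSV path or generator spec
    reference_group: str | None = None  # diagnosis label whose slope corrects everyone
    families: Mapping[str, Sequence[str]] | None = None  # Bonferroni families
    alpha: float = 0.05
    n_boot: int = 2000
    match_k: int = 21
    match_rel_sd_max: float = 0.01
    score: str | None = None  # cognition score column; first available if None
    anchor_region: str = "hippocampus"
    seed: int = 0
    analyses: tuple[str, ...] = ALL_ANALYSES
    average_hemispheres: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; choose from {ALL_ANALYSES}")


@dataclass
class ReportBundle:
    """Everything a run produced, ready to serialize."""

    cohort: Cohort
    adjusted: dict  # mode -> AdjustedCohort
    correlation_patterns: list = field(default_factory=list)
    gender_tables: dict = field(default_factory=dict)  # (mode, family) -> GroupComparisonTable
    direction_grids: dict = field(default_factory=dict)  # family -> DataFrame
    matched: object | None = None
    matched_tests: pd.DataFrame | None = None
    cognition_fits: list = field(default_factory=list)
    voi_fits: list = field(default_factory=list)
    anova: object | None = None
    auc: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every enabled analysis and return the report bundle."""
    manifest: dict = {
        "icvnorm_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "choices": {
            "t_test": "welch",
            "multiplicity": "bonferroni per family",
            "age_gate": "per-region plain Pearson, uncorrected two-sided alpha 0.05",
            "bootstrap_null": "replicates centered at observed t",
            "auc_ci": "delong placement-value variance",
            "auc_comparison": "paired delong",
            "proportion_scale": "unitless fraction",
            "rounding": "half away from zero (reports only)",
        },
    }

    cohort = _load_cohort(config)
    manifest["n_subjects"] = cohort.n
    manifest["diagnoses"] = list(cohort.diagnoses)
    manifest["regions"] = len(cohort.regions)

    reference = config.reference_group
    if reference is None and len(cohort.diagnoses) == 1:
        reference = cohort.diagnoses[0]
    manifest["reference_group"] = reference

    model = _fit_model(cohort, reference)
    adjusted = {mode: _adjust(cohort, mode, model) for mode in MODES}
    bundle = ReportBundle(cohort=cohort, adjusted=adjusted, manifest=manifest)

    families = config.families
    if families is None:
        catalog = {
            name: tuple(r for r in regions if r in cohort.regions)
            for name, regions in DEFAULT_FAMILIES.items()
        }
        catalog = {k: v for k, v in catalog.items() if v}
        families = catalog or {"all": cohort.regions}
    manifest["families"] = {k: len(v) for k, v in families.items()}

    if "correlation" in config.analyses:
        _run_correlation(bundle)
    if "gender" in config.analyses:
        _run_gender(bundle, config, families, reference)
    if "matched" in config.analyses:
        _run_matched(bundle, config, families, reference)
    if "cognition" in config.analyses:
        _run_cognition(bundle, config, reference)
    if "auc" in config.analyses and len(cohort.diagnoses) >= 2:
        _run_auc(bundle, config)
    return bundle


@_stage("load_cohort")
def _load_cohort(config: RunConfig) -> Cohort:
    if isinstance(config.source, CohortSpec):
        spec = config.source
        if spec.seed != config.seed:
            spec = dataclasses.replace(spec, seed=config.seed)
        return generate_cohort(spec)
    return read_cohort(config.source, average_hemispheres_flag=config.average_hemispheres)


@_stage("fit_reference_model")
def _fit_model(cohort, reference):
    return fit_reference_model(cohort, reference)


@_stage("normalize")
def _adjust(cohort, mode, model):
    return adjust(cohort, mode, model=model)


@_stage("correlation_patterns")
def _run_correlation(bundle: ReportBundle) -> None:
    for mode, adj in bundle.adjusted.items():
        for dx in bundle.cohort.diagnoses:
            bundle.correlation_patterns.append(correlation_pattern(adj, group=dx))


@_stage("gender_comparison")
def _run_gender(bundle, config, families, reference) -> None:
    # gender comparisons are run within the reference stratum, where the
    # control-slope convention makes all three modes comparable
    for mode, adj in bundle.adjusted.items():
        sub = adj if reference is None else adj.subset(reference)
        for fam_name, regions in families.items():
            bundle.gender_tables[(mode, fam_name)] = compare_groups(
                sub, group_col="gender", family=regions, alpha=config.alpha
            )
    for fam_name in families:
        bundle.direction_grids[fam_name] = direction_table(
            {mode: bundle.gender_tables[(mode, fam_name)] for mode in bundle.adjusted}
        )


@_stage("matched_subsample")
def _run_matched(bundle, config, families, reference) -> None:
    cohort = bundle.cohort if reference is None else bundle.cohort.subset(reference)
    try:
        sub = match_by_icv(
            cohort, "gender", k=config.match_k, rel_sd_max=config.match_rel_sd_max
        )
    except ValueError as exc:
        bundle.manifest["matched_subsample"] = f"skipped: {exc}"
        return
    bundle.matched = sub
    family_size = len(cohort.regions)
    df = cohort.data.set_index("subject_id")
    a_lab, b_lab = sub.levels
    rows = []
    for i, region in enumerate(cohort.regions):
        xa = df.loc[sub.ids[a_lab], region].to_numpy(dtype=float)
        xb = df.loc[sub.ids[b_lab], region].to_numpy(dtype=float)
        mw = mann_whitney(xa, xb)
        boot = bootstrap_t(
            sub, cohort, region, n_boot=config.n_boot, seed=config.seed + i
        )
        rows.append({
            "region": region,
            "u": mw.u, "p_mw": mw.p, "mw_method": mw.method,
            "t_observed": boot.t_observed, "p_boot": boot.p_sim,
            "p_boot_bonferroni": min(1.0, boot.p_sim * family_size),
        })
    bundle.matched_tests = pd.DataFrame(rows)


@_stage("cognition_models")
def _run_cognition(bundle, config, reference) -> None:
    cohort = bundle.cohort
    score = config.score or (cohort.scores[0] if cohort.scores else None)
    region = config.anchor_region
    if region in cohort.regions and score is not None:
        for mode, adj in bundle.adjusted.items():
            bundle.cognition_fits.append((mode, fit_score_model(adj, score, region)))
        bundle.cognition_fits.append(
            ("raw+interaction", fit_score_model(bundle.adjusted["raw"], score, region, with_interaction=True))
        )
    if region in cohort.regions:
        for dx in cohort.diagnoses:
            bundle.voi_fits.append((dx, fit_voi_on_icv_age(cohort, region, group=dx)))
        if len(cohort.diagnoses) >= 2:
            bundle.anova = {
                mode: anova_tukey(adj, region, "diagnosis", alpha=config.alpha)
                for mode, adj in bundle.adjusted.items()
            }


@_stage("diagnostic_auc")
def _run_auc(bundle, config) -> None:
    labels = list(bundle.cohort.diagnoses)
    contrasts = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    bundle.auc = diagnostic_auc_table(bundle.adjusted, config.anchor_region, contrasts)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_tables(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write every bundle artifact as CSV plus a JSON manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index, encoding="utf-8")
        written.append(path)

    bundle.cohort.to_csv(out / "cohort.csv")
    written.append(out / "cohort.csv")
    for mode, adj in bundle.adjusted.items():
        adj.to_csv(out / f"adjusted_{mode}.csv")
        written.append(out / f"adjusted_{mode}.csv")
    if bundle.correlation_patterns:
        _csv(pd.concat([p.to_frame() for p in bundle.correlation_patterns], ignore_index=True),
             "correlation_patterns.csv")
        _csv(pd.DataFrame([
            {"mode": p.mode, "group": "+".join(p.group), **p.summary}
            for p in bundle.correlation_patterns
        ]), "correlation_summaries.csv")
    for (mode, fam), table in bundle.gender_tables.items():
        _csv(table.table, f"gender_{fam}_{mode}.csv")
    for fam, grid in bundle.direction_grids.items():
        _csv(grid, f"directions_{fam}.csv", index=True)
    if bundle.matched is not None:
        _csv(bundle.matched.stats, "matched_subsample.csv")
        _csv(bundle.matched_tests, "matched_tests.csv")
    if bundle.cognition_fits:
        frames = []
        for mode, fit in bundle.cognition_fits:
            frame = fit.to_frame()
            frame.insert(0, "model", mode)
            frame["r_squared"] = fit.r_squared
            frames.append(frame)
        _csv(pd.concat(frames, ignore_index=True), "cognition_models.csv")
    if bundle.voi_fits:
        frames = []
        for dx, fit in bundle.voi_fits:
            frame = fit.to_frame()
            frame.insert(0, "group", dx)
            frame["r_squared"] = fit.r_squared
            frames.append(frame)
        _csv(pd.concat(frames, ignore_index=True), "voi_icv_age_models.csv")
    if bundle.anova:
        frames = []
        for mode, res in bundle.anova.items():
            frame = res.pairwise.copy()
            frame.insert(0, "mode", mode)
            frame["anova_f"] = res.f
            frame["anova_p"] = res.p
            frames.append(frame)
        _csv(pd.concat(frames, ignore_index=True), "anova_tukey.csv")
    if bundle.auc:
        per_mode, pairwise = [], []
        for cmp_ in bundle.auc:
            pm = cmp_.per_mode.copy()
            pm.insert(0, "contrast", "_vs_".join(cmp_.contrast))
            per_mode.append(pm)
            pw = cmp_.pairwise.copy()
            pw.insert(0, "contrast", "_vs_".join(cmp_.contrast))
            pairwise.append(pw)
        _csv(pd.concat(per_mode, ignore_index=True), "auc_table.csv")
        _csv(pd.concat(pairwise, ignore_index=True), "auc_pairwise.csv")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    written.append(manifest_path)
    return written
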