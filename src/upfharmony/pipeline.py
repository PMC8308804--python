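"""End-to-end orchestration: taxonomy -> intake -> exposure -> statistics.

``run_pipeline`` takes a run configuration (either file paths to observed
tables or a simulation configuration), applies the inclusion rules,
computes the per-system UPF exposures and quintiles, and writes the result
tables: per-quintile nutrient profiles with ANOVA and the Q1-Q5 Tukey
contrast, the three nested association models per system and outcome (plus
sensitivity exposures), pairwise concordance, and per-processing-group
consumption shares.  All randomness flows from the single run seed, and
outputs are a pure function of (inputs, config, seed): identical runs are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import exposure as expo
from . import stats as st
from .errors import DomainError, ValidationError
from .ffq import (
    FoodCompositionTable,
    FrequencyScale,
    finalize_profile,
    intake_from_ffq,
    nutrient_intake,
)
from .simulate import SimulationConfig, SyntheticCohort, synthesize_cohort
from .taxonomy import TaxonomyTable, get_system, load_taxonomy

__all__ = [
    "RunConfig",
    "PipelineResult",
    "NUTRITION_VARIABLES",
    "group_consumption_shares",
    "participant_group_shares",
    "build_analysis",
    "run_pipeline",
]

#: nutrient-profile variables summarised per UPF quintile
NUTRITION_VARIABLES = (
    "energy_kcal", "protein_g", "pct_protein", "fat_g", "pct_fat", "sfa_g",
    "pct_sfa", "mufa_g", "pct_mufa", "pufa_g", "pct_pufa", "carb_g",
    "pct_carb", "fiber_g", "sugars_g", "sodium_mg", "gi", "gl", "omega3_g",
)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Inputs and options of one pipeline run."""

    outdir: str | Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    taxonomy_path: str | Path | None = None
    ffq_path: str | Path | None = None
    composition_path: str | Path | None = None
    participants_path: str | Path | None = None
    frequency_scale_path: str | Path | None = None
    systems: tuple[str, ...] = ("NOVA", "IARC", "IFIC", "UNC")
    icc_form: str = "absolute"
    sensitivity: bool = True
    models: tuple[int, ...] = (1, 2, 3)
    outcomes: tuple[str, ...] = expo.OUTCOME_COLUMNS

    def __post_init__(self) -> None:
        if not self.systems:
            raise ValidationError("at least one system is required")
        for s in self.systems:
            get_system(s)
        if self.simulate is None and self.ffq_path is None:
            raise ValidationError(
                "either a simulation config or input paths are required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"unknown run-config key(s): {', '.join(sorted(unknown))}"
            )
        for key in ("systems", "models", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)


@dataclass
class PipelineResult:
    """In-memory view of everything one run computed."""

    included: pd.Index
    exclusion_log: pd.DataFrame
    exposures: pd.DataFrame
    nutrient_profiles: pd.DataFrame
    regressions: pd.DataFrame
    concordance: pd.DataFrame
    group_shares: pd.DataFrame
    sex_upf_means: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def participant_group_shares(intake: pd.DataFrame, taxonomy: TaxonomyTable,
                             system) -> pd.DataFrame:
    """Per-participant percentage of classified grams in each group."""
    sys_ = get_system(system)
    allocated = set(taxonomy.allocated_ids(sys_))
    cols = [c for c in intake.columns if c in allocated]
    total = intake[cols].sum(axis=1)
    if (total <= 0).any():
        raise DomainError("zero classified intake for some participants")
    shares = {}
    for code in sys_.group_codes:
        group_items = [c for c in cols
                       if taxonomy[c].code(sys_) == code]
        shares[code] = 100.0 * intake[group_items].sum(axis=1) / total
    return pd.DataFrame(shares, index=intake.index)


def group_consumption_shares(intake: pd.DataFrame, taxonomy: TaxonomyTable,
                             system) -> pd.Series:
    """Cohort-mean share of intake per processing group (sums to 100)."""
    return participant_group_shares(intake, taxonomy, system).mean(axis=0)


@dataclass(frozen=True)
class AnalysisData:
    """Validated intermediate tables shared by the statistics stage."""

    intake: pd.DataFrame
    profiles: pd.DataFrame
    participants: pd.DataFrame
    included: pd.Index
    exclusion_log: pd.DataFrame
    exposures: pd.DataFrame
    taxonomy: TaxonomyTable


def build_analysis(participants: pd.DataFrame, categories: pd.DataFrame,
                   portions: pd.DataFrame, composition: FoodCompositionTable,
                   taxonomy: TaxonomyTable,
                   scale: FrequencyScale | None = None,
                   systems: Sequence[str] = ("NOVA", "IARC", "IFIC", "UNC"),
                   ) -> AnalysisData:
    """FFQ -> grams/day -> nutrient profiles -> inclusion -> exposures."""
    intake = intake_from_ffq(categories, portions, scale)
    profiles = finalize_profile(nutrient_intake(intake, composition))
    included, log = expo.apply_inclusion(participants, profiles)
    exposures = expo.compute_exposures(
        intake.loc[included], taxonomy,
        participants.loc[included, "weight"],
        profiles.loc[included, "energy_kcal"], systems=systems)
    return AnalysisData(intake=intake, profiles=profiles,
                        participants=participants, included=included,
                        exclusion_log=log, exposures=exposures,
                        taxonomy=taxonomy)


def _nutrient_profile_table(data: AnalysisData,
                            systems: Sequence[str]) -> pd.DataFrame:
    rows = []
    for system in systems:
        sub = data.exposures[data.exposures["system"] == system]
        labels = sub.set_index("participant_id")["quintile"]
        prof = data.profiles.loc[labels.index]
        for var in NUTRITION_VARIABLES:
            qp = st.quintile_profile(prof[var].to_numpy(),
                                     labels.to_numpy(), "continuous",
                                     variable=var, with_tukey=True)
            t15 = qp.tukey[(qp.tukey["q_i"] == 1) & (qp.tukey["q_j"] == 5)]
            for _, r in qp.summary.iterrows():
                rows.append((var, system, int(r["quintile"]), r["mean"],
                             r["sd"], qp.anova_f, qp.anova_p,
                             float(t15["estimate"].iloc[0]),
                             float(t15["se"].iloc[0]),
                             float(t15["p_adj"].iloc[0])))
    return pd.DataFrame(rows, columns=[
        "variable", "system", "quintile", "mean", "sd", "anova_f", "anova_p",
        "q1_q5_estimate", "q1_q5_se", "q1_q5_p"])


def _regression_table(data: AnalysisData, systems: Sequence[str],
                      outcomes: Sequence[str], models: Sequence[int],
                      sensitivity: bool) -> pd.DataFrame:
    results = []
    part = data.participants.loc[data.included].copy()
    part["energy_kcal"] = data.profiles.loc[data.included, "energy_kcal"]
    for system in systems:
        sub = data.exposures[data.exposures["system"] == system]
        sub = sub.set_index("participant_id")
        frame = part.copy()
        frame["increment"] = sub["upf_pct"] / 5.0
        frame["upf_g_per_kg"] = sub["upf_g_per_kg"]
        frame["upf_kcal_adj"] = sub["upf_kcal_adj"]
        exposures = ["increment"]
        if sensitivity:
            exposures += ["upf_g_per_kg", "upf_kcal_adj"]
        for exposure_col in exposures:
            model_ids = models if exposure_col == "increment" else (3,)
            for outcome in outcomes:
                for model_id in model_ids:
                    results.append(st.fit_association_model(
                        frame, outcome, model_id=model_id,
                        exposure=exposure_col, system=system))
    return pd.DataFrame([{
        "outcome": r.outcome, "system": r.system, "exposure": r.exposure,
        "model": r.model_id, "beta": r.beta, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p, "n": r.n} for r in results])


def run_pipeline(config: RunConfig,
                 cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Execute the full analysis and write the result tables.

    In simulate mode the cohort comes from the generator (or may be passed
    in directly); otherwise the observed tables are read from the
    configured TSV paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if cohort is None and config.simulate is not None:
        cohort = synthesize_cohort(config.simulate)
    if cohort is not None:
        participants = cohort.participants
        categories, portions = cohort.ffq_categories, cohort.ffq_portions
        composition, taxonomy = cohort.composition, cohort.taxonomy
        scale = cohort.scale
        log_lines.append(
            f"simulated cohort: n={len(participants)} "
            f"seed={cohort.config.seed}")
    else:
        taxonomy = (load_taxonomy(config.taxonomy_path)
                    if config.taxonomy_path else None)
        if taxonomy is None:
            from .taxonomy import default_taxonomy
            taxonomy = default_taxonomy()
        composition = FoodCompositionTable.load(config.composition_path)
        scale = (FrequencyScale.from_yaml(config.frequency_scale_path)
                 if config.frequency_scale_path else FrequencyScale())
        ffq = pd.read_csv(config.ffq_path, sep="\t")
        categories = ffq.pivot(index="participant_id", columns="item_id",
                               values="category")
        portions = ffq.pivot(index="participant_id", columns="item_id",
                             values="portion_g")
        participants = pd.read_csv(config.participants_path, sep="\t",
                                   index_col="participant_id")
    systems = tuple(get_system(s).name for s in config.systems)

    data = build_analysis(participants, categories, portions, composition,
                          taxonomy, scale, systems=systems)
    log_lines.append(f"included {len(data.included)} of "
                     f"{len(participants)} participants")
    reasons = data.exclusion_log["reason"].str.split(":").str[0]
    for reason, count in reasons.value_counts().sort_index().items():
        log_lines.append(f"excluded ({reason}): {count}")

    profiles_tbl = _nutrient_profile_table(data, systems)
    regressions = _regression_table(data, systems, config.outcomes,
                                    config.models, config.sensitivity)

    labels = data.exposures.pivot(index="participant_id", columns="system",
                                  values="quintile")[list(systems)]
    if len(systems) >= 2:
        concordance = st.pairwise_concordance(labels, form=config.icc_form)
        overall_icc = st.icc_agreement(labels.to_numpy(),
                                       form=config.icc_form).icc
    else:
        concordance = pd.DataFrame(columns=["system_a", "system_b", "icc3",
                                            "overall", "q1", "q5"])
        overall_icc = float("nan")
        log_lines.append("concordance skipped: fewer than two systems")

    shares = pd.concat(
        {s: group_consumption_shares(data.intake.loc[data.included],
                                     taxonomy, s) for s in systems},
        names=["system", "group"]).rename("share_pct").reset_index()
    sex_means = (data.exposures.merge(
        participants[["sex"]], left_on="participant_id", right_index=True)
        .groupby(["system", "sex"], observed=True)["upf_pct"].mean()
        .rename("mean_upf_pct").reset_index())

    manifest = {
        "seed": config.seed,
        "systems": list(systems),
        "icc_form": config.icc_form,
        "n_input": int(len(participants)),
        "n_included": int(len(data.included)),
        "n_excluded": int(len(data.exclusion_log)),
        "overall_icc": None if np.isnan(overall_icc) else
            round(float(overall_icc), 6),
        "mean_upf_pct": {
            s: round(float(data.exposures.loc[
                data.exposures["system"] == s, "upf_pct"].mean()), 4)
            for s in systems},
    }

    _write(data.exposures, outdir / "exposure.tsv")
    _write(data.exclusion_log, outdir / "exclusions.tsv")
    _write(profiles_tbl, outdir / "table1_nutrient_profile.tsv")
    _write(regressions, outdir / "table3_regressions.tsv")
    _write(concordance, outdir / "table4_concordance.tsv")
    _write(shares, outdir / "figure3_group_shares.tsv")
    _write(sex_means, outdir / "sex_upf_means.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        included=data.included, exclusion_log=data.exclusion_log,
        exposures=data.exposures, nutrient_profiles=profiles_tbl,
        regressions=regressions, concordance=concordance,
        group_shares=shares, sex_upf_means=sex_means, manifest=manifest)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
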