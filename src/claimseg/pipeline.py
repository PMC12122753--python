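"""End-to-end analysis pipeline over (synthetic or real-format) claims.

Chains every stage of the analysis: cohort extraction and validation,
indicator construction, missing-data imputation, local-independence
screening, train/validation split, the 1..Kmax model grid with the
multi-criterion selection rule, stability validation, application of
the chosen model to the full cohort, and class profiling with outcome
regressions. Intermediate artifacts are kept on the result object so
each stage can be inspected or re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AttritionReport, build_cohort
from .config import CodeConfig, DEFAULT_CODES
from .impute import ImputationResult, impute
from .indicators import build_indicator_matrix, charlson_table
from .lca import LCAModel, fit_lca, order_by_disease_stage, posterior
from .profiling import (class_profiles, logistic_or, profiles_to_frames,
                        regression_frame, site_outlier_filter, summary_report,
                        top_diagnoses)
from .selection import (FitSummary, SelectionReport, StabilityReport,
                        bootstrap_stability, correlation_screen, fit_grid,
                        holdout_confirmation, select, split_sample)
from .synthetic import (ClaimsTables, LatentClassSpec, SimulationConfig,
                        default_latent_class_spec, simulate)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    attrition: AttritionReport
    matrix: pd.DataFrame
    imputation: ImputationResult
    screen: object
    summary: FitSummary
    selection: SelectionReport
    model: LCAModel | None
    assignment: pd.Series | None
    stability: StabilityReport | None
    holdout: StabilityReport | None
    profiles: list | None
    regressions: pd.DataFrame | None
    outcomes: pd.DataFrame | None
    cci: pd.DataFrame | None
    top_ed: dict | None
    top_hospital: dict | None
    excluded_sites: list = field(default_factory=list)


def derive_outcomes(tables: ClaimsTables, cohort: pd.DataFrame) -> pd.DataFrame:
    """Dichotomous outcomes per cohort member from the ED visit table.

    Recurrent ED use: more than one visit in the index year. Inpatient
    admission: at least one admitted visit.
    """
    visits = tables.ed_visits[tables.ed_visits["patient_id"].isin(cohort["patient_id"])]
    per = visits.groupby("patient_id").agg(
        n_visits=("visit_id", "size"), admitted=("admitted", "max"))
    out = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    out["recurrent_ed"] = (per["n_visits"].reindex(out.index).fillna(0) > 1).astype(int)
    out["admitted"] = per["admitted"].reindex(out.index).fillna(0).astype(int)
    return out


def run_pipeline(
    tables: ClaimsTables,
    codes: CodeConfig = DEFAULT_CODES,
    Kmax: int = 10,
    split_ratio: float = 0.7,
    restarts: int = 10,
    bootstrap_B: int = 20,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis over a set of claims tables."""
    cohort, attrition = build_cohort(tables, codes)
    matrix = build_indicator_matrix(cohort, tables, codes)
    cci = charlson_table(cohort, tables, codes)
    outcomes = derive_outcomes(tables, cohort)

    imp = impute(matrix, max_iter=10, seed=seed)
    screen = correlation_screen(imp.completed)
    screened = screen.retained

    train_idx, val_idx = split_sample(len(screened), split_ratio, seed)
    train = screened.iloc[train_idx]
    validation = screened.iloc[val_idx]

    summary = fit_grid(train, Kmax=Kmax, restarts=restarts, seed=seed)
    sel = select(summary)

    model = assignment = stability = holdout = None
    profiles = regressions = top_ed = top_hosp = None
    excluded = []
    if sel.chosen_K is not None:
        model = order_by_disease_stage(summary.models[sel.chosen_K])
        stability = bootstrap_stability(train, model, B=bootstrap_B, seed=seed + 1)
        holdout = holdout_confirmation(model, validation, seed=seed + 2,
                                       restarts=restarts)
        # apply the chosen model to the full cohort
        post = posterior(model, screened)
        assignment = pd.Series(post.map_labels, index=screened.index, name="class")
        profiles = class_profiles(assignment, imp.completed, outcomes, cci)
        regs = []
        for oc in ("recurrent_ed", "admitted"):
            y = outcomes[oc]
            regs += logistic_or(y, assignment)
            regs += logistic_or(y, assignment, age_cat=imp.completed["age_cat"])
        regressions = regression_frame(regs)
        excluded = site_outlier_filter(tables.ed_visits)
        top_ed = top_diagnoses(tables, assignment, source="ED",
                               exclude_sites=excluded)
        top_hosp = top_diagnoses(tables, assignment, source="main_hospital")

    result = PipelineResult(
        cohort=cohort, attrition=attrition, matrix=matrix, imputation=imp,
        screen=screen, summary=summary, selection=sel, model=model,
        assignment=assignment, stability=stability, holdout=holdout,
        profiles=profiles, regressions=regressions, outcomes=outcomes,
        cci=cci, top_ed=top_ed, top_hospital=top_hosp, excluded_sites=excluded,
    )
    if outdir is not None:
        write_report(result, outdir, seed=seed)
    return result


def write_report(result: PipelineResult, outdir: str | Path, seed: int = 0) -> Path:
    """Write the full report bundle (CSV tables + manifest) to disk."""
    frames: dict[str, pd.DataFrame] = {
        "fit_summary": result.summary.table.reset_index(),
        "indicator_matrix": result.matrix.reset_index(),
        "cohort": result.cohort,
    }
    if result.regressions is not None:
        frames["regressions"] = result.regressions
    if result.profiles is not None:
        frames.update(profiles_to_frames(result.profiles))
    if result.top_ed is not None:
        frames["top_ed_diagnoses"] = pd.concat(
            [df.assign(group=name) for name, df in result.top_ed.items()])
        frames["top_hospital_diagnoses"] = pd.concat(
            [df.assign(group=name) for name, df in result.top_hospital.items()])
    if result.screen is not None:
        frames["correlation_matrix"] = result.screen.correlation.reset_index()
    return summary_report(
        outdir,
        seeds={"master": seed},
        config={"Kmax": len(result.summary.table),
                "dropped_indicators": list(result.screen.dropped)},
        attrition=result.attrition.as_dict(),
        selection_trace=result.selection.trace,
        frames=frames,
    )


def run_synthetic_study(
    n_patients: int = 10_000,
    n_distractors: int = 500,
    seed: int = 0,
    spec: LatentClassSpec | None = None,
    config: SimulationConfig | None = None,
    **pipeline_kwargs,
) -> tuple[PipelineResult, object]:
    """Simulate a claims dataset and run the full pipeline over it."""
    config = config or SimulationConfig(n_patients=n_patients,
                                        n_distractors=n_distractors, seed=seed)
    sim = simulate(config, spec or default_latent_class_spec(), seed=seed)
    result = run_pipeline(sim.tables, config.codes, seed=seed, **pipeline_kwargs)
    return result, sim
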