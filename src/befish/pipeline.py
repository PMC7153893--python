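"""End-to-end pipeline: filters -> diversity/markers -> screening ->
bootstrap model selection -> leave-one-out stratification.

The stages mirror how the analysis is meant to be run on a real cohort:

1. validate tables and apply inclusion filters (>= 50 cells per panel,
   no baseline dysplasia, no progression within 6 months);
2. compute the diversity matrix (both panels, subsets of 1-4 markers) and
   individual marker scores;
3. univariate Cox screen of clinical covariates, marker scores and
   candidate diversity scores; retain p_Wald <= 0.05, flag 0.05-0.10 as
   borderline (borderline covariates stay eligible for multivariate models);
4. bootstrap out-of-bag evaluation of candidate multivariate models
   (<= 3 covariates each), ranked by median iAUC then median AIC;
5. leave-one-out risk scores for the winning model, cut-off sweep,
   stratification statistics, KM curves and annual progression rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, SET1, SET2, apply_inclusion_filters
from .cox import Covariate, ModelSpec, fit_cox
from .diversity import diversity_matrix, diversity_matrix_tidy
from .markers import marker_score_table
from .selection import bootstrap_evaluate, rank_models
from .stratify import (annual_progression_rate, confusion_at_cutoff,
                       cutoff_sweep, km_logrank, loo_risk_scores,
                       select_cutoff)

__all__ = ["PipelineConfig", "PipelineResult", "assemble_features",
           "run_pipeline", "default_candidate_models", "NC_SET2_COLUMN"]

log = logging.getLogger("befish")

NC_SET2_COLUMN = "normalized_clone:CEP7/CEP17/20q/c-MYC"
NC_SET1_3M_COLUMN = "normalized_clone:TP53/ERBB2/CEP17"

CLINICAL_NUMERIC = ["age", "c_length", "m_length", "bmi"]


@dataclass
class PipelineConfig:
    min_cells: int = 50
    min_followup_months: float = 6.0
    candidate_models: list[ModelSpec] = field(default_factory=list)
    B: int = 1000
    seed: int = 0
    tau: float | None = None
    target_sensitivity: float = 0.90
    max_covariates: int = 3
    screen_alpha: float = 0.05
    borderline_alpha: float = 0.10


def default_candidate_models(max_covariates: int = 3) -> list[ModelSpec]:
    """The candidate set: null, clinical-only, and clinical+diversity models
    with and without a spline on age (splines applied to age first)."""
    age = Covariate("age", "clinical")
    age_s = Covariate("age", "clinical", spline=True, spline_df=3)
    c_len = Covariate("c_length", "clinical")
    nc2 = Covariate(NC_SET2_COLUMN, "diversity")
    nc1 = Covariate(NC_SET1_3M_COLUMN, "diversity")
    mk = max_covariates
    return [
        ModelSpec("null", (), mk),
        ModelSpec("clinical", (age, c_len), mk),
        ModelSpec("clinical_spline_age", (age_s, c_len), mk),
        ModelSpec("clinical+NC_set2", (age, c_len, nc2), mk),
        ModelSpec("clinical_spline_age+NC_set2", (age_s, c_len, nc2), mk),
        ModelSpec("clinical+NC_set1_3m", (age, c_len, nc1), mk),
    ]


def assemble_features(cohort: Cohort,
                      diversity: pd.DataFrame | None = None,
                      markers: pd.DataFrame | None = None) -> pd.DataFrame:
    """One wide patient x covariate table (clinical + markers + diversity)."""
    clin = cohort.clinical_frame()
    feat = clin[CLINICAL_NUMERIC].astype(float).copy()
    feat["male"] = (clin["sex"] == "M").astype(float)
    feat["smoker"] = (clin["smoking"] == "current_or_former").astype(float)
    feat["ppi"] = clin["ppi"].astype(float)
    for extra in (markers, diversity):
        if extra is not None:
            feat = feat.join(extra, how="left")
    return feat


@dataclass
class PipelineResult:
    cohort: Cohort
    exclusions: pd.DataFrame
    features: pd.DataFrame
    diversity_set1: pd.DataFrame
    diversity_set2: pd.DataFrame
    markers: pd.DataFrame
    screen: pd.DataFrame
    ranking: pd.DataFrame
    best_spec: ModelSpec
    loo_scores: pd.Series
    sweep: pd.DataFrame
    chosen_cutoff: float
    stratification: pd.DataFrame
    logrank_p: float
    km_frames: pd.DataFrame


def univariate_screen(features: pd.DataFrame, outcomes: pd.DataFrame,
                      covariates: list[str], alpha: float = 0.05,
                      borderline: float = 0.10) -> pd.DataFrame:
    """Univariate Cox models per covariate (Wald + likelihood-ratio p)."""
    rows = []
    for name in covariates:
        spec = ModelSpec(f"uni:{name}", (Covariate(name),))
        fit = fit_cox(features[[name]].dropna(), outcomes, spec)
        if len(fit.beta) == 0:  # constant covariate: no information
            rows.append({"variable": name, "p_wald": 1.0, "p_lr": 1.0,
                         "HR": 1.0, "ci_lower": np.nan, "ci_upper": np.nan,
                         "status": "constant"})
            continue
        p_w = float(fit.wald_p.iloc[0])
        status = ("significant" if p_w <= alpha
                  else "borderline" if p_w <= borderline else "ns")
        rows.append({"variable": name, "p_wald": p_w, "p_lr": fit.lr_p,
                     "HR": float(fit.hazard_ratios.iloc[0]),
                     "ci_lower": float(fit.ci_lower.iloc[0]),
                     "ci_upper": float(fit.ci_upper.iloc[0]),
                     "status": status})
    return pd.DataFrame(rows)


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    cfg = config or PipelineConfig()
    cohort.validate()
    filtered, exclusions = apply_inclusion_filters(
        cohort, min_cells=cfg.min_cells,
        min_followup_months=cfg.min_followup_months)
    log.info("inclusion filters: kept %d of %d patients (%d excluded)",
             len(filtered.clinical), len(cohort.clinical), len(exclusions))
    if not filtered.clinical:
        raise RuntimeError("inclusion filters removed every patient")

    div1 = diversity_matrix(filtered, SET1)
    div2 = diversity_matrix(filtered, SET2)
    mks = marker_score_table(filtered)
    # CEP17 is on both panels: the {CEP17} subset column exists in both
    # matrices, so set1's colliding columns get an @set1 suffix
    collide = div1.columns.intersection(div2.columns)
    div = pd.concat(
        [div1.rename(columns={c: f"{c}@set1" for c in collide}), div2], axis=1)
    features = assemble_features(filtered, diversity=div, markers=mks)
    outcomes = filtered.outcomes_frame()

    screen_covs = (CLINICAL_NUMERIC
                   + [c for c in mks.columns]
                   + [NC_SET2_COLUMN, NC_SET1_3M_COLUMN])
    screen = univariate_screen(features, outcomes, screen_covs,
                               cfg.screen_alpha, cfg.borderline_alpha)
    log.info("univariate screen: %d significant, %d borderline",
             (screen["status"] == "significant").sum(),
             (screen["status"] == "borderline").sum())

    candidates = cfg.candidate_models or default_candidate_models(cfg.max_covariates)
    for spec in candidates:
        if len(spec.covariates) > cfg.max_covariates:
            raise ValueError(
                f"model {spec.spec_id!r} has more than {cfg.max_covariates} "
                f"covariates; refused by the events/overfitting rule")
    evals = [bootstrap_evaluate(features, outcomes, spec, B=cfg.B,
                                seed=cfg.seed, tau=cfg.tau)
             for spec in candidates]
    ranking = rank_models(evals)
    best_id = ranking.iloc[0]["model_id"]
    best_spec = next(s for s in candidates if s.spec_id == best_id)
    log.info("best model by median iAUC: %s", best_id)
    if not best_spec.covariates:
        raise RuntimeError("the null model won the ranking; nothing to stratify")

    scores = loo_risk_scores(features, outcomes, best_spec)
    sweep = cutoff_sweep(scores, outcomes["progressed"])
    cutoff = select_cutoff(sweep, cfg.target_sensitivity)
    strat_rows = []
    stats = confusion_at_cutoff(scores, outcomes["progressed"], cutoff)
    high = scores >= cutoff
    row = stats.as_row()
    row["annual_rate_high"] = annual_progression_rate(outcomes, high)
    row["annual_rate_low"] = annual_progression_rate(outcomes, ~high)
    strat_rows.append(row)
    curves, lr = km_logrank(outcomes, high.map({True: "high", False: "low"}))
    km_frames = pd.concat([c.as_frame() for c in curves.values()],
                          ignore_index=True)

    return PipelineResult(
        cohort=filtered, exclusions=exclusions, features=features,
        diversity_set1=div1, diversity_set2=div2, markers=mks, screen=screen,
        ranking=ranking, best_spec=best_spec, loo_scores=scores, sweep=sweep,
        chosen_cutoff=cutoff, stratification=pd.DataFrame(strat_rows),
        logrank_p=lr.p, km_frames=km_frames,
    )


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write the report bundle as CSVs plus a short human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    diversity_matrix_tidy(result.diversity_set1, SET1).to_csv(
        outdir / "diversity_set1.csv", index=False)
    diversity_matrix_tidy(result.diversity_set2, SET2).to_csv(
        outdir / "diversity_set2.csv", index=False)
    result.markers.to_csv(outdir / "marker_scores.csv")
    result.screen.to_csv(outdir / "univariate_screen.csv", index=False)
    result.ranking.to_csv(outdir / "model_ranking.csv", index=False)
    result.loo_scores.rename("score").to_csv(outdir / "risk_scores.csv")
    result.sweep.to_csv(outdir / "cutoff_sweep.csv", index=False)
    result.stratification.to_csv(outdir / "stratification.csv", index=False)
    result.km_frames.to_csv(outdir / "km_curves.csv", index=False)
    strat = result.stratification.iloc[0]
    summary = (
        f"patients analyzed: {len(result.features)}\n"
        f"best model: {result.best_spec.spec_id}\n"
        f"chosen cut-off: {result.chosen_cutoff:.4g}\n"
        f"sensitivity {strat['sensitivity']:.2f}, "
        f"specificity {strat['specificity']:.2f}, "
        f"PPV {strat['ppv']:.2f}, NPV {strat['npv']:.2f}\n"
        f"annual progression rate high/low: "
        f"{strat['annual_rate_high']:.2f}% / {strat['annual_rate_low']:.2f}%\n"
        f"log-rank p: {result.logrank_p:.3g}\n"
    )
    (outdir / "summary.txt").write_text(summary)
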