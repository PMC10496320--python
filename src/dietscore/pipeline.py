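"""End-to-end pipeline: files in, score/analysis tables out.

Binds the FFQ engine, lifestyle derivation, scorers and inference into the
runs the CLI exposes: score a cohort's six composites per participant, then
produce correlation, model, stratified-model and quartile tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ffq_engine as ffq
from . import inference, lifestyle, scores

logger = logging.getLogger(__name__)

#: Open-section substitutions: (qualifier, value) -> {item -> variant item}.
DEFAULT_SUBSTITUTIONS = {
    ("milk_type", "skim"): {"milk_full": "milk_skim"},
    ("milk_type", "full"): {"milk_skim": "milk_full"},
}

SCORE_COLUMNS = list(scores.SCORE_NAMES)

BIOMARKERS = ("paf", "lppla2", "hscrp")


class PipelineError(ValueError):
    """Raised when pipeline inputs fail validation."""


@dataclass
class ParticipantInputs:
    """Everything needed to score one participant."""

    intake: ffq.DailyIntake
    activity_category: int
    water_fraction: float
    energy: lifestyle.EnergyAssignment
    qualifiers: dict[str, str]


def _participant_inputs(
    row: pd.Series,
    responses: list[ffq.FFQResponse],
    qualifiers: dict[str, str],
    table: ffq.FoodCompositionTable,
) -> ParticipantInputs:
    resolved = ffq.apply_open_section(
        responses, {row["participant_id"]: qualifiers}, DEFAULT_SUBSTITUTIONS, table
    )
    intake = ffq.quantify(resolved, table)
    met = lifestyle.gpaq_met_minutes(
        vigorous_work_days=row["gpaq_vig_work_days"],
        vigorous_work_min=row["gpaq_vig_work_min"],
        moderate_work_days=row["gpaq_mod_work_days"],
        moderate_work_min=row["gpaq_mod_work_min"],
        travel_days=row["gpaq_travel_days"],
        travel_min=row["gpaq_travel_min"],
        vigorous_recreation_days=row["gpaq_vig_rec_days"],
        vigorous_recreation_min=row["gpaq_vig_rec_min"],
        moderate_recreation_days=row["gpaq_mod_rec_days"],
        moderate_recreation_min=row["gpaq_mod_rec_min"],
    )
    category = lifestyle.classify_activity(met)
    diary = lifestyle.DiaryBeverages(
        water_ml=(row["water_d1"], row["water_d2"], row["water_d3"]),
        total_ml=(row["total_d1"], row["total_d2"], row["total_d3"]),
    )
    wf = lifestyle.water_fraction(diary)
    energy = lifestyle.estimate_energy(
        age=row["age"], sex=row["sex"], weight_kg=row["weight_kg"],
        activity_category=category,
    )
    return ParticipantInputs(intake, category, wf, energy, qualifiers)


def score_participant(
    inputs: ParticipantInputs,
    table: ffq.FoodCompositionTable,
    config: dict,
) -> dict[str, scores.ScoreResult]:
    """All six composites for one participant's derived inputs."""
    out: dict[str, scores.ScoreResult] = {}
    out["dash"] = scores.score_dash(inputs.intake, inputs.energy, config)
    out["dash_dairy_adj"] = scores.score_dash(
        inputs.intake, inputs.energy, config, dairy_adjusted=True
    )
    out["vegetarian"] = scores.score_vegetarian(
        inputs.intake,
        eer_kj=inputs.energy.eer_kj,
        activity_category=inputs.activity_category,
        water_frac=inputs.water_fraction,
        b12_source=inputs.qualifiers.get("b12_source", "no") == "yes",
        config=config,
    )
    out["heifa"] = scores.score_heifa(
        inputs.intake, table, inputs.water_fraction, config
    )
    screener = scores.derive_screener(inputs.intake, inputs.qualifiers)
    out["medas"] = scores.score_medas(screener, config)
    out["ermeddiet"] = scores.score_ermeddiet(screener, config)
    return out


def score_cohort(
    covariates: pd.DataFrame,
    ffq_by_pid: dict[str, list[ffq.FFQResponse]],
    open_by_pid: dict[str, dict[str, str]],
    table: ffq.FoodCompositionTable,
    config: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six composites per participant plus a long per-component table."""
    config = config or scores.load_config()
    comp_rows, long_rows = [], []
    for _, row in covariates.iterrows():
        pid = row["participant_id"]
        responses = ffq_by_pid.get(pid)
        if not responses:
            raise PipelineError(f"participant {pid!r}: no FFQ responses")
        inputs = _participant_inputs(row, responses, open_by_pid.get(pid, {}), table)
        results = score_participant(inputs, table, config)
        comp_rows.append(
            {"participant_id": pid,
             **{name: res.composite for name, res in results.items()}}
        )
        for name, res in results.items():
            for comp, pts in res.component_points.items():
                long_rows.append(
                    {"participant_id": pid, "index": name,
                     "component": comp, "points": pts}
                )
    return pd.DataFrame(comp_rows), pd.DataFrame(long_rows)


def analysis_frame(
    covariates: pd.DataFrame, composites: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge covariates (+ composites) into the numeric modelling frame.

    Adds indicator columns gender_female / year_2022 / risk_high and the
    activity tertile from the GPAQ columns.
    """
    df = covariates.copy()
    if composites is not None:
        df = df.merge(composites, on="participant_id", how="inner", validate="1:1")
    df["gender_female"] = (df["sex"] == "female").astype(int)
    df["year_2022"] = (df["year"].astype(int) == 2022).astype(int)
    df["risk_high"] = (df["cvd_risk"] == "high").astype(int)
    met = (
        df["gpaq_vig_work_days"] * df["gpaq_vig_work_min"] * 8
        + df["gpaq_mod_work_days"] * df["gpaq_mod_work_min"] * 4
        + df["gpaq_travel_days"] * df["gpaq_travel_min"] * 4
        + df["gpaq_vig_rec_days"] * df["gpaq_vig_rec_min"] * 8
        + df["gpaq_mod_rec_days"] * df["gpaq_mod_rec_min"] * 4
    )
    df["met_min_week"] = met
    df["activity"] = np.select([met < 600, met < 1500], [0, 1], default=2)
    return df


def run_models(
    frame: pd.DataFrame,
    score_cols: list[str] | None = None,
    outcomes: tuple[str, ...] = BIOMARKERS,
) -> pd.DataFrame:
    """Model 1 and 2 fits for every outcome x score; one row per fit."""
    score_cols = score_cols or SCORE_COLUMNS
    rows = []
    for outcome in outcomes:
        for score in score_cols:
            for model_id in (1, 2):
                try:
                    fit = inference.fit_model(frame, outcome, score, model_id)
                except inference.InferenceError as exc:
                    logger.warning("skipping %s/%s model %d: %s",
                                   outcome, score, model_id, exc)
                    rows.append({"outcome": outcome, "score": score,
                                 "model": model_id, "error": str(exc)})
                    continue
                rows.append({
                    "outcome": outcome, "score": score, "model": model_id,
                    "log_outcome": fit.log_outcome, "n_used": fit.n_used,
                    "beta_std": fit.beta_std, "p_value": fit.p_value,
                    "exp_beta": fit.exp_beta, "pct_change": fit.pct_change,
                    "vif_max": max(fit.vif.values()),
                    "tolerance_min": min(fit.tolerance.values()),
                })
    return pd.DataFrame(rows)


def run_stratified_models(
    frame: pd.DataFrame,
    score_cols: list[str] | None = None,
    outcomes: tuple[str, ...] = ("paf", "lppla2"),
) -> pd.DataFrame:
    """Per-year refits (year covariate dropped within each stratum)."""
    score_cols = score_cols or SCORE_COLUMNS
    rows = []
    for year, sub in frame.groupby("year"):
        for outcome in outcomes:
            for score in score_cols:
                for model_id in (1, 2):
                    try:
                        fit = inference.fit_model(
                            sub, outcome, score, model_id,
                            include_year=False, stratum=str(year),
                        )
                    except inference.InferenceError as exc:
                        rows.append({"year": year, "outcome": outcome,
                                     "score": score, "model": model_id,
                                     "error": str(exc)})
                        continue
                    rows.append({
                        "year": year, "outcome": outcome, "score": score,
                        "model": model_id, "n_used": fit.n_used,
                        "beta_std": fit.beta_std, "p_value": fit.p_value,
                    })
    return pd.DataFrame(rows)


def run_correlations(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-score matrix and score-biomarker correlation table.

    Biomarker correlations use log hsCRP and log PAF (natural log) and raw
    Lp-PLA2, mirroring the analysis convention for skewed markers.
    """
    r, p, _ = inference.pearson_matrix(frame, SCORE_COLUMNS)
    score_score = r.round(6)

    work = frame.copy()
    work["log_paf"] = inference.log_transform(work["paf"])
    work["log_hscrp"] = inference.log_transform(work["hscrp"])
    rows = []
    for score in SCORE_COLUMNS:
        for marker in ("log_paf", "lppla2", "log_hscrp"):
            sub = work[[score, marker]].dropna()
            rm, pm, _ = inference.pearson_matrix(sub, [score, marker])
            rows.append({
                "score": score, "marker": marker,
                "r": rm.iloc[0, 1], "p_value": pm.iloc[0, 1],
                "magnitude": inference.correlation_magnitude(rm.iloc[0, 1]),
                "n": len(sub),
            })
    return score_score, pd.DataFrame(rows)


def run_quartiles(frame: pd.DataFrame) -> pd.DataFrame:
    """Descriptive mean biomarker per quartile of each score (long form)."""
    rows = []
    for score in SCORE_COLUMNS:
        for marker in BIOMARKERS:
            qs = inference.quartile_summary(frame, score, marker)
            for quartile, r in qs.iterrows():
                rows.append({
                    "score": score, "marker": marker, "quartile": quartile,
                    "marker_mean": r[f"{marker}_mean"], "n": int(r["n"]),
                })
    return pd.DataFrame(rows)


def load_inputs(in_dir: str | Path):
    """Read the four input files a simulate run writes."""
    d = Path(in_dir)
    covariates = pd.read_csv(d / "covariates.csv")
    ffq_by_pid = ffq.read_ffq_csv(d / "ffq.csv")
    open_by_pid = ffq.read_open_section_csv(d / "open_section.csv")
    table = ffq.FoodCompositionTable.from_csv(d / "composition.csv")
    return covariates, ffq_by_pid, open_by_pid, table
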