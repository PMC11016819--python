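"""Session file formats, validation, and the end-to-end pipeline driver.

A *session* is one participant-visit: demographics, group label, the raw
trial-level responses of all six tasks (coordinates in screen centimetres
after card calibration), questionnaire totals, and the dates needed to apply
the blood-draw freshness rule. Sessions are stored one-per-file as versioned
JSON; all tabular pipeline outputs are plain CSV so the statistical layer
stays inspectable.
"""

from __future__ import annotations

import datetime as _dt
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

#: sessions completed more than this many days after the blood draw are dropped
#: (day 21 itself is still accepted).
MAX_DAYS_AFTER_DRAW = 21

GroupLabel = Literal["AD", "EHC1", "EHC2"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OMTTrial(_StrictModel):
    """One "what was where?" trial: remember 1 or 3 fractals, identify the
    target among a foil, drag it to its remembered location."""

    n_items: int = Field(ge=1)
    item_locations: list[tuple[float, float]]
    target_index: int = Field(ge=0)
    identified: bool
    response_location: tuple[float, float]
    identification_time: float = Field(gt=0)
    localization_time: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_layout(self) -> "OMTTrial":
        if len(self.item_locations) != self.n_items:
            raise ValueError("item_locations length must equal n_items")
        if self.target_index >= self.n_items:
            raise ValueError("target_index out of range")
        return self


class OISTrial(_StrictModel):
    """Object-in-scene trial: choose the studied object from a 20-object pool
    (which contains a same-category foil) and replace it in the scene."""

    stage: Literal["immediate", "delayed"]
    target_object: str
    target_category: str
    chosen_object: str
    chosen_category: str
    target_location: tuple[float, float]
    response_location: tuple[float, float]


class ROCFResponse(_StrictModel):
    """Drag-and-drop complex-figure response: element name -> placed centre (cm).
    Omitted elements are simply absent from the mapping."""

    stage: Literal["copy", "recall"]
    placements: dict[str, tuple[float, float]]


class CorsiTrial(_StrictModel):
    """Freestyle Corsi trial: an ordered dot sequence and the ordered clicks."""

    sequence: list[tuple[float, float]]
    response: list[tuple[float, float]]


class DSSTResponse(_StrictModel):
    timestamp: float = Field(ge=0)
    correct: bool


class TMTTrial(_StrictModel):
    condition: Literal["A", "B", "motor"]
    n_targets: int = Field(ge=2)
    click_times: list[float]
    completed: bool


class Demographics(_StrictModel):
    age: float = Field(ge=18, le=110)
    sex: Literal["M", "F"]
    education_years: float = Field(ge=0)


class Questionnaires(_StrictModel):
    ace_total: Optional[float] = None
    ami_total: Optional[float] = None
    gds_total: Optional[float] = None
    #: answers to the embedded validation item of each questionnaire;
    #: the only accepted answer is "Completely untrue".
    validation_answers: list[str] = Field(default_factory=list)


class SessionRecord(_StrictModel):
    schema_version: int = SCHEMA_VERSION
    participant_id: str
    visit: int = 1
    group: GroupLabel
    demographics: Demographics
    session_date: _dt.date
    blood_draw_date: Optional[_dt.date] = None
    calibration_px_per_cm: float = Field(default=38.0, gt=0)
    omt: list[OMTTrial] = Field(default_factory=list)
    ois: list[OISTrial] = Field(default_factory=list)
    rocf: list[ROCFResponse] = Field(default_factory=list)
    corsi: list[CorsiTrial] = Field(default_factory=list)
    dsst: list[DSSTResponse] = Field(default_factory=list)
    dsst_window_s: float = 120.0
    tmt: list[TMTTrial] = Field(default_factory=list)
    questionnaires: Questionnaires = Field(default_factory=Questionnaires)

    def days_after_draw(self) -> Optional[int]:
        if self.blood_draw_date is None:
            return None
        return (self.session_date - self.blood_draw_date).days


class BiomarkerPanel(_StrictModel):
    """Plasma panel (pg/mL) for one participant-visit. ``abeta_ratio`` is the
    Aβ42/40 ratio and is stored explicitly so it always equals abeta42/abeta40."""

    participant_id: str
    visit: int = 1
    ptau181: float = Field(gt=0)
    gfap: float = Field(gt=0)
    nfl: float = Field(gt=0)
    abeta42: float = Field(gt=0)
    abeta40: float = Field(gt=0)
    abeta_ratio: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_ratio(self) -> "BiomarkerPanel":
        if abs(self.abeta_ratio - self.abeta42 / self.abeta40) > 1e-6:
            raise ValueError("abeta_ratio must equal abeta42 / abeta40")
        return self


BIOMARKER_COLUMNS = ["ptau181", "gfap", "nfl", "abeta_ratio", "abeta42", "abeta40"]


class SessionFormatError(ValueError):
    """Raised when a session file fails schema validation."""


def write_session(session: SessionRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(session.model_dump_json(indent=1))
    return path


def write_sessions(sessions: list[SessionRecord], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sessions:
        paths.append(write_session(s, directory / f"{s.participant_id}_v{s.visit}.json"))
    return paths


def read_session(path: str | Path) -> SessionRecord:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{path}: malformed JSON ({exc})") from exc
    version = payload.get("schema_version") if isinstance(payload, dict) else None
    if version != SCHEMA_VERSION:
        raise SessionFormatError(
            f"{path}: unsupported schema_version {version!r}; this reader handles "
            f"version {SCHEMA_VERSION} — upgrade the file or the package"
        )
    try:
        return SessionRecord.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SessionFormatError(f"{path}: field '{loc}': {first['msg']}") from exc


def read_sessions(path: str | Path) -> list[SessionRecord]:
    """Read one session file or every ``*.json`` session in a directory."""
    path = Path(path)
    if path.is_dir():
        return [read_session(p) for p in sorted(path.glob("*.json"))]
    return [read_session(path)]


def panels_to_frame(panels: list[BiomarkerPanel]) -> pd.DataFrame:
    rows = [p.model_dump() for p in panels]
    return pd.DataFrame(rows).set_index(["participant_id", "visit"]) if rows else pd.DataFrame(
        columns=BIOMARKER_COLUMNS
    )


def filter_fresh_sessions(
    sessions: list[SessionRecord], max_days: int = MAX_DAYS_AFTER_DRAW
) -> tuple[list[SessionRecord], list[tuple[str, int]]]:
    """Drop sessions completed more than ``max_days`` days after the blood draw.

    Returns (kept, dropped) where dropped is a list of (participant_id, days).
    Sessions without a blood draw (the online normative group) are always kept.
    """
    kept, dropped = [], []
    for s in sessions:
        days = s.days_after_draw()
        if days is not None and days > max_days:
            dropped.append((s.participant_id, days))
        else:
            kept.append(s)
    return kept, dropped


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    metric_table: pd.DataFrame
    zscore_table: pd.DataFrame
    qc_summary: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    feature_ranking: pd.DataFrame
    model_comparison: pd.DataFrame
    roc_summary: dict
    manifest: dict
    excluded_participants: list[str] = field(default_factory=list)


def run_pipeline(
    cohort_config=None,
    outdir: str | Path | None = None,
    *,
    window_years: float = 3.0,
    n_min: int = 20,
    alpha: float = 0.05,
    max_model_candidates: int = 12,
) -> PipelineResult:
    """Simulate -> score -> QC -> average visits -> z-score -> statistics ->
    classification, writing every artifact plus a reproducibility manifest.

    Stages run on the synthetic cohort described by ``cohort_config``
    (defaults emulate the AD n=46 / EHC1 n=53 / EHC2 n=352 study structure).
    """
    # local imports keep module import cheap and avoid cycles
    from . import classification as cls
    from . import normalization as norm
    from . import stats as st
    from .quality_control import run_attention_checks
    from .synthetic_data import CohortConfig, generate_cohort
    from .task_scoring import PRIMARY_METRICS, score_session

    if cohort_config is None:
        cohort_config = CohortConfig(seed=0)

    cohort = generate_cohort(cohort_config)
    sessions = [s for s, _ in cohort]
    panels = [p for _, p in cohort if p is not None]

    sessions, dropped_late = filter_fresh_sessions(sessions)

    qc_rows, metric_rows = [], []
    excluded: list[str] = []
    for s in sessions:
        report = run_attention_checks(s)
        qc_rows.append(
            {
                "participant_id": s.participant_id,
                "visit": s.visit,
                "group": s.group,
                "n_failed": report.n_failed,
                "excluded": report.participant_excluded,
                "tasks_discarded": ";".join(sorted(report.tasks_discarded)),
            }
        )
        if report.participant_excluded:
            excluded.append(s.participant_id)
            continue
        metrics = score_session(s)
        for task in report.tasks_discarded:
            for col in list(metrics):
                if col.startswith(task):
                    metrics[col] = float("nan")
        metric_rows.append(
            {
                "participant_id": s.participant_id,
                "visit": s.visit,
                "group": s.group,
                "age": s.demographics.age,
                "sex": s.demographics.sex,
                "education_years": s.demographics.education_years,
                **metrics,
            }
        )

    metric_table = pd.DataFrame(metric_rows)
    qc_summary = pd.DataFrame(qc_rows)

    averaged = norm.average_visits(metric_table)
    reference = averaged[averaged["group"] == "EHC2"]
    zscore_table = norm.build_zscore_table(
        averaged, reference, metrics=PRIMARY_METRICS, window=window_years, n_min=n_min
    )

    zcols = [f"{m} (z)" for m in PRIMARY_METRICS]
    ad = zscore_table[zscore_table["group"] == "AD"]
    ehc1 = zscore_table[zscore_table["group"] == "EHC1"]
    contrasts = st.contrast_table(ad, ehc1, zcols, groups=("AD", "EHC1"))

    panel_df = panels_to_frame(panels).groupby("participant_id").mean()
    merged = zscore_table.set_index("participant_id").join(panel_df, how="inner")
    covariates = pd.DataFrame(
        {
            "age": merged["age"],
            "sex": (merged["sex"] == "F").astype(float),
            "education_years": merged["education_years"],
        }
    )
    correlations = st.correlation_grid(
        merged[["ptau181", "gfap", "nfl", "abeta_ratio"]],
        merged[zcols],
        covariates,
        alpha=alpha,
    )

    # one representative metric per task (the paper's Figure-5 style selection)
    selected = {
        "OMT": "OMT Identification Accuracy (z)",
        "OIS": "OIS Object Identification Accuracy - Immediate (z)",
        "ROCF": "ROCF Immediate Recall Score (%) (z)",
        "DSST": "DSST Number of Correct Responses (z)",
        "TMT": "TMT-A Average Completion Time (s) (z)",
        "CORSI": "CORSI Mean Location Error (cm) (z)",
    }
    import numpy as np

    features = merged[list(selected.values())].copy()
    for b in ["ptau181", "gfap", "nfl", "abeta_ratio"]:
        features[f"log10 {b}"] = np.log10(merged[b])
    labels = (merged["group"] == "AD").astype(int)
    complete = features.notna().all(axis=1)
    features, labels = features[complete], labels[complete]

    ranking = cls.rank_features_classification(features, labels)
    feature_ranking = pd.DataFrame(
        [{"feature": r.feature, "score": r.score, "p": r.p, "rank": r.rank} for r in ranking]
    )
    candidates = features.columns[:max_model_candidates]
    comparison = cls.exhaustive_model_selection(features[candidates], labels, family="logistic")
    model_comparison = comparison.table

    combined_cols = [
        "ROCF Immediate Recall Score (%) (z)",
        "OIS Object Identification Accuracy - Immediate (z)",
        "DSST Number of Correct Responses (z)",
    ]
    combined_scores = cls.fit_penalized_logistic(features[combined_cols], labels).scores
    ptau_scores = features["log10 ptau181"].to_numpy()
    roc_a, roc_b, z_stat, p_delong = cls.roc_with_delong(
        combined_scores, ptau_scores, labels.to_numpy()
    )
    roc_summary = {
        "combined_model": combined_cols,
        "combined_auc": roc_a.auc,
        "ptau181_auc": roc_b.auc,
        "delong_z": z_stat,
        "delong_p": p_delong,
    }

    manifest = {
        "seed": cohort_config.seed,
        "schema_version": SCHEMA_VERSION,
        "cohort_config": json.loads(cohort_config.model_dump_json()),
        "n_sessions": len(sessions),
        "dropped_late_sessions": dropped_late,
        "excluded_participants": excluded,
        "window_years": window_years,
        "n_min": n_min,
        "alpha": alpha,
        "python": platform.python_version(),
    }

    result = PipelineResult(
        metric_table=metric_table,
        zscore_table=zscore_table,
        qc_summary=qc_summary,
        contrasts=contrasts,
        correlations=correlations,
        feature_ranking=feature_ranking,
        model_comparison=model_comparison,
        roc_summary=roc_summary,
        manifest=manifest,
        excluded_participants=excluded,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metric_table.to_csv(outdir / "metric_table.csv", index=False)
        zscore_table.to_csv(outdir / "zscore_table.csv", index=False)
        qc_summary.to_csv(outdir / "qc_summary.csv", index=False)
        contrasts.to_csv(outdir / "group_contrasts.csv", index=False)
        correlations.to_csv(outdir / "correlation_grid.csv", index=False)
        feature_ranking.to_csv(outdir / "feature_ranking.csv", index=False)
        model_comparison.to_csv(outdir / "model_comparison.csv", index=False)
        (outdir / "roc_summary.json").write_text(json.dumps(roc_summary, indent=1, default=str))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return result
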