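"""Reduce raw trial responses to participant-level cognitive metrics.

Six online tasks are scored:

* **OMT** ("what was where?") — identification accuracy, location error,
  identification/localization reaction times, and the decomposition of
  localization responses into target detection, misbinding (placing the item
  at a *non-target* item's location — a feature-location binding failure),
  and guessing, plus spatial imprecision.
* **OIS** (object-in-scene) — object and semantic-category identification
  accuracy and location error, separately for immediate and delayed recall.
* **ROCF** (drag-and-drop complex figure) — a continuous anchor-distance
  precision score over 13 elements, scaled to percent.
* **CORSI** (freestyle tapping) — mean click-to-dot distance.
* **DSST** — correct digit-symbol matches inside a 2-minute window.
* **TMT** — mean trail completion time per condition (A / B / motor control).

All coordinates are centimetres (post card-calibration), distances Euclidean.
Scoring is deterministic: the same session always yields the same row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .session_io import (
    CorsiTrial,
    DSSTResponse,
    OISTrial,
    OMTTrial,
    SessionRecord,
    TMTTrial,
)

#: nearest-item classification threshold (cm). Matches the task's 3-cm clear
#: zone around item locations: a response farther than this from *every*
#: displayed item is a guess.
OMT_GUESS_THRESHOLD_CM = 3.0

#: distance cap (cm) charged for missing Corsi clicks — the default arena diagonal.
CORSI_CAP_CM = math.hypot(28.0, 16.0)


def _dist(a: Sequence[float], b: Sequence[float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


# ---------------------------------------------------------------------------
# OMT
# ---------------------------------------------------------------------------


@dataclass
class OMTMetrics:
    identification_accuracy: float
    location_error: float  # cm, over identification-correct trials
    identification_time: float  # s, median
    localization_time: float  # s, median
    target_detection_rate: float
    misbinding_rate: float
    guessing_rate: float
    imprecision: float  # cm, SD of distance to the assigned item centre
    n_trials: int = 0


def classify_omt_response(
    trial: OMTTrial, threshold: float = OMT_GUESS_THRESHOLD_CM
) -> str:
    """Classify a localization as ``target`` / ``misbind`` / ``guess``.

    Nearest-item rule: the response is assigned to the closest displayed item;
    if it lies farther than ``threshold`` from every item it is a guess.
    With a single displayed item misbinding is impossible by construction.
    """
    dists = [_dist(trial.response_location, loc) for loc in trial.item_locations]
    nearest = int(np.argmin(dists))
    if dists[nearest] > threshold:
        return "guess"
    return "target" if nearest == trial.target_index else "misbind"


def score_omt(
    trials: Sequence[OMTTrial], threshold: float = OMT_GUESS_THRESHOLD_CM
) -> OMTMetrics:
    """Score the OMT. Requires at least one completed trial.

    ``location_error`` is the mean response-to-target distance over
    identification-correct trials; if no trial was identified correctly it is
    reported missing (NaN), never zero. The three response rates are fractions
    of all classified trials and sum to one.
    """
    if not trials:
        raise ValueError("score_omt requires at least one trial")
    n = len(trials)
    identified = [t for t in trials if t.identified]
    classes = [classify_omt_response(t, threshold) for t in trials]
    rate = lambda c: classes.count(c) / n

    target_dists = [
        _dist(t.response_location, t.item_locations[t.target_index])
        for t, c in zip(trials, classes)
        if c == "target"
    ]
    imprecision = float(np.std(target_dists, ddof=1)) if len(target_dists) >= 2 else float("nan")
    if identified:
        loc_err = float(
            np.mean(
                [_dist(t.response_location, t.item_locations[t.target_index]) for t in identified]
            )
        )
    else:
        loc_err = float("nan")

    return OMTMetrics(
        identification_accuracy=len(identified) / n,
        location_error=loc_err,
        identification_time=float(np.median([t.identification_time for t in trials])),
        localization_time=float(np.median([t.localization_time for t in trials])),
        target_detection_rate=rate("target"),
        misbinding_rate=rate("misbind"),
        guessing_rate=rate("guess"),
        imprecision=imprecision,
        n_trials=n,
    )


# ---------------------------------------------------------------------------
# OIS
# ---------------------------------------------------------------------------


@dataclass
class OISStageMetrics:
    object_identification_accuracy: float
    semantic_identification_accuracy: float
    location_error: float  # cm
    n_trials: int = 0


@dataclass
class OISMetrics:
    immediate: Optional[OISStageMetrics]
    delayed: Optional[OISStageMetrics]


def _score_ois_stage(trials: Sequence[OISTrial]) -> OISStageMetrics:
    n = len(trials)
    obj = sum(t.chosen_object == t.target_object for t in trials) / n
    # an exact identity match is necessarily the correct category, so
    # semantic accuracy can never fall below object accuracy
    sem = sum(t.chosen_category == t.target_category for t in trials) / n
    err = float(np.mean([_dist(t.response_location, t.target_location) for t in trials]))
    return OISStageMetrics(obj, sem, err, n)


def score_ois(trials: Sequence[OISTrial]) -> OISMetrics:
    """Score object / semantic accuracy and location error per recall stage.

    With the task's 20-object pool containing one same-category foil, a
    uniform random chooser scores 5% object and 10% semantic accuracy.
    """
    for t in trials:
        if t.stage not in ("immediate", "delayed"):  # pragma: no cover - schema enforced
            raise ValueError("OIS trial missing stage tag")
    stages = {}
    for stage in ("immediate", "delayed"):
        subset = [t for t in trials if t.stage == stage]
        stages[stage] = _score_ois_stage(subset) if subset else None
    return OISMetrics(immediate=stages["immediate"], delayed=stages["delayed"])


# ---------------------------------------------------------------------------
# ROCF
# ---------------------------------------------------------------------------

#: Schematic 13-element template (synthetic): element -> ideal centre (cm).
#: The published figure's element geometry is not distributed, and only the
#: *anchor-relative distances* enter the score, so any template with plausible
#: distances is faithful. The middle large rectangle is the anchor.
ROCF_TEMPLATE: dict[str, tuple[float, float]] = {
    "large_rectangle": (0.0, 0.0),
    "left_cross": (-6.2, 0.3),
    "horizontal_midline": (0.0, 0.1),
    "vertical_midline": (-0.1, 0.0),
    "main_diagonals": (0.2, -0.1),
    "small_rectangle_left": (-3.1, 1.6),
    "upper_left_segment": (-2.6, -1.1),
    "short_vertical_left": (-1.9, 0.8),
    "circle_with_dots": (1.4, -1.2),
    "parallel_lines_right": (1.6, 1.7),
    "right_triangle": (5.2, 0.0),
    "lower_square": (-1.6, 3.4),
    "lower_cross": (0.6, 3.9),
}

ROCF_ANCHOR = "large_rectangle"


@dataclass
class ROCFScore:
    element_scores: dict[str, float]
    raw_sum: float
    percent: float
    anchor_fallback: bool = False  # anchor unplaced; template anchor position used


def score_rocf(
    placements: Mapping[str, Sequence[float]],
    template: Mapping[str, Sequence[float]] = ROCF_TEMPLATE,
    anchor: str = ROCF_ANCHOR,
    d0: float = 1.0,
    far_cutoff: float = 10.0,
) -> ROCFScore:
    """Anchor-distance precision score for the drag-and-drop complex figure.

    Per element: unplaced scores 0; otherwise the absolute difference ``d``
    between its ideal and actual distance from the anchor is compressed
    logarithmically, ``scaled = min(1, log(1 + d/d0) / log(1 + far_cutoff/d0))``,
    and the element scores ``1 - scaled`` (zero at or beyond ``far_cutoff``).
    The raw sum is out of 13; ``percent`` rescales to 0-100. If the anchor
    itself is unplaced the template anchor position is used and the result is
    flagged, rather than silently zeroing the whole figure.

    Depends only on anchor-relative distances, hence invariant under rigid
    motions applied to all placements.
    """
    t_anchor = template[anchor]
    if anchor in placements:
        a_pos = placements[anchor]
        fallback = False
    else:
        a_pos = t_anchor
        fallback = True
    denom = math.log1p(far_cutoff / d0)
    scores: dict[str, float] = {}
    for name, ideal in template.items():
        if name not in placements:
            scores[name] = 0.0
            continue
        ideal_d = _dist(ideal, t_anchor)
        actual_d = _dist(placements[name], a_pos)
        err = abs(ideal_d - actual_d)
        scaled = min(1.0, math.log1p(err / d0) / denom)
        scores[name] = 1.0 - scaled
    raw = float(sum(scores.values()))
    return ROCFScore(
        element_scores=scores,
        raw_sum=raw,
        percent=100.0 * raw / len(template),
        anchor_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# CORSI
# ---------------------------------------------------------------------------


@dataclass
class CorsiMetrics:
    mean_location_error: float  # cm, over all trials
    error_by_length: dict[int, float]
    capped_trials: int = 0  # trials with missing clicks charged at the cap


def score_corsi(trials: Sequence[CorsiTrial], cap: float = CORSI_CAP_CM) -> CorsiMetrics:
    """Mean click-to-dot distance, overall and per sequence length.

    A response shorter than its target sequence has each missing click charged
    at the ``cap`` distance (arena diagonal by default) and the trial counted
    in ``capped_trials`` — partial responses are penalized, not dropped.
    """
    if not trials:
        raise ValueError("score_corsi requires at least one trial")
    per_trial: list[tuple[int, float]] = []
    capped = 0
    for t in trials:
        n = len(t.sequence)
        if len(t.response) > n:
            raise ValueError("response longer than target sequence")
        dists = [_dist(r, s) for r, s in zip(t.response, t.sequence)]
        if len(t.response) < n:
            capped += 1
            dists += [cap] * (n - len(t.response))
        per_trial.append((n, float(np.mean(dists))))
    by_length: dict[int, float] = {}
    for length in sorted({n for n, _ in per_trial}):
        by_length[length] = float(np.mean([e for n, e in per_trial if n == length]))
    return CorsiMetrics(
        mean_location_error=float(np.mean([e for _, e in per_trial])),
        error_by_length=by_length,
        capped_trials=capped,
    )


# ---------------------------------------------------------------------------
# DSST
# ---------------------------------------------------------------------------


@dataclass
class DSSTMetrics:
    correct_count: int
    correct_rate: float
    idle_time: float  # s, accumulated gap time beyond the grace unit
    n_responses: int = 0


def score_dsst(
    responses: Sequence[DSSTResponse],
    window: float = 120.0,
    idle_grace: float = 5.0,
) -> DSSTMetrics:
    """Count correct matches with timestamps inside the response window.

    ``idle_time`` accumulates, over consecutive gaps (including the gap from
    window start to the first response), the excess of each gap over the
    ``idle_grace`` unit; it feeds the attention-check layer.
    """
    times = [r.timestamp for r in responses]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("DSST timestamps must be non-decreasing")
    in_window = [r for r in responses if r.timestamp < window]
    correct = sum(r.correct for r in in_window)
    n = len(in_window)
    gaps = np.diff([0.0] + [r.timestamp for r in in_window])
    idle = float(np.sum(np.maximum(0.0, gaps - idle_grace))) if n else window
    return DSSTMetrics(
        correct_count=int(correct),
        correct_rate=correct / n if n else 0.0,
        idle_time=idle,
        n_responses=n,
    )


# ---------------------------------------------------------------------------
# TMT
# ---------------------------------------------------------------------------


@dataclass
class TMTMetrics:
    mean_time_a: float
    mean_time_b: float
    mean_time_motor: float
    incomplete_trials: int = 0


def score_tmt(trials: Sequence[TMTTrial]) -> TMTMetrics:
    """Mean completion time per condition; completion time is the timestamp of
    the last correct click. Incomplete trails are excluded from the mean (a
    condition with no complete trial is missing, never zero)."""
    times: dict[str, list[float]] = {"A": [], "B": [], "motor": []}
    incomplete = 0
    for t in trials:
        if not t.completed or len(t.click_times) < t.n_targets:
            incomplete += 1
            continue
        times[t.condition].append(t.click_times[-1])
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return TMTMetrics(
        mean_time_a=mean(times["A"]),
        mean_time_b=mean(times["B"]),
        mean_time_motor=mean(times["motor"]),
        incomplete_trials=incomplete,
    )


# ---------------------------------------------------------------------------
# session reduction
# ---------------------------------------------------------------------------

#: the 19 primary metrics entering normalization, statistics, and the
#: biomarker correlation grid (4 biomarkers x 19 metrics = 76 pairs)
PRIMARY_METRICS = [
    "OMT Identification Accuracy",
    "OMT Location Error (cm)",
    "OMT Identification Time (s)",
    "OMT Localization Time (s)",
    "OMT Target Detection Rate",
    "OMT Misbinding Rate",
    "OMT Guessing Rate",
    "OMT Imprecision (cm)",
    "OIS Object Identification Accuracy - Immediate",
    "OIS Semantic Identification Accuracy - Immediate",
    "OIS Location Error - Immediate (cm)",
    "OIS Object Identification Accuracy - Delayed",
    "OIS Semantic Identification Accuracy - Delayed",
    "OIS Location Error - Delayed (cm)",
    "ROCF Copy Score (%)",
    "ROCF Immediate Recall Score (%)",
    "CORSI Mean Location Error (cm)",
    "DSST Number of Correct Responses",
    "TMT-A Average Completion Time (s)",
]

#: direction of impairment per metric: +1 means larger raw value = worse
WORSE_IF_HIGHER = {
    "OMT Identification Accuracy": -1,
    "OMT Location Error (cm)": 1,
    "OMT Identification Time (s)": 1,
    "OMT Localization Time (s)": 1,
    "OMT Target Detection Rate": -1,
    "OMT Misbinding Rate": 1,
    "OMT Guessing Rate": 1,
    "OMT Imprecision (cm)": 1,
    "OIS Object Identification Accuracy - Immediate": -1,
    "OIS Semantic Identification Accuracy - Immediate": -1,
    "OIS Location Error - Immediate (cm)": 1,
    "OIS Object Identification Accuracy - Delayed": -1,
    "OIS Semantic Identification Accuracy - Delayed": -1,
    "OIS Location Error - Delayed (cm)": 1,
    "ROCF Copy Score (%)": -1,
    "ROCF Immediate Recall Score (%)": -1,
    "CORSI Mean Location Error (cm)": 1,
    "DSST Number of Correct Responses": -1,
    "TMT-A Average Completion Time (s)": 1,
}


def score_session(session: SessionRecord) -> dict[str, float]:
    """Reduce one session to its metric row (column names as in the exports)."""
    out: dict[str, float] = {}
    nan = float("nan")

    if session.omt:
        m = score_omt(session.omt)
        out.update(
            {
                "OMT Identification Accuracy": m.identification_accuracy,
                "OMT Location Error (cm)": m.location_error,
                "OMT Identification Time (s)": m.identification_time,
                "OMT Localization Time (s)": m.localization_time,
                "OMT Target Detection Rate": m.target_detection_rate,
                "OMT Misbinding Rate": m.misbinding_rate,
                "OMT Guessing Rate": m.guessing_rate,
                "OMT Imprecision (cm)": m.imprecision,
            }
        )
    if session.ois:
        o = score_ois(session.ois)
        for stage, sm in (("Immediate", o.immediate), ("Delayed", o.delayed)):
            out[f"OIS Object Identification Accuracy - {stage}"] = (
                sm.object_identification_accuracy if sm else nan
            )
            out[f"OIS Semantic Identification Accuracy - {stage}"] = (
                sm.semantic_identification_accuracy if sm else nan
            )
            out[f"OIS Location Error - {stage} (cm)"] = sm.location_error if sm else nan
    if session.rocf:
        for r in session.rocf:
            label = "Copy" if r.stage == "copy" else "Immediate Recall"
            out[f"ROCF {label} Score (%)"] = score_rocf(r.placements).percent
    if session.corsi:
        c = score_corsi(session.corsi)
        out["CORSI Mean Location Error (cm)"] = c.mean_location_error
    if session.dsst:
        d = score_dsst(session.dsst, window=session.dsst_window_s)
        out["DSST Number of Correct Responses"] = float(d.correct_count)
    if session.tmt:
        t = score_tmt(session.tmt)
        out["TMT-A Average Completion Time (s)"] = t.mean_time_a
        out["TMT-B Average Completion Time (s)"] = t.mean_time_b
        out["TMT-Motor Average Completion Time (s)"] = t.mean_time_motor
    return out
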