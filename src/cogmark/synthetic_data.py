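"""Synthetic cohorts of trial-level task responses and plasma biomarker panels.

The generator emulates the study structure the pipeline is built for: an
Alzheimer's disease group (AD, n=46) and an in-person elderly control group
(EHC1, n=53), both with plasma panels, plus a larger online normative control
group (EHC2, n=352) without blood sampling.

A single latent *severity* value per participant drives every task parameter
and, through per-biomarker coupling fractions, the plasma panel. This shared
factor is what produces the joint structure downstream analyses must recover:
AD impaired on every metric, and biomarker-cognition correlations strongest
for p-tau181 and weakest for the Aβ42/40 ratio. Group biomarker levels are
log-normal with raw-scale moments matched to the published cohort means/SDs.

All randomness flows from one integer seed; the same config is bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .session_io import (
    BiomarkerPanel,
    CorsiTrial,
    Demographics,
    DSSTResponse,
    OISTrial,
    OMTTrial,
    Questionnaires,
    ROCFResponse,
    SessionRecord,
    TMTTrial,
)
from .task_scoring import OMT_GUESS_THRESHOLD_CM, ROCF_TEMPLATE

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: raw-scale (mean, SD) of the log-normally generated biomarkers per group,
#: pg/mL except the dimensionless Aβ42/40 ratio. Aβ42 is derived as
#: ratio x Aβ40 so the ratio keeps exactly these moments.
DEFAULT_BIOMARKER_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "ptau181": {"AD": (5.4, 3.4), "EHC1": (2.6, 1.3)},
    "gfap": {"AD": (224.7, 118.0), "EHC1": (111.8, 57.9)},
    "nfl": {"AD": (29.7, 19.0), "EHC1": (17.1, 11.0)},
    "abeta_ratio": {"AD": (0.059, 0.01), "EHC1": (0.067, 0.01)},
    "abeta40": {"AD": (115.2, 25.7), "EHC1": (108.4, 19.9)},
}

#: fraction of the between-group log-scale slope that also operates *within*
#: group (via latent severity). Orders the biomarker-cognition correlation
#: strengths: p-tau181 strongest, Aβ42/40 ratio weakest.
DEFAULT_BIOMARKER_COUPLING: dict[str, float] = {
    "ptau181": 1.0,
    "gfap": 0.15,
    "nfl": 1.0,
    "abeta_ratio": 0.05,
    "abeta40": 0.05,
}

#: latent severity (mean, SD) per group: controls separate at 0, the AD group
#: sits two within-group SD-units higher, the online normative group slightly
#: above the in-person controls (it performs a little worse, with more spread).
DEFAULT_GROUP_EFFECTS: dict[str, tuple[float, float]] = {
    "AD": (2.0, 0.8),
    "EHC1": (0.0, 0.8),
    "EHC2": (0.35, 0.8),
}

DEFAULT_AGE_PARAMS: dict[str, tuple[float, float]] = {
    "AD": (68.3, 10.2),
    "EHC1": (68.6, 7.0),
    "EHC2": (59.9, 8.5),
}


class TrialCounts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    omt_one_item: int = Field(default=20, ge=0)
    omt_three_item: int = Field(default=20, ge=0)
    ois_pairs: int = Field(default=20, ge=1)  # probed at both recall stages
    corsi_per_length: int = Field(default=5, ge=1)
    corsi_max_length: int = Field(default=5, ge=1, le=9)
    tmt_a: int = Field(default=3, ge=0)
    tmt_b: int = Field(default=3, ge=0)
    tmt_motor: int = Field(default=4, ge=0)
    dsst_window_s: float = Field(default=120.0, gt=0)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"AD": 46, "EHC1": 53, "EHC2": 352}
    )
    group_effects: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    biomarker_params: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BIOMARKER_PARAMS.items()}
    )
    biomarker_coupling: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_COUPLING)
    )
    age_params: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    age_range: tuple[float, float] = (50.0, 95.0)
    arena_cm: tuple[float, float] = (28.0, 16.0)
    trial_counts: TrialCounts = Field(default_factory=TrialCounts)
    #: inject a >60 s idle gap into every DSST session (attention-check testing)
    inject_dsst_idle: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g}] must be >= 1")
        for g, (_, sd) in self.group_effects.items():
            if sd <= 0:
                raise ValueError(f"group_effects[{g}] SD scale must be > 0")
        lo, hi = self.age_range
        if not (50.0 <= lo < hi <= 95.0):
            raise ValueError("age_range must be within [50, 95]")
        for b, groups in self.biomarker_params.items():
            for g, (m, s) in groups.items():
                if m <= 0 or s <= 0:
                    raise ValueError(f"biomarker_params[{b}][{g}] must be positive")
        return self


class ResponderProfile(BaseModel):
    """Mixture description of one participant's OMT responding: a response is
    target-directed, misbound (centred on a non-target item), or a guess."""

    model_config = ConfigDict(extra="forbid")

    p_target: float = Field(ge=0, le=1)
    p_misbind: float = Field(ge=0, le=1)
    p_guess: float = Field(ge=0, le=1)
    sigma: float = Field(gt=0)  # spatial imprecision SD, cm
    p_identify: float = Field(default=1.0, ge=0, le=1)
    rt_ident_log_mu: float = math.log(1.5)
    rt_loc_log_mu: float = math.log(2.5)
    rt_log_sigma: float = 0.35

    @model_validator(mode="after")
    def _simplex(self) -> "ResponderProfile":
        total = self.p_target + self.p_misbind + self.p_guess
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"p_target + p_misbind + p_guess must be 1, got {total}")
        return self


def responder_profile_from_severity(d: float, rt_offset: float = 0.0) -> ResponderProfile:
    """Map latent severity to an OMT responder profile.

    Healthy responding (d = 0) is mostly target-directed with ~22% misbinding
    and ~6% guessing; severity shifts mass towards misbinding and guessing,
    inflates spatial imprecision, slows responses, and lowers identification.
    """
    p_guess = float(expit(-2.75 + 0.50 * d))
    p_mis_given = float(expit(-1.21 + 0.35 * d))
    p_misbind = (1.0 - p_guess) * p_mis_given
    return ResponderProfile(
        p_target=1.0 - p_guess - p_misbind,
        p_misbind=p_misbind,
        p_guess=p_guess,
        sigma=max(0.3, 0.75 + 0.20 * d),
        p_identify=float(expit(2.59 - 0.60 * d)),
        rt_ident_log_mu=math.log(1.5) + 0.30 * d + rt_offset,
        rt_loc_log_mu=math.log(2.5) + 0.30 * d + rt_offset,
    )


# ---------------------------------------------------------------------------
# OMT layouts and responses
# ---------------------------------------------------------------------------


def generate_omt_layout(
    n_items: int,
    arena: tuple[float, float] = (28.0, 16.0),
    rng: np.random.Generator | None = None,
    min_separation: float = 3.0,
    margin: float = 1.0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample ``n_items`` locations, pairwise >= ``min_separation`` cm
    apart and at least ``margin`` cm inside the arena bounds."""
    rng = np.random.default_rng() if rng is None else rng
    w, h = arena
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("arena too small for the requested margin")
    for _ in range(max_tries):
        pts = rng.uniform([margin, margin], [w - margin, h - margin], size=(n_items, 2))
        if n_items == 1:
            return pts
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        if d[np.triu_indices(n_items, k=1)].min() >= min_separation:
            return pts
    raise ValueError(
        f"could not place {n_items} items >= {min_separation} cm apart in a "
        f"{w} x {h} cm arena after {max_tries} attempts"
    )


def _uniform_outside_zones(
    centers: np.ndarray,
    arena: tuple[float, float],
    rng: np.random.Generator,
    radius: float,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Uniform point in the arena conditioned on lying >= radius from every centre."""
    w, h = arena
    for _ in range(max_tries):
        p = rng.uniform([0.0, 0.0], [w, h])
        if np.linalg.norm(centers - p, axis=1).min() >= radius:
            return p
    raise ValueError("guess region is empty: item zones cover the arena")


def generate_omt_trial_response(
    layout: np.ndarray,
    profile: ResponderProfile,
    rng: np.random.Generator,
    target_index: int = 0,
    arena: tuple[float, float] = (28.0, 16.0),
    guess_clear_zone: float = OMT_GUESS_THRESHOLD_CM,
) -> OMTTrial:
    """Draw one trial response under the target / misbind / guess mixture.

    Target- and misbind-directed placements are the chosen item's centre plus
    isotropic Gaussian noise of SD ``profile.sigma``. A guess is a placement
    not directed at any remembered item: uniform over the arena excluding the
    clear zone around every displayed item (the same clear zone the layout
    generator enforces). With a single item, misbinding mass is renormalized
    onto target and guess.
    """
    layout = np.asarray(layout, dtype=float)
    n = len(layout)
    if n < 1:
        raise ValueError("layout must contain at least one item")
    p_t, p_m, p_g = profile.p_target, profile.p_misbind, profile.p_guess
    if n == 1 and p_m > 0:
        rest = p_t + p_g
        if rest == 0:
            p_t, p_m, p_g = 1.0, 0.0, 0.0
        else:
            p_t, p_g, p_m = p_t / rest, p_g / rest, 0.0
    component = rng.choice(["target", "misbind", "guess"], p=[p_t, p_m, p_g])
    if component == "guess":
        placement = _uniform_outside_zones(layout, arena, rng, guess_clear_zone)
    else:
        if component == "target":
            centre = layout[target_index]
        else:
            others = [i for i in range(n) if i != target_index]
            centre = layout[int(rng.choice(others))]
        placement = centre + rng.normal(0.0, profile.sigma, size=2)
    identified = bool(rng.random() < profile.p_identify)
    rt_i = float(np.exp(rng.normal(profile.rt_ident_log_mu, profile.rt_log_sigma)))
    rt_l = float(np.exp(rng.normal(profile.rt_loc_log_mu, profile.rt_log_sigma)))
    return OMTTrial(
        n_items=n,
        item_locations=[tuple(map(float, p)) for p in layout],
        target_index=target_index,
        identified=identified,
        response_location=(float(placement[0]), float(placement[1])),
        identification_time=rt_i,
        localization_time=rt_l,
    )


def generate_omt_trials(
    profile: ResponderProfile,
    rng: np.random.Generator,
    n_one: int = 20,
    n_three: int = 20,
    arena: tuple[float, float] = (28.0, 16.0),
) -> list[OMTTrial]:
    trials = []
    for n_items in [1] * n_one + [3] * n_three:
        layout = generate_omt_layout(n_items, arena, rng)
        target = int(rng.integers(n_items))
        trials.append(generate_omt_trial_response(layout, profile, rng, target, arena))
    rng.shuffle(trials)
    return trials


# ---------------------------------------------------------------------------
# TMT maps
# ---------------------------------------------------------------------------


def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper intersection of open segments p1p2 and p3p4 (shared endpoints ok)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def path_has_crossing(points: np.ndarray) -> bool:
    n = len(points)
    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            if _segments_cross(points[i], points[i + 1], points[j], points[j + 1]):
                return True
    return False


def generate_tmt_map(
    n_circles: int = 25,
    arena: tuple[float, float] = (28.0, 16.0),
    rng: np.random.Generator | None = None,
    radius: float = 0.8,
    max_tries: int = 200,
) -> np.ndarray:
    """Trail map: ``n_circles`` non-overlapping circle centres, returned in
    visiting order along a non-self-intersecting path.

    Centres are rejection-sampled (pairwise distance >= 2*radius); the visiting
    order starts random and is uncrossed by 2-opt segment reversal, which
    strictly shortens the path and therefore terminates. Falls back to an
    x-monotone ordering (crossing-free by construction) if uncrossing stalls.
    """
    rng = np.random.default_rng() if rng is None else rng
    w, h = arena
    # dart-throwing: place circles one at a time, resampling on conflict
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_circles:
        p = rng.uniform([radius, radius], [w - radius, h - radius])
        if not placed or min(np.linalg.norm(q - p) for q in placed) >= 2 * radius:
            placed.append(p)
        else:
            tries += 1
            if tries > max_tries * n_circles:
                raise ValueError(
                    f"could not place {n_circles} non-overlapping circles in the arena"
                )
    pts = np.array(placed)

    order = rng.permutation(n_circles)
    path = pts[order]
    for _ in range(500):
        swapped = False
        n = len(path)
        for i in range(n - 1):
            for j in range(i + 2, n - 1):
                if _segments_cross(path[i], path[i + 1], path[j], path[j + 1]):
                    path[i + 1 : j + 1] = path[i + 1 : j + 1][::-1]
                    swapped = True
        if not swapped:
            break
    if path_has_crossing(path):
        path = path[np.lexsort((path[:, 1], path[:, 0]))]
    return path


def tmt_labels(condition: str, n: int = 25) -> list[str]:
    if condition == "A":
        return [str(i) for i in range(1, n + 1)]
    letters = [chr(ord("A") + i) for i in range(26)]
    out, num, let = [], 1, 0
    while len(out) < n:
        out.append(str(num))
        num += 1
        if len(out) < n:
            out.append(letters[let])
            let += 1
    return out


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------


def _lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Natural-log (mu, sigma) of a log-normal with the given raw moments."""
    var_log = math.log1p((sd / mean) ** 2)
    return math.log(mean) - var_log / 2.0, math.sqrt(var_log)


def _biomarker_model(config: CohortConfig) -> dict[str, dict]:
    """Per-biomarker log-scale group intercepts, severity slope, and residual SD.

    The slope is identified from the AD vs EHC1 log-mean difference and the
    configured severity separation; the coupling fraction sets how much of it
    also acts within group. Residual SD is chosen so the total within-group
    log-variance reproduces the configured moments, which keeps raw-scale
    sample means on target.
    """
    d_ad = config.group_effects.get("AD", (0.0, 1.0))[0]
    d_ehc1 = config.group_effects.get("EHC1", (0.0, 1.0))[0]
    sep = d_ad - d_ehc1
    model: dict[str, dict] = {}
    for b, groups in config.biomarker_params.items():
        mus, sigmas = {}, {}
        for g, (m, s) in groups.items():
            mus[g], sigmas[g] = _lognormal_from_moments(m, s)
        if "AD" in mus and "EHC1" in mus and sep != 0:
            beta = (mus["AD"] - mus["EHC1"]) / sep
        else:
            beta = 0.0
        kappa = config.biomarker_coupling.get(b, 0.0)
        resid = {}
        for g in mus:
            sd_d = config.group_effects.get(g, (0.0, 1.0))[1]
            within = kappa * beta * sd_d
            resid[g] = math.sqrt(max(sigmas[g] ** 2 - within**2, (0.15 * sigmas[g]) ** 2))
        model[b] = {"mu": mus, "beta": beta, "kappa": kappa, "resid": resid}
    return model


def generate_biomarker_panel(
    participant_id: str,
    group: str,
    severity: float,
    config: CohortConfig,
    rng: np.random.Generator,
    visit: int = 1,
) -> Optional[BiomarkerPanel]:
    """Log-normal plasma panel coupled to latent severity; None for groups
    without configured biomarker parameters (the online normative group)."""
    model = _biomarker_model(config)
    values: dict[str, float] = {}
    mean_d = config.group_effects.get(group, (0.0, 1.0))[0]
    for b, m in model.items():
        if group not in m["mu"]:
            return None
        log_val = (
            m["mu"][group]
            + m["kappa"] * m["beta"] * (severity - mean_d)
            + rng.normal(0.0, m["resid"][group])
        )
        values[b] = math.exp(log_val)
    abeta40 = values["abeta40"]
    ratio = values["abeta_ratio"]
    return BiomarkerPanel(
        participant_id=participant_id,
        visit=visit,
        ptau181=values["ptau181"],
        gfap=values["gfap"],
        nfl=values["nfl"],
        abeta40=abeta40,
        abeta42=ratio * abeta40,
        abeta_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# other tasks
# ---------------------------------------------------------------------------

_OIS_CATEGORIES = [
    "guitar", "lamp", "mug", "clock", "plant",
    "chair", "book", "hat", "kettle", "ball",
]


def _generate_ois_trials(
    d: float, rng: np.random.Generator, n_pairs: int, arena: tuple[float, float]
) -> list[OISTrial]:
    """Each studied object-scene pair is probed immediately and again delayed.

    The 20-object pool is 10 categories x 2 exemplars; the same-category foil
    makes semantic accuracy dissociable from object accuracy.
    """
    pool = [(c, i) for c in _OIS_CATEGORIES for i in (1, 2)]
    p_obj = {"immediate": float(expit(2.8 - 0.70 * d)), "delayed": float(expit(2.6 - 0.90 * d))}
    p_guess_loc = float(expit(-3.5 + 1.10 * d))
    sigma = max(0.2, 0.8 + 0.35 * d)
    w, h = arena
    trials = []
    for _ in range(n_pairs):
        cat, ex = pool[int(rng.integers(len(pool)))]
        target_obj = f"{cat}_{ex}"
        loc = rng.uniform([1.0, 1.0], [w - 1.0, h - 1.0])
        for stage in ("immediate", "delayed"):
            if rng.random() < p_obj[stage]:
                chosen_cat, chosen_obj = cat, target_obj
            elif rng.random() < 0.55:  # semantic memory intact: category foil
                chosen_cat, chosen_obj = cat, f"{cat}_{3 - ex}"
            else:
                other = _OIS_CATEGORIES[int(rng.integers(len(_OIS_CATEGORIES) - 1))]
                if other == cat:
                    other = _OIS_CATEGORIES[-1]
                chosen_cat, chosen_obj = other, f"{other}_{int(rng.integers(1, 3))}"
            if rng.random() < p_guess_loc:
                resp = rng.uniform([0.0, 0.0], [w, h])
            else:
                resp = loc + rng.normal(0.0, sigma, size=2)
            trials.append(
                OISTrial(
                    stage=stage,
                    target_object=target_obj,
                    target_category=cat,
                    chosen_object=chosen_obj,
                    chosen_category=chosen_cat,
                    target_location=(float(loc[0]), float(loc[1])),
                    response_location=(float(resp[0]), float(resp[1])),
                )
            )
    return trials


def _generate_rocf_response(d: float, rng: np.random.Generator, stage: str) -> ROCFResponse:
    if stage == "copy":
        p_omit = float(expit(-5.0 + 1.3 * d))
        log_disp_mu, log_disp_sd = math.log(0.08) + 0.9 * d, 0.8
    else:
        p_omit = float(expit(-3.2 + 0.9 * d))
        log_disp_mu, log_disp_sd = math.log(0.30) + 1.0 * d, 0.9
    placements: dict[str, tuple[float, float]] = {}
    for name, (x, y) in ROCF_TEMPLATE.items():
        if name != "large_rectangle" and rng.random() < p_omit:
            continue
        disp = math.exp(rng.normal(log_disp_mu, log_disp_sd))
        theta = rng.uniform(0, 2 * math.pi)
        placements[name] = (x + disp * math.cos(theta), y + disp * math.sin(theta))
    return ROCFResponse(stage=stage, placements=placements)


def _generate_corsi_trials(
    d: float, rng: np.random.Generator, per_length: int, max_length: int,
    arena: tuple[float, float],
) -> list[CorsiTrial]:
    p_guess = float(expit(-3.2 + 0.8 * d))
    sigma = max(0.2, 1.0 + 0.5 * d)
    w, h = arena
    trials = []
    for length in range(1, max_length + 1):
        for _ in range(per_length):
            seq = rng.uniform([0.5, 0.5], [w - 0.5, h - 0.5], size=(length, 2))
            resp = []
            for p in seq:
                if rng.random() < p_guess:
                    resp.append(tuple(map(float, rng.uniform([0, 0], [w, h]))))
                else:
                    resp.append(tuple(map(float, p + rng.normal(0.0, sigma, size=2))))
            trials.append(
                CorsiTrial(sequence=[tuple(map(float, p)) for p in seq], response=resp)
            )
    return trials


def _generate_dsst_responses(
    d: float, rng: np.random.Generator, window: float, inject_idle: bool
) -> list[DSSTResponse]:
    irt_mu = math.log(2.3) + 0.28 * d
    p_correct = float(expit(3.0 - 0.45 * d))
    t = 0.0
    responses = []
    idle_injected = not inject_idle
    while True:
        gap = float(np.exp(rng.normal(irt_mu, 0.30)))
        if not idle_injected and t > window / 3:
            gap += 70.0  # single long idle period for attention-check testing
            idle_injected = True
        t += gap
        if t >= window:
            break
        responses.append(DSSTResponse(timestamp=t, correct=bool(rng.random() < p_correct)))
    return responses


def _generate_tmt_trials(
    d: float,
    rng: np.random.Generator,
    counts: TrialCounts,
) -> list[TMTTrial]:
    trials = []
    p_incomplete = float(expit(-4.0 + 0.7 * d))
    specs = [("A", counts.tmt_a, math.log(28.0) + 0.40 * d, 25)]
    specs += [("B", counts.tmt_b, math.log(65.0) + 0.45 * d, 25)]
    specs += [("motor", counts.tmt_motor, math.log(3.5) + 0.20 * d, 2)]
    for condition, n_trials, log_mu, n_targets in specs:
        for _ in range(n_trials):
            total = float(np.exp(rng.normal(log_mu, 0.25)))
            fracs = np.sort(rng.uniform(0.05, 1.0, size=n_targets - 1))
            clicks = list(np.concatenate([total * fracs, [total]]))
            completed = rng.random() >= p_incomplete
            if not completed:
                clicks = clicks[: max(1, n_targets // 2)]
            trials.append(
                TMTTrial(
                    condition=condition,
                    n_targets=n_targets,
                    click_times=[float(c) for c in clicks],
                    completed=completed,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_ACE_PARAMS = {"AD": (63.5, 20.0), "EHC1": (97.4, 2.0), "EHC2": (95.0, 3.0)}
_AMI_PARAMS = {"AD": (1.5, 0.3), "EHC1": (1.2, 0.4), "EHC2": (1.5, 0.4)}
_GDS_PARAMS = {"AD": (6.9, 1.9), "EHC1": (4.9, 1.1), "EHC2": (5.7, 2.0)}


def generate_session(
    participant_id: str,
    group: str,
    severity: float,
    config: CohortConfig,
    rng: np.random.Generator,
    visit: int = 1,
) -> SessionRecord:
    counts = config.trial_counts
    arena = config.arena_cm
    lo, hi = config.age_range
    mu_age, sd_age = config.age_params.get(group, (65.0, 8.0))
    age = float(np.clip(rng.normal(mu_age, sd_age), lo, hi))
    rt_offset = float(rng.normal(0.0, 0.15))
    profile = responder_profile_from_severity(severity, rt_offset)

    draw_date = _dt.date(2024, 1, 15) if group in ("AD", "EHC1") else None
    session_date = (
        draw_date + _dt.timedelta(days=int(rng.integers(1, 8)))
        if draw_date
        else _dt.date(2024, 1, 20)
    )

    def q(params):
        m, s = params[group]
        return float(rng.normal(m, s))

    return SessionRecord(
        participant_id=participant_id,
        visit=visit,
        group=group,
        demographics=Demographics(
            age=age,
            sex="M" if rng.random() < 0.5 else "F",
            education_years=float(np.clip(rng.normal(15.0, 3.0), 6, 25)),
        ),
        session_date=session_date,
        blood_draw_date=draw_date,
        omt=generate_omt_trials(
            profile, rng, counts.omt_one_item, counts.omt_three_item, arena
        ),
        ois=_generate_ois_trials(severity, rng, counts.ois_pairs, arena),
        rocf=[
            _generate_rocf_response(severity, rng, "copy"),
            _generate_rocf_response(severity, rng, "recall"),
        ],
        corsi=_generate_corsi_trials(
            severity, rng, counts.corsi_per_length, counts.corsi_max_length, arena
        ),
        dsst=_generate_dsst_responses(
            severity, rng, counts.dsst_window_s, config.inject_dsst_idle
        ),
        dsst_window_s=counts.dsst_window_s,
        tmt=_generate_tmt_trials(severity, rng, counts),
        questionnaires=Questionnaires(
            ace_total=float(np.clip(q(_ACE_PARAMS), 0, 100)),
            ami_total=float(np.clip(q(_AMI_PARAMS), 0, 4)),
            gds_total=float(np.clip(q(_GDS_PARAMS), 0, 15)),
            validation_answers=["Completely untrue", "Completely untrue"],
        ),
    )


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[SessionRecord, Optional[BiomarkerPanel]]]:
    """Generate the full cohort: one (session, panel) pair per participant,
    deterministic in ``config.seed``. Groups without biomarker parameters get
    ``None`` panels (no blood draw)."""
    rng = np.random.default_rng(config.seed)
    cohort: list[tuple[SessionRecord, Optional[BiomarkerPanel]]] = []
    for group in sorted(config.n_per_group):
        mean_d, sd_d = config.group_effects.get(group, (0.0, 1.0))
        for i in range(config.n_per_group[group]):
            pid = f"{group}-{i + 1:03d}"
            severity = float(rng.normal(mean_d, sd_d))
            session = generate_session(pid, group, severity, config, rng)
            panel = generate_biomarker_panel(pid, group, severity, config, rng)
            cohort.append((session, panel))
    return cohort
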