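import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats as sps

from cogmark.synthetic_data import (
    CohortConfig,
    ResponderProfile,
    TrialCounts,
    generate_biomarker_panel,
    generate_cohort,
    generate_omt_layout,
    generate_omt_trial_response,
    generate_tmt_map,
    path_has_crossing,
    responder_profile_from_severity,
)

SMALL = dict(
    n_per_group={"AD": 3, "EHC1": 3, "EHC2": 5},
    trial_counts=TrialCounts(
        omt_one_item=3, omt_three_item=3, ois_pairs=4,
        corsi_per_length=1, corsi_max_length=3,
        tmt_a=1, tmt_b=1, tmt_motor=1, dsst_window_s=30.0,
    ),
)


def test_same_seed_gives_byte_identical_cohort():
    a = generate_cohort(CohortConfig(seed=7, **SMALL))
    b = generate_cohort(CohortConfig(seed=7, **SMALL))
    assert len(a) == len(b)
    for (sa, pa), (sb, pb) in zip(a, b):
        assert sa.model_dump_json() == sb.model_dump_json()
        assert (pa is None) == (pb is None)
        if pa is not None:
            assert pa.model_dump_json() == pb.model_dump_json()


def test_different_seed_changes_cohort():
    a = generate_cohort(CohortConfig(seed=7, **SMALL))
    b = generate_cohort(CohortConfig(seed=8, **SMALL))
    assert a[0][0].model_dump_json() != b[0][0].model_dump_json()


def test_config_validation_names_offending_field():
    with pytest.raises((ValidationError, ValueError), match="n_per_group"):
        CohortConfig(seed=1, n_per_group={"AD": 0})
    with pytest.raises((ValidationError, ValueError), match="age_range"):
        CohortConfig(seed=1, age_range=(40, 95))
    with pytest.raises((ValidationError, ValueError), match="group_effects"):
        CohortConfig(seed=1, group_effects={"AD": (1.0, 0.0)})


def test_responder_profile_requires_probability_simplex():
    with pytest.raises(ValidationError):
        ResponderProfile(p_target=0.5, p_misbind=0.5, p_guess=0.5, sigma=1.0)
    p = ResponderProfile(p_target=0.6, p_misbind=0.3, p_guess=0.1, sigma=1.0)
    assert p.p_target + p.p_misbind + p.p_guess == pytest.approx(1.0, abs=1e-12)


def test_omt_layout_respects_separation_and_bounds(rng):
    arena = (28.0, 16.0)
    for _ in range(500):
        pts = generate_omt_layout(3, arena, rng)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert d[np.triu_indices(3, k=1)].min() >= 3.0
        assert (pts >= 1.0).all()
        assert (pts[:, 0] <= arena[0] - 1.0).all() and (pts[:, 1] <= arena[1] - 1.0).all()


def test_omt_layout_single_item_in_bounds(rng):
    pts = generate_omt_layout(1, (28.0, 16.0), rng)
    assert pts.shape == (1, 2)


def test_omt_layout_infeasible_arena_raises(rng):
    with pytest.raises(ValueError):
        generate_omt_layout(3, (2.0, 2.0), rng, max_tries=200)


def test_noiseless_target_responder_places_on_target(rng):
    layout = np.array([[5.0, 5.0], [12.0, 5.0], [20.0, 10.0]])
    profile = ResponderProfile(p_target=1.0, p_misbind=0.0, p_guess=0.0, sigma=1e-9)
    for target in range(3):
        t = generate_omt_trial_response(layout, profile, rng, target_index=target)
        assert np.allclose(t.response_location, layout[target], atol=1e-6)


def test_pure_guesser_uniform_outside_item_zones(rng):
    """Guesses cover the arena uniformly outside the 3-cm clear zones around items."""
    arena = (28.0, 16.0)
    layout = np.array([[6.0, 6.0], [14.0, 8.0], [22.0, 10.0]])
    profile = ResponderProfile(p_target=0.0, p_misbind=0.0, p_guess=1.0, sigma=1.0)
    pts = np.array(
        [
            generate_omt_trial_response(layout, profile, rng).response_location
            for _ in range(10_000)
        ]
    )
    # never inside a clear zone
    d = np.linalg.norm(pts[:, None, :] - layout[None, :, :], axis=-1)
    assert d.min(axis=1).min() >= 3.0
    # chi-square uniformity over cells fully outside the zones
    xs = np.linspace(0, arena[0], 8)
    ys = np.linspace(0, arena[1], 5)
    counts, areas = [], []
    for i in range(7):
        for j in range(4):
            corners = np.array(
                [[xs[i], ys[j]], [xs[i + 1], ys[j]], [xs[i], ys[j + 1]], [xs[i + 1], ys[j + 1]]]
            )
            centre = corners.mean(axis=0)
            probe = np.vstack([corners, centre])
            if np.linalg.norm(probe[:, None, :] - layout[None, :, :], axis=-1).min() < 3.0:
                continue  # cell touches a clear zone
            inside = (
                (pts[:, 0] >= xs[i]) & (pts[:, 0] < xs[i + 1])
                & (pts[:, 1] >= ys[j]) & (pts[:, 1] < ys[j + 1])
            )
            counts.append(inside.sum())
            areas.append((xs[i + 1] - xs[i]) * (ys[j + 1] - ys[j]))
    counts, areas = np.array(counts), np.array(areas)
    expected = counts.sum() * areas / areas.sum()
    _, p = sps.chisquare(counts, expected)
    assert p > 0.01


def test_single_item_renormalizes_misbinding_mass(rng):
    layout = np.array([[10.0, 8.0]])
    profile = ResponderProfile(p_target=0.6, p_misbind=0.3, p_guess=0.1, sigma=0.5)
    # must not raise, and guesses/targets only
    trials = [generate_omt_trial_response(layout, profile, rng) for _ in range(200)]
    assert all(t.n_items == 1 for t in trials)


def test_tmt_maps_valid_and_deterministic():
    rng = np.random.default_rng(3)
    maps = [generate_tmt_map(25, rng=rng, radius=0.8) for _ in range(50)]
    for pts in maps:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert d[np.triu_indices(25, k=1)].min() >= 1.6  # no overlapping circles
        assert not path_has_crossing(pts)
    again = generate_tmt_map(25, rng=np.random.default_rng(11))
    once = generate_tmt_map(25, rng=np.random.default_rng(11))
    assert np.array_equal(again, once)


def test_tmt_path_segments_noncrossing_brute_force(rng):
    """Independent O(n^2) segment-intersection sweep over consecutive-label legs."""

    def cross(p1, p2, p3, p4):
        def o(a, b, c):
            v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

        return (
            o(p1, p2, p3) != o(p1, p2, p4)
            and o(p3, p4, p1) != o(p3, p4, p2)
            and 0 not in (o(p1, p2, p3), o(p1, p2, p4), o(p3, p4, p1), o(p3, p4, p2))
        )

    for _ in range(20):
        pts = generate_tmt_map(25, rng=rng)
        segs = list(zip(pts[:-1], pts[1:]))
        for i in range(len(segs)):
            for j in range(i + 2, len(segs)):
                assert not cross(*segs[i], *segs[j])


def test_ad_ptau_sample_mean_matches_configured_moments():
    """Raw-scale geometric-to-arithmetic moment matching: AD p-tau181 mean 5.4,
    in-person control mean 2.6 pg/mL, within 2% at n=10,000."""
    config = CohortConfig(seed=5)
    rng = np.random.default_rng(5)
    for group, mean_d, expected in [("AD", 2.0, 5.4), ("EHC1", 0.0, 2.6)]:
        sd_d = config.group_effects[group][1]
        vals = []
        for i in range(10_000):
            d = rng.normal(mean_d, sd_d)
            panel = generate_biomarker_panel(f"x{i}", group, d, config, rng)
            vals.append(panel.ptau181)
        assert np.mean(vals) == pytest.approx(expected, rel=0.02)


def test_ehc2_has_no_biomarker_panel():
    cohort = generate_cohort(CohortConfig(seed=2, **SMALL))
    for s, p in cohort:
        if s.group == "EHC2":
            assert p is None
        else:
            assert p is not None
            assert p.abeta_ratio == pytest.approx(p.abeta42 / p.abeta40)


def test_zero_group_effects_yield_null_group_separation():
    """With all severity means equal, the downstream per-metric AD-vs-control AUC
    sits at chance (within 0.03 at n=1,000/group)."""
    from cogmark.classification import auc_mann_whitney
    from cogmark.task_scoring import PRIMARY_METRICS, score_session

    config = CohortConfig(
        seed=99,
        n_per_group={"AD": 1000, "EHC1": 1000},
        group_effects={"AD": (0.0, 0.6), "EHC1": (0.0, 0.6)},
        trial_counts=TrialCounts(
            omt_one_item=2, omt_three_item=4, ois_pairs=4,
            corsi_per_length=1, corsi_max_length=3,
            tmt_a=1, tmt_b=1, tmt_motor=1, dsst_window_s=20.0,
        ),
    )
    cohort = generate_cohort(config)
    import pandas as pd

    rows = [{"group": s.group, **score_session(s)} for s, _ in cohort]
    df = pd.DataFrame(rows)
    labels = (df["group"] == "AD").astype(int).to_numpy()
    for metric in PRIMARY_METRICS:
        vals = df[metric].to_numpy()
        ok = ~np.isnan(vals)
        auc = auc_mann_whitney(vals[ok], labels[ok])
        assert abs(auc - 0.5) < 0.03, f"{metric}: AUC {auc:.3f}"


def test_severity_profile_mapping_monotone():
    healthy = responder_profile_from_severity(0.0)
    impaired = responder_profile_from_severity(2.0)
    assert impaired.p_target < healthy.p_target
    assert impaired.p_misbind > healthy.p_misbind
    assert impaired.p_guess > healthy.p_guess
    assert impaired.sigma > healthy.sigma
    assert impaired.p_identify < healthy.p_identify
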