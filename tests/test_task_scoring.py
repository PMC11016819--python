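import math

import numpy as np
import pytest

from cogmark.session_io import CorsiTrial, DSSTResponse, TMTTrial
from cogmark.synthetic_data import (
    ResponderProfile,
    generate_omt_layout,
    generate_omt_trial_response,
)
from cogmark.task_scoring import (
    ROCF_TEMPLATE,
    score_corsi,
    score_dsst,
    score_ois,
    score_omt,
    score_rocf,
    score_tmt,
)
from conftest import make_ois_trial, perfect_omt_trial


class TestOMT:
    def test_perfect_responses(self):
        trials = [perfect_omt_trial(3, t) for t in range(3)]
        m = score_omt(trials)
        assert m.identification_accuracy == 1.0
        assert m.location_error == 0.0
        assert m.target_detection_rate == 1.0
        assert m.misbinding_rate == 0.0
        assert m.guessing_rate == 0.0

    def test_rates_sum_to_one(self, rng):
        profile = ResponderProfile(p_target=0.5, p_misbind=0.3, p_guess=0.2, sigma=0.75)
        trials = [
            generate_omt_trial_response(generate_omt_layout(3, rng=rng), profile, rng)
            for _ in range(300)
        ]
        m = score_omt(trials)
        total = m.target_detection_rate + m.misbinding_rate + m.guessing_rate
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_single_item_trials_cannot_misbind(self, rng):
        profile = ResponderProfile(p_target=0.6, p_misbind=0.3, p_guess=0.1, sigma=0.75)
        trials = [
            generate_omt_trial_response(generate_omt_layout(1, rng=rng), profile, rng)
            for _ in range(300)
        ]
        assert score_omt(trials).misbinding_rate == 0.0

    def test_no_identified_trials_flags_location_error_missing(self):
        t = perfect_omt_trial()
        t = t.model_copy(update={"identified": False})
        m = score_omt([t])
        assert math.isnan(m.location_error)
        assert m.identification_accuracy == 0.0

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            score_omt([])


class TestOIS:
    def test_uniform_chooser_hits_pool_chance_levels(self):
        """Exhaustive enumeration over the 20-object pool: object accuracy 1/20,
        semantic accuracy 2/20 (the pool holds one same-category foil)."""
        cats = [f"cat{i}" for i in range(10)]
        pool = [(c, i) for c in cats for i in (1, 2)]
        trials = [
            make_ois_trial(
                chosen=f"{c}_{i}", chosen_cat=c, target="cat0_1", target_cat="cat0"
            )
            for c, i in pool
        ]
        m = score_ois(trials).immediate
        assert m.object_identification_accuracy == pytest.approx(0.05)
        assert m.semantic_identification_accuracy == pytest.approx(0.10)

    def test_perfect_responder(self):
        m = score_ois([make_ois_trial(), make_ois_trial(stage="delayed")])
        for stage in (m.immediate, m.delayed):
            assert stage.object_identification_accuracy == 1.0
            assert stage.semantic_identification_accuracy == 1.0
            assert stage.location_error == 0.0

    def test_semantic_accuracy_never_below_object_accuracy(self, rng):
        trials = []
        for _ in range(100):
            correct = rng.random() < 0.5
            semantic_only = rng.random() < 0.5
            if correct:
                trials.append(make_ois_trial())
            elif semantic_only:
                trials.append(make_ois_trial(chosen="guitar_2", chosen_cat="guitar"))
            else:
                trials.append(make_ois_trial(chosen="lamp_1", chosen_cat="lamp"))
        m = score_ois(trials).immediate
        assert m.semantic_identification_accuracy >= m.object_identification_accuracy


class TestROCF:
    def test_perfect_placement_full_marks(self):
        r = score_rocf(dict(ROCF_TEMPLATE))
        assert r.raw_sum == pytest.approx(13.0)
        assert r.percent == pytest.approx(100.0)

    def test_nothing_placed_scores_zero(self):
        r = score_rocf({})
        assert r.percent == 0.0
        assert r.anchor_fallback

    def test_one_far_element_scores_zero_rest_full(self):
        placements = dict(ROCF_TEMPLATE)
        x, y = placements["right_triangle"]
        placements["right_triangle"] = (x + 50.0, y)  # way past the far cutoff
        r = score_rocf(placements)
        assert r.raw_sum == pytest.approx(12.0)
        assert r.percent == pytest.approx(92.31, abs=0.01)

    def test_unplaced_element_scores_zero(self):
        placements = dict(ROCF_TEMPLATE)
        del placements["lower_cross"]
        r = score_rocf(placements)
        assert r.element_scores["lower_cross"] == 0.0
        assert r.raw_sum == pytest.approx(12.0)

    def test_missing_anchor_falls_back_to_template_position(self):
        placements = dict(ROCF_TEMPLATE)
        del placements["large_rectangle"]
        r = score_rocf(placements)
        assert r.anchor_fallback
        assert r.raw_sum == pytest.approx(12.0)  # others still perfect

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.8])
    def test_rigid_motion_invariance(self, angle):
        """Scores depend only on anchor-relative distances, so a joint rotation
        plus translation of every placement leaves the score unchanged."""
        shift = np.array([4.5, -2.0])
        rot = np.array([[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]])
        rng = np.random.default_rng(0)
        noisy = {
            k: tuple(np.asarray(v) + rng.normal(0, 1.0, 2)) for k, v in ROCF_TEMPLATE.items()
        }
        moved = {k: tuple(rot @ np.asarray(v) + shift) for k, v in noisy.items()}
        assert score_rocf(moved).raw_sum == pytest.approx(score_rocf(noisy).raw_sum, abs=1e-9)

    def test_scaling_is_monotone_in_displacement(self):
        base = dict(ROCF_TEMPLATE)
        scores = []
        for d in (0.0, 1.0, 3.0, 8.0, 12.0):
            p = dict(base)
            x, y = p["right_triangle"]
            p["right_triangle"] = (x + d, y)
            scores.append(score_rocf(p).element_scores["right_triangle"])
        assert scores[0] == 1.0
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[-1] == 0.0


class TestCorsi:
    def test_perfect_clicks(self):
        t = CorsiTrial(sequence=[(1.0, 1.0), (5.0, 5.0)], response=[(1.0, 1.0), (5.0, 5.0)])
        assert score_corsi([t]).mean_location_error == 0.0

    def test_constant_offset(self):
        t = CorsiTrial(sequence=[(1.0, 1.0), (5.0, 5.0)], response=[(3.0, 1.0), (7.0, 5.0)])
        assert score_corsi([t]).mean_location_error == pytest.approx(2.0)

    def test_short_response_charged_at_cap_and_flagged(self):
        t = CorsiTrial(sequence=[(1.0, 1.0), (5.0, 5.0)], response=[(1.0, 1.0)])
        m = score_corsi([t], cap=10.0)
        assert m.capped_trials == 1
        assert m.mean_location_error == pytest.approx(5.0)  # (0 + 10) / 2

    def test_random_clicks_match_monte_carlo_uniform_distance(self, rng):
        """Scorer agrees with a direct Monte-Carlo estimate of the mean
        uniform-to-uniform distance over the arena."""
        w, h = 28.0, 16.0
        seqs = rng.uniform([0, 0], [w, h], size=(10_000, 2))
        resps = rng.uniform([0, 0], [w, h], size=(10_000, 2))
        trials = [
            CorsiTrial(sequence=[tuple(s)], response=[tuple(r)]) for s, r in zip(seqs, resps)
        ]
        direct = float(np.mean(np.linalg.norm(seqs - resps, axis=1)))
        assert score_corsi(trials).mean_location_error == pytest.approx(direct, abs=1e-9)
        # and the estimate sits near the independent MC expectation
        a = rng.uniform([0, 0], [w, h], size=(200_000, 2))
        b = rng.uniform([0, 0], [w, h], size=(200_000, 2))
        expected = float(np.mean(np.linalg.norm(a - b, axis=1)))
        se = float(np.std(np.linalg.norm(seqs - resps, axis=1))) / math.sqrt(10_000)
        assert abs(direct - expected) < 4 * se

    def test_error_reported_per_sequence_length(self, rng):
        trials = []
        for length in (1, 2, 3):
            seq = [(float(i), 1.0) for i in range(length)]
            trials.append(CorsiTrial(sequence=seq, response=seq))
        assert set(score_corsi(trials).error_by_length) == {1, 2, 3}


class TestDSST:
    def test_counts_correct_in_window(self):
        responses = [DSSTResponse(timestamp=2.0 * i + 1, correct=i % 10 != 0) for i in range(40)]
        m = score_dsst(responses, window=120.0)
        in_window = [r for r in responses if r.timestamp < 120.0]
        assert m.correct_count == sum(r.correct for r in in_window)

    def test_response_after_window_excluded(self):
        responses = [DSSTResponse(timestamp=10.0, correct=True),
                     DSSTResponse(timestamp=121.0, correct=True)]
        assert score_dsst(responses, window=120.0).correct_count == 1

    def test_uniform_digit_guessing_sits_at_one_ninth(self):
        """A guesser matching one of nine digits: expected correct rate 1/9,
        printed as 11% when rounded to whole percent."""
        responses = [
            DSSTResponse(timestamp=float(i + 1), correct=(i % 9 == 0)) for i in range(90)
        ]
        m = score_dsst(responses, window=120.0)
        assert m.correct_rate == pytest.approx(1 / 9)
        assert round(100 * m.correct_rate) == 11

    def test_idle_time_accumulates_beyond_grace(self):
        responses = [
            DSSTResponse(timestamp=2.0, correct=True),
            DSSTResponse(timestamp=40.0, correct=True),   # 38 s gap -> 33 over grace
            DSSTResponse(timestamp=45.0, correct=True),   # 5 s gap -> 0
            DSSTResponse(timestamp=100.0, correct=True),  # 55 s gap -> 50
        ]
        m = score_dsst(responses, window=120.0, idle_grace=5.0)
        assert m.idle_time == pytest.approx(33.0 + 50.0)

    def test_non_monotone_timestamps_rejected(self):
        responses = [DSSTResponse(timestamp=5.0, correct=True),
                     DSSTResponse(timestamp=3.0, correct=True)]
        with pytest.raises(ValueError):
            score_dsst(responses)


class TestTMT:
    @staticmethod
    def _trial(condition, total, n_targets=25, completed=True):
        clicks = list(np.linspace(total / n_targets, total, n_targets)) if completed else [1.0]
        return TMTTrial(
            condition=condition, n_targets=n_targets, click_times=clicks, completed=completed
        )

    def test_mean_completion_time(self):
        trials = [self._trial("A", t) for t in (30.0, 40.0, 50.0)]
        assert score_tmt(trials).mean_time_a == pytest.approx(40.0)

    def test_motor_condition_never_pooled(self):
        trials = [self._trial("A", 30.0), self._trial("motor", 3.0, n_targets=2)]
        m = score_tmt(trials)
        assert m.mean_time_a == pytest.approx(30.0)
        assert m.mean_time_motor == pytest.approx(3.0)

    def test_incomplete_trials_excluded_from_mean(self):
        trials = [self._trial("A", 30.0), self._trial("A", 99.0, completed=False)]
        m = score_tmt(trials)
        assert m.mean_time_a == pytest.approx(30.0)
        assert m.incomplete_trials == 1

    def test_all_incomplete_yields_missing_not_zero(self):
        trials = [self._trial("A", 30.0, completed=False)]
        assert math.isnan(score_tmt(trials).mean_time_a)
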