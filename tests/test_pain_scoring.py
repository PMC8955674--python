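"""Rubric categories, boundary rules, and exhaustive flag combinations."""

from itertools import product

import pytest

import murihrv as m


def obs(**kw):
    kw.setdefault("body_weight", 30.0)
    kw.setdefault("body_temp", 36.5)
    return m.PainObservation(**kw)


class TestPhysiological:
    def test_weight_gain_above_ten_percent(self):
        assert m.score_physiological(obs(prev_body_weight=30.0, body_weight=33.5)) == 1

    def test_small_weight_change_is_normal(self):
        assert m.score_physiological(obs(prev_body_weight=30.0, body_weight=31.0)) == 0

    def test_exactly_ten_percent_is_normal(self):
        # the rule is strict: "more than 10%"
        assert m.score_physiological(obs(prev_body_weight=30.0, body_weight=33.0)) == 0

    def test_hypothermia_scores(self):
        # tumor-burdened mice present *below*-range temperatures
        assert m.score_physiological(obs(body_temp=35.6)) == 1

    def test_hyperthermia_scores(self):
        assert m.score_physiological(obs(body_temp=37.6)) == 1

    @pytest.mark.parametrize("temp", [35.8, 36.5, 37.4])
    def test_range_boundaries_inclusive(self, temp):
        assert m.score_physiological(obs(body_temp=temp)) == 0

    def test_above_only_mode_ignores_hypothermia(self):
        assert m.score_physiological(obs(body_temp=35.0), temp_above_only=True) == 0
        assert m.score_physiological(obs(body_temp=38.0), temp_above_only=True) == 1

    def test_diarrhea_scores(self):
        assert m.score_physiological(obs(diarrhea=True)) == 1

    def test_first_observation_skips_weight(self):
        assert m.score_physiological(obs(prev_body_weight=None)) == 0


class TestPostureAppearance:
    def test_no_signs(self):
        assert m.score_posture(obs()) == 0
        assert m.score_appearance(obs()) == 0

    def test_pinched_face_is_appearance(self):
        assert m.score_appearance(obs(pinched_face=True)) == 1

    def test_hunched_is_posture_not_appearance(self):
        o = obs(hunched_posture=True)
        assert m.score_posture(o) == 1
        assert m.score_appearance(o) == 0

    @pytest.mark.parametrize("flag", [
        "rough_hair_coat", "pinched_face", "distended_abdomen", "reluctance_to_move"])
    def test_each_appearance_flag(self, flag):
        assert m.score_appearance(obs(**{flag: True})) == 1


class TestActivity:
    def test_regular_activity_is_normal(self):
        events = tuple(range(0, 301, 10))
        assert m.score_activity(obs(activity_event_times=events)) == 0

    def test_no_events_scores(self):
        assert m.score_activity(obs()) == 1

    def test_single_long_gap_scores(self):
        events = (0.0, 31.0) + tuple(range(40, 301, 10))
        assert m.score_activity(obs(activity_event_times=events)) == 1

    def test_gap_of_exactly_thirty_seconds_is_normal(self):
        events = tuple(range(0, 301, 30))
        assert m.score_activity(obs(activity_event_times=events)) == 0

    def test_inactive_start_counts(self):
        events = tuple(range(40, 301, 10))
        assert m.score_activity(obs(activity_event_times=events)) == 1

    def test_events_outside_observation_rejected(self):
        with pytest.raises(m.ValidationError):
            obs(activity_event_times=(350.0,))


class TestTotal:
    def test_most_painful_case_scores_four(self):
        o = obs(
            prev_body_weight=30.0, body_weight=25.0, body_temp=35.0,
            diarrhea=True, hunched_posture=True, rough_hair_coat=True,
            pinched_face=True, activity_event_times=(),
        )
        assert m.total_pain_score(o).total == 4

    def test_normal_mouse_scores_zero(self):
        o = obs(prev_body_weight=30.0, body_weight=30.5,
                activity_event_times=tuple(range(0, 301, 10)))
        assert m.total_pain_score(o).total == 0

    def test_two_categories(self):
        o = obs(hunched_posture=True, diarrhea=True,
                activity_event_times=tuple(range(0, 301, 10)))
        assert m.total_pain_score(o).total == 2

    def test_monotone_in_sign_flags(self):
        flags = ["diarrhea", "hunched_posture", "rough_hair_coat",
                 "pinched_face", "distended_abdomen", "reluctance_to_move"]
        base = dict(activity_event_times=tuple(range(0, 301, 10)))
        for k in range(len(flags)):
            without = m.total_pain_score(obs(**base, **{f: True for f in flags[:k]}))
            with_one = m.total_pain_score(obs(**base, **{f: True for f in flags[:k + 1]}))
            assert with_one.total >= without.total

    def test_exhaustive_flag_combinations_match_brute_force(self):
        flags = ["diarrhea", "hunched_posture", "rough_hair_coat",
                 "pinched_face", "distended_abdomen", "reluctance_to_move"]
        active = tuple(range(0, 301, 10))
        for combo in product([False, True], repeat=len(flags)):
            kw = dict(zip(flags, combo))
            score = m.total_pain_score(obs(activity_event_times=active, **kw))
            expected = (
                int(kw["diarrhea"])
                + int(kw["hunched_posture"])
                + int(kw["rough_hair_coat"] or kw["pinched_face"]
                      or kw["distended_abdomen"] or kw["reluctance_to_move"])
            )
            assert score.total == expected
            assert 0 <= score.total <= 4
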