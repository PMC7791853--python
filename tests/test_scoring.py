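"""Rubric engine tests: exhaustive enumeration is the oracle throughout."""

import pytest

from lamscore.scoring import (
    FOOT_LIFT_LEVELS,
    GAIT_CIRCLE_LEVELS,
    GAIT_WALK_LEVELS,
    PULSE_LEVELS,
    MeierExam,
    ObelExam,
    check_inclusion,
    enumerate_attainable_totals,
    grade_obel,
    iter_valid_meier_exams,
    iter_valid_obel_exams,
    score_meier,
)


def _exam(**overrides) -> MeierExam:
    base = dict(
        weight_shifting=False,
        foot_lift_left="prompt",
        foot_lift_right="prompt",
        gait_walk="normal",
        gait_circle="normal",
        pulse_left="normal",
        pulse_right="normal",
    )
    base.update(overrides)
    return MeierExam(**base)


class TestMeier:
    @pytest.mark.parametrize(
        "overrides, total, parts",
        [
            ({}, 0, (0, 0, 0, 0, 0)),
            (
                dict(
                    weight_shifting=True,
                    foot_lift_left="unable",
                    foot_lift_right="unable",
                    gait_walk="severe",
                    gait_circle="not_assessed",
                    pulse_left="bounding",
                    pulse_right="bounding",
                ),
                12,
                (2, 2, 6, 0, 2),
            ),
            (
                dict(
                    weight_shifting=True,
                    foot_lift_left="reluctant",
                    gait_walk="moderate",
                    gait_circle="moderate",
                    pulse_left="bounding",
                ),
                9,
                (2, 1, 2, 2, 2),
            ),
        ],
    )
    def test_worked_examples(self, overrides, total, parts):
        s = score_meier(_exam(**overrides))
        assert s.total == total
        assert (
            s.weight_shifting_pts,
            s.foot_lift_pts,
            s.walk_pts,
            s.circle_pts,
            s.pulse_pts,
        ) == parts

    def test_severe_walk_skips_circle(self):
        s = score_meier(_exam(gait_walk="severe", gait_circle="not_assessed"))
        assert s.circle_skipped and s.circle_pts == 0 and s.walk_pts == 6

    def test_severe_walk_with_circle_assessed_rejected(self):
        with pytest.raises(ValueError, match="not_assessed"):
            _exam(gait_walk="severe", gait_circle="mild")

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            _exam(foot_lift_left="limping")

    def test_forelimb_criteria_take_worse_limb(self):
        s = score_meier(_exam(foot_lift_left="unable", foot_lift_right="prompt",
                              pulse_right="bounding"))
        assert s.foot_lift_pts == 2 and s.pulse_pts == 2

    def test_attainable_totals_span_full_scale(self):
        totals = enumerate_attainable_totals()
        assert totals == frozenset(range(13))
        assert max(totals) == 12 and min(totals) == 0

    def test_every_valid_exam_scores_within_scale(self):
        for exam in iter_valid_meier_exams():
            s = score_meier(exam)
            assert 0 <= s.total <= 12
            assert s.total in enumerate_attainable_totals()

    def test_worsening_any_single_criterion_never_decreases_total(self):
        for exam in iter_valid_meier_exams():
            base = score_meier(exam).total
            for worse in _single_criterion_worsenings(exam):
                assert score_meier(worse).total >= base


def _single_criterion_worsenings(exam: MeierExam):
    if not exam.weight_shifting:
        yield _replace(exam, weight_shifting=True)
    for field, levels in (
        ("foot_lift_left", FOOT_LIFT_LEVELS),
        ("foot_lift_right", FOOT_LIFT_LEVELS),
        ("pulse_left", PULSE_LEVELS),
        ("pulse_right", PULSE_LEVELS),
    ):
        idx = levels.index(getattr(exam, field))
        for worse in levels[idx + 1 :]:
            yield _replace(exam, **{field: worse})
    walk_idx = GAIT_WALK_LEVELS.index(exam.gait_walk)
    for worse in GAIT_WALK_LEVELS[walk_idx + 1 :]:
        circle = "not_assessed" if worse == "severe" else exam.gait_circle
        yield _replace(exam, gait_walk=worse, gait_circle=circle)
    if exam.gait_walk != "severe" and exam.gait_circle != "not_assessed":
        ordered = GAIT_CIRCLE_LEVELS[:4]  # normal..severe
        idx = ordered.index(exam.gait_circle)
        for worse in ordered[idx + 1 :]:
            yield _replace(exam, gait_circle=worse)


def _replace(exam: MeierExam, **kw) -> MeierExam:
    fields = dict(
        weight_shifting=exam.weight_shifting,
        foot_lift_left=exam.foot_lift_left,
        foot_lift_right=exam.foot_lift_right,
        gait_walk=exam.gait_walk,
        gait_circle=exam.gait_circle,
        pulse_left=exam.pulse_left,
        pulse_right=exam.pulse_right,
    )
    fields.update(kw)
    return MeierExam(**fields)


class TestObel:
    def test_sound_horse_grades_zero(self):
        assert grade_obel(ObelExam()).grade == 0

    def test_stilted_walk_difficult_turn_liftable_is_grade_two(self):
        exam = ObelExam(
            stilted_at_walk=True,
            turns_with_great_difficulty=True,
            forelimb_liftable="willingly",
        )
        assert grade_obel(exam).grade == 2

    def test_moves_only_if_forced_is_grade_four(self):
        exam = ObelExam(moves_only_if_forced=True, reluctant_to_walk=True)
        assert grade_obel(exam).grade == 4

    def test_reluctant_walk_difficult_lift_is_grade_three(self):
        exam = ObelExam(reluctant_to_walk=True, forelimb_liftable="with_great_difficulty")
        assert grade_obel(exam).grade == 3

    def test_every_valid_exam_gets_exactly_one_grade(self):
        count = 0
        for exam in iter_valid_obel_exams():
            assert grade_obel(exam).grade in (0, 1, 2, 3, 4)
            count += 1
        assert count > 0

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            ObelExam(moves_only_if_forced=True, reluctant_to_walk=False)
        with pytest.raises(ValueError):
            ObelExam(sound_at_walk=True, stilted_at_walk=True)


class TestInclusion:
    def test_threshold_pairs(self):
        assert check_inclusion(5, 1) is True
        assert check_inclusion(4, 4) is False
        assert check_inclusion(12, 0) is False

    def test_exhaustive_against_closed_form(self):
        for total in range(13):
            for grade in range(5):
                assert check_inclusion(total, grade) == (total >= 5 and grade >= 1)

    @pytest.mark.parametrize("total, grade", [(-1, 1), (13, 1), (5, -1), (5, 5)])
    def test_out_of_range_rejected(self, total, grade):
        with pytest.raises(ValueError):
            check_inclusion(total, grade)
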