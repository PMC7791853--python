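"""Executable Meier and Obel laminitis severity rubrics.

The Obel method is the classical 0-4 ordinal lameness grading for laminitis.
The Meier method ("modified Obel") is a three-stage composite examination
scoring five clinical signs — weight shifting, forelimb lift, gait at the
walk, gait at the circle and the forelimb digital pulse — summed to a total
on a 0-12 scale.  A safety rule applies: a horse with severe difficulty
walking is not forced to circle, so the circle assessment is skipped (0
points) and the walk criterion alone carries the locomotor severity (6
points).

Per-forelimb criteria (foot lift, digital pulse) contribute the worse of the
two limbs, keeping each criterion within its printed maximum (2 points each)
and the total within 0-12; summing limbs would breach the scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "MeierExam",
    "MeierScore",
    "ObelExam",
    "ObelGrade",
    "score_meier",
    "grade_obel",
    "check_inclusion",
    "enumerate_attainable_totals",
    "iter_valid_meier_exams",
    "iter_valid_obel_exams",
]

FOOT_LIFT_LEVELS = ("prompt", "reluctant", "unable")
GAIT_WALK_LEVELS = ("normal", "mild", "moderate", "severe")
GAIT_CIRCLE_LEVELS = ("normal", "mild", "moderate", "severe", "not_assessed")
PULSE_LEVELS = ("normal", "bounding")
FORELIMB_LIFT_LEVELS = ("willingly", "with_great_difficulty", "not_liftable")

_FOOT_LIFT_PTS = {"prompt": 0, "reluctant": 1, "unable": 2}
_WALK_PTS = {"normal": 0, "mild": 1, "moderate": 2, "severe": 6}
_CIRCLE_PTS = {"normal": 0, "mild": 1, "moderate": 2, "severe": 3, "not_assessed": 0}
_PULSE_PTS = {"normal": 0, "bounding": 2}


@dataclass(frozen=True)
class MeierExam:
    """Per-criterion observations for one horse at one visit.

    Stage 1 examines the standing horse (weight shifting, forelimb lift);
    stage 2 the gait at the walk and in a circle; stage 3 the digital pulse.
    ``gait_circle`` must be ``"not_assessed"`` when ``gait_walk`` is
    ``"severe"`` (the horse is not forced to turn).
    """

    weight_shifting: bool
    foot_lift_left: str
    foot_lift_right: str
    gait_walk: str
    gait_circle: str
    pulse_left: str
    pulse_right: str

    def __post_init__(self) -> None:
        _check_level("foot_lift_left", self.foot_lift_left, FOOT_LIFT_LEVELS)
        _check_level("foot_lift_right", self.foot_lift_right, FOOT_LIFT_LEVELS)
        _check_level("gait_walk", self.gait_walk, GAIT_WALK_LEVELS)
        _check_level("gait_circle", self.gait_circle, GAIT_CIRCLE_LEVELS)
        _check_level("pulse_left", self.pulse_left, PULSE_LEVELS)
        _check_level("pulse_right", self.pulse_right, PULSE_LEVELS)
        if not isinstance(self.weight_shifting, bool):
            raise ValueError("weight_shifting must be a boolean (present/absent)")
        if self.gait_walk == "severe" and self.gait_circle != "not_assessed":
            raise ValueError(
                "severe gait at the walk requires gait_circle == 'not_assessed' "
                "(the circle assessment is skipped; do not force the horse to turn)"
            )


@dataclass(frozen=True)
class MeierScore:
    """Criterion points and total for one Meier examination."""

    weight_shifting_pts: int
    foot_lift_pts: int
    walk_pts: int
    circle_pts: int
    pulse_pts: int
    total: int
    circle_skipped: bool

    def __post_init__(self) -> None:
        parts = (
            self.weight_shifting_pts,
            self.foot_lift_pts,
            self.walk_pts,
            self.circle_pts,
            self.pulse_pts,
        )
        if sum(parts) != self.total:
            raise ValueError("total must equal the sum of the five criterion points")
        if not 0 <= self.total <= 12:
            raise ValueError(f"total {self.total} outside the 0-12 scale")
        if self.circle_skipped != (self.walk_pts == 6):
            raise ValueError("circle_skipped must hold exactly when walk_pts == 6")
        if self.circle_skipped and self.circle_pts != 0:
            raise ValueError("a skipped circle assessment scores 0 points")


@dataclass(frozen=True)
class ObelExam:
    """Clinical observations feeding the Obel 0-4 grading."""

    weight_shift_at_rest: bool = False
    sound_at_walk: bool = False
    stilted_at_trot_and_turn: bool = False
    stilted_at_walk: bool = False
    turns_with_great_difficulty: bool = False
    forelimb_liftable: str = "willingly"
    reluctant_to_walk: bool = False
    moves_only_if_forced: bool = False

    def __post_init__(self) -> None:
        _check_level("forelimb_liftable", self.forelimb_liftable, FORELIMB_LIFT_LEVELS)
        if self.moves_only_if_forced and not self.reluctant_to_walk:
            raise ValueError("a horse that moves only if forced is a fortiori reluctant to walk")
        if self.sound_at_walk and self.stilted_at_walk:
            raise ValueError("sound_at_walk and stilted_at_walk are mutually exclusive")


@dataclass(frozen=True)
class ObelGrade:
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"Obel grade must be 0-4, got {self.grade}")


def _check_level(name: str, value: str, levels: tuple[str, ...]) -> None:
    if value not in levels:
        raise ValueError(f"{name} must be one of {levels}, got {value!r}")


def score_meier(exam: MeierExam) -> MeierScore:
    """Score one Meier examination.

    Weight shifting present scores 2; forelimb lift and digital pulse take
    the worse forelimb (0/1/2 and 0/2); gait at the walk scores 0/1/2/6 and,
    when severe (6), the circle is skipped for 0; the circle otherwise
    scores 0/1/2/3.  The total is the sum, 0-12.
    """
    ws = 2 if exam.weight_shifting else 0
    lift = max(_FOOT_LIFT_PTS[exam.foot_lift_left], _FOOT_LIFT_PTS[exam.foot_lift_right])
    walk = _WALK_PTS[exam.gait_walk]
    skipped = exam.gait_walk == "severe"
    circle = 0 if skipped else _CIRCLE_PTS[exam.gait_circle]
    pulse = max(_PULSE_PTS[exam.pulse_left], _PULSE_PTS[exam.pulse_right])
    total = ws + lift + walk + circle + pulse
    return MeierScore(
        weight_shifting_pts=ws,
        foot_lift_pts=lift,
        walk_pts=walk,
        circle_pts=circle,
        pulse_pts=pulse,
        total=total,
        circle_skipped=skipped,
    )


def grade_obel(exam: ObelExam) -> ObelGrade:
    """Grade one Obel examination; the highest matching grade wins.

    Grade 4: moves only if forced.  Grade 3: reluctant to walk and a
    forelimb liftable only with great difficulty.  Grade 2: stilted at the
    walk, turns with great difficulty, but a forelimb lifts willingly.
    Grade 1: shifts weight at rest, sound at the walk, stilted at the trot
    and on turning.  Anything else grades 0 (appears sound).
    """
    if exam.moves_only_if_forced:
        return ObelGrade(4)
    if exam.reluctant_to_walk and exam.forelimb_liftable == "with_great_difficulty":
        return ObelGrade(3)
    if (
        exam.stilted_at_walk
        and exam.turns_with_great_difficulty
        and exam.forelimb_liftable == "willingly"
    ):
        return ObelGrade(2)
    if exam.weight_shift_at_rest and exam.sound_at_walk and exam.stilted_at_trot_and_turn:
        return ObelGrade(1)
    return ObelGrade(0)


def check_inclusion(meier_total: int, obel_grade: int) -> bool:
    """Study inclusion predicate: Meier total >= 5/12 and Obel grade >= 1/4."""
    if not 0 <= meier_total <= 12:
        raise ValueError(f"Meier total must be 0-12, got {meier_total}")
    if not 0 <= obel_grade <= 4:
        raise ValueError(f"Obel grade must be 0-4, got {obel_grade}")
    return meier_total >= 5 and obel_grade >= 1


def iter_valid_meier_exams():
    """Yield every Meier exam satisfying the skip rule (exhaustive)."""
    for ws, fl_l, fl_r, walk, pulse_l, pulse_r in itertools.product(
        (False, True),
        FOOT_LIFT_LEVELS,
        FOOT_LIFT_LEVELS,
        GAIT_WALK_LEVELS,
        PULSE_LEVELS,
        PULSE_LEVELS,
    ):
        circles = ("not_assessed",) if walk == "severe" else GAIT_CIRCLE_LEVELS
        for circle in circles:
            yield MeierExam(
                weight_shifting=ws,
                foot_lift_left=fl_l,
                foot_lift_right=fl_r,
                gait_walk=walk,
                gait_circle=circle,
                pulse_left=pulse_l,
                pulse_right=pulse_r,
            )


def iter_valid_obel_exams():
    """Yield every Obel exam satisfying its invariants (exhaustive)."""
    flags = (False, True)
    for rest, sound, trot, stilt, turns, lift, reluct, forced in itertools.product(
        flags, flags, flags, flags, flags, FORELIMB_LIFT_LEVELS, flags, flags
    ):
        if forced and not reluct:
            continue
        if sound and stilt:
            continue
        yield ObelExam(
            weight_shift_at_rest=rest,
            sound_at_walk=sound,
            stilted_at_trot_and_turn=trot,
            stilted_at_walk=stilt,
            turns_with_great_difficulty=turns,
            forelimb_liftable=lift,
            reluctant_to_walk=reluct,
            moves_only_if_forced=forced,
        )


@lru_cache(maxsize=1)
def enumerate_attainable_totals() -> frozenset[int]:
    """All totals reachable by a valid Meier exam, by brute-force enumeration."""
    return frozenset(score_meier(e).total for e in iter_valid_meier_exams())


@lru_cache(maxsize=1)
def attainable_decompositions() -> dict[int, list[tuple[int, int, int, int, int]]]:
    """Map each attainable total to its valid criterion-point decompositions.

    Tuples are ordered (weight shifting, foot lift, walk, circle, pulse).
    """
    out: dict[int, set] = {}
    for exam in iter_valid_meier_exams():
        s = score_meier(exam)
        parts = (s.weight_shifting_pts, s.foot_lift_pts, s.walk_pts, s.circle_pts, s.pulse_pts)
        out.setdefault(s.total, set()).add(parts)
    return {k: sorted(v) for k, v in out.items()}
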