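"""CSV/JSON readers and writers.

All tabular output is UTF-8 CSV with a header row and dot decimals; fit
reports and provenance are JSON.  Cohort CSVs are long format: one row per
(horse, visit) with ``horse_id, day, score`` plus optional ``group``,
``raw_score``, ``obel_grade`` and the five per-sign point columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import SIGN_COLUMNS, CohortData
from .scoring import MeierExam, ObelExam, grade_obel, score_meier

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_exams",
    "score_exam_table",
    "write_json",
]

_MEIER_EXAM_COLUMNS = (
    "weight_shifting",
    "foot_lift_left",
    "foot_lift_right",
    "gait_walk",
    "gait_circle",
    "pulse_left",
    "pulse_right",
)
_OBEL_EXAM_COLUMNS = (
    "weight_shift_at_rest",
    "sound_at_walk",
    "stilted_at_trot_and_turn",
    "stilted_at_walk",
    "turns_with_great_difficulty",
    "forelimb_liftable",
    "reluctant_to_walk",
    "moves_only_if_forced",
)

_TRUE_STRINGS = {"true", "present", "yes", "1"}
_FALSE_STRINGS = {"false", "absent", "no", "0"}


def read_cohort_csv(path) -> CohortData:
    """Read a long-format cohort CSV, validating columns, duplicates and range."""
    df = pd.read_csv(path)
    required = {"horse_id", "day", "score"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if not pd.api.types.is_numeric_dtype(df["score"]):
        raise ValueError(f"{path}: non-numeric values in the score column")
    if not pd.api.types.is_numeric_dtype(df["day"]):
        raise ValueError(f"{path}: non-numeric values in the day column")
    bad = df[(df["score"] < 0) | (df["score"] > 12)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: score {row['score']} for horse {row['horse_id']!r} on day "
            f"{row['day']} is outside the 0-12 Meier scale"
        )
    df["horse_id"] = df["horse_id"].astype(str)
    df["day"] = df["day"].astype(int)
    return CohortData.from_frame(df)


def write_cohort_csv(cohort: CohortData, path) -> None:
    """Write a cohort to long-format CSV (round-trips with read_cohort_csv)."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False)


def _parse_flag(value, column: str):
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"column {column!r}: cannot interpret {value!r} as present/absent")


def read_exams(path) -> pd.DataFrame:
    """Read per-visit examination records from CSV or JSON.

    Expects ``horse_id``, ``day``, the seven Meier exam columns with
    lower-case level names, and optionally the eight Obel exam columns.
    Returns the validated table with parsed boolean flags.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = sorted(({"horse_id", "day"} | set(_MEIER_EXAM_COLUMNS)) - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing exam columns {missing}")
    df["weight_shifting"] = [_parse_flag(v, "weight_shifting") for v in df["weight_shifting"]]
    if set(_OBEL_EXAM_COLUMNS) <= set(df.columns):
        for col in _OBEL_EXAM_COLUMNS:
            if col != "forelimb_liftable":
                df[col] = [_parse_flag(v, col) for v in df[col]]
    return df


def score_exam_table(exams: pd.DataFrame) -> pd.DataFrame:
    """Score every examination row with the Meier (and, if present, Obel) rubric.

    Returns one row per visit: horse_id, day, the five criterion points,
    total, circle_skipped, and obel_grade when the Obel columns are present.
    """
    has_obel = set(_OBEL_EXAM_COLUMNS) <= set(exams.columns)
    rows = []
    for _, rec in exams.iterrows():
        exam = MeierExam(**{c: rec[c] for c in _MEIER_EXAM_COLUMNS})
        s = score_meier(exam)
        row = {
            "horse_id": rec["horse_id"],
            "day": rec["day"],
            "weight_shifting_pts": s.weight_shifting_pts,
            "foot_lift_pts": s.foot_lift_pts,
            "walk_pts": s.walk_pts,
            "circle_pts": s.circle_pts,
            "pulse_pts": s.pulse_pts,
            "total": s.total,
            "circle_skipped": s.circle_skipped,
        }
        if has_obel:
            obel = ObelExam(**{c: rec[c] for c in _OBEL_EXAM_COLUMNS})
            row["obel_grade"] = grade_obel(obel).grade
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(obj: Mapping, path) -> None:
    """Write a JSON report deterministically (sorted keys, native floats)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
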