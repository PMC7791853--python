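"""Core data containers and the structural decay model.

The package models clinical improvement from hyperinsulinaemia-associated
laminitis (HAL) as an exponential-type decay of the composite Meier severity
score (0-12 scale).  For horse ``i`` observed on study day ``t``:

    y_it = theta0_i * exp(-theta1_i * t**theta2_i) + eps_it,
    eps_it ~ N(0, sigma^2)

with horse-level parameters ``(log theta0_i, log theta1_i, theta2_i)`` drawn
from a multivariate normal with diagonal covariance
``Omega = diag(omega0, omega1, omega2)``.  ``theta0_i`` is the day-0 score,
``theta1_i`` the decay rate and ``theta2_i`` a dimensionless power on time
(``theta2 = 1`` gives plain exponential decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DAYS",
    "REFERENCE_PARAMS",
    "SIGN_COLUMNS",
    "PopulationParams",
    "IndividualEffects",
    "Trajectory",
    "CohortData",
    "decay_curve",
    "structural_mean",
]

#: Study visit schedule: diagnosis day (0) plus five follow-up visits.
DEFAULT_DAYS: tuple[int, ...] = (0, 4, 9, 14, 25, 42)

#: Long-format column names for the five Meier criterion scores, in the
#: order of the examination stages.
SIGN_COLUMNS: tuple[str, ...] = (
    "weight_shifting_pts",
    "foot_lift_pts",
    "walk_pts",
    "circle_pts",
    "pulse_pts",
)

_PARAM_NAMES = ("log_theta0", "log_theta1", "theta2")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the decay model.

    Parameters
    ----------
    log_theta0
        Log of the population day-0 score (score units on the natural scale).
    log_theta1
        Log of the population decay rate (1/day on the natural scale).
    theta2
        Power on time; dimensionless.  ``1`` means exponential decay.
    omega0, omega1, omega2
        Between-horse *variances* of ``log theta0``, ``log theta1`` and
        ``theta2`` respectively.  Must be non-negative.
    sigma
        Residual standard deviation in score units.  Must be positive.
    """

    log_theta0: float
    log_theta1: float
    theta2: float
    omega0: float = 0.0
    omega1: float = 0.0
    omega2: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("omega0", "omega1", "omega2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def fixed_effects(self) -> np.ndarray:
        """Fixed-effect vector ``(log theta0, log theta1, theta2)``."""
        return np.array([self.log_theta0, self.log_theta1, self.theta2], dtype=float)

    @property
    def omegas(self) -> np.ndarray:
        """Diagonal of the random-effect covariance, ``(omega0, omega1, omega2)``."""
        return np.array([self.omega0, self.omega1, self.omega2], dtype=float)

    def with_(self, **kwargs) -> "PopulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {
            "log_theta0": self.log_theta0,
            "log_theta1": self.log_theta1,
            "theta2": self.theta2,
            "omega0": self.omega0,
            "omega1": self.omega1,
            "omega2": self.omega2,
            "sigma": self.sigma,
        }


#: Published population estimates for the fast-improvement phenotype in a
#: 64-horse clinical cohort of naturally occurring HAL; used as the default
#: generating parameters for synthetic cohorts.  Day-0 score
#: exp(2.07) = 7.92, decay rate exp(-1.95) = 0.142/day, power 1.16.
REFERENCE_PARAMS = PopulationParams(
    log_theta0=2.07,
    log_theta1=-1.95,
    theta2=1.16,
    omega0=0.025,
    omega1=0.361,
    omega2=0.087,
    sigma=0.99,
)


@dataclass(frozen=True)
class IndividualEffects:
    """Realized decay parameters for one horse."""

    horse_id: str
    log_theta0_i: float
    log_theta1_i: float
    theta2_i: float

    def __post_init__(self) -> None:
        vals = (self.log_theta0_i, self.log_theta1_i, self.theta2_i)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite individual effects for {self.horse_id}: {vals}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.log_theta0_i, self.log_theta1_i, self.theta2_i], dtype=float)


def decay_curve(phi: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Structural mean score for parameter array ``phi`` at times ``t``.

    ``phi`` has shape ``(..., 3)`` holding ``(log theta0, log theta1,
    theta2)``; ``t`` broadcasts against ``phi[..., 0]``.  ``0**theta2`` is
    defined as 0 for any ``theta2`` so the day-0 mean is exactly ``theta0``.
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float)
    lth0 = phi[..., 0]
    lth1 = phi[..., 1]
    th2 = phi[..., 2]
    safe_t = np.where(t > 0, t, 1.0)
    t_pow = np.where(t > 0, safe_t**th2, 0.0)
    return np.exp(lth0 - np.exp(lth1) * t_pow)


def structural_mean(effects: IndividualEffects | PopulationParams, t) -> np.ndarray | float:
    """Noise-free model score for one horse (or the population curve) at ``t``.

    Accepts an :class:`IndividualEffects` or, for the population-average
    curve, a :class:`PopulationParams` (whose fixed effects are used).
    """
    if isinstance(effects, PopulationParams):
        phi = effects.fixed_effects
    else:
        phi = effects.as_array
    t_arr = np.asarray(t, dtype=float)
    out = decay_curve(phi, t_arr)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


@dataclass
class Trajectory:
    """Score time series for one horse.

    ``scores`` are totals on the 0-12 Meier scale (integers when the
    generator rounds); ``raw_scores`` optionally retains the continuous,
    unclipped model draw that produced each score.  ``signs`` optionally
    holds per-visit criterion points (columns :data:`SIGN_COLUMNS`).
    """

    horse_id: str
    days: np.ndarray
    scores: np.ndarray
    group: str = "unknown"
    raw_scores: np.ndarray | None = None
    signs: pd.DataFrame | None = None
    obel_grades: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        self.scores = np.asarray(self.scores)
        if self.days.ndim != 1 or len(self.days) != len(self.scores):
            raise ValueError(f"days/scores length mismatch for horse {self.horse_id}")
        if np.any(self.days < 0):
            raise ValueError(f"negative visit day for horse {self.horse_id}")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"visit days must be strictly increasing for horse {self.horse_id}")
        if self.group not in ("fast", "slow", "unknown"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.raw_scores is not None:
            self.raw_scores = np.asarray(self.raw_scores, dtype=float)
            if len(self.raw_scores) != len(self.days):
                raise ValueError(f"raw_scores length mismatch for horse {self.horse_id}")

    def __len__(self) -> int:
        return len(self.days)

    def score_on(self, day: int) -> float | None:
        """Score at the given visit day, or None if that visit is absent."""
        idx = np.nonzero(self.days == day)[0]
        if len(idx) == 0:
            return None
        return float(self.scores[idx[0]])


class CohortData:
    """A cohort of score trajectories with a long-format tabular view."""

    def __init__(self, trajectories: Iterable[Trajectory]):
        self.trajectories: list[Trajectory] = list(trajectories)
        ids = [t.horse_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({h for h in ids if ids.count(h) > 1})
            raise ValueError(f"duplicate horse ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def horse_ids(self) -> list[str]:
        return [t.horse_id for t in self.trajectories]

    def get(self, horse_id: str) -> Trajectory:
        for t in self.trajectories:
            if t.horse_id == horse_id:
                return t
        raise KeyError(horse_id)

    def subset(self, horse_ids: Sequence[str]) -> "CohortData":
        wanted = set(horse_ids)
        return CohortData([t for t in self.trajectories if t.horse_id in wanted])

    @property
    def has_signs(self) -> bool:
        return all(t.signs is not None for t in self.trajectories) and len(self) > 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (horse, visit)."""
        rows = []
        for t in self.trajectories:
            df = pd.DataFrame({"horse_id": t.horse_id, "day": t.days, "score": t.scores})
            df["group"] = t.group
            if t.raw_scores is not None:
                df["raw_score"] = t.raw_scores
            if t.obel_grades is not None:
                df["obel_grade"] = t.obel_grades
            if t.signs is not None:
                for col in SIGN_COLUMNS:
                    df[col] = t.signs[col].to_numpy()
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["horse_id", "day", "score", "group"])
        out = pd.concat(rows, ignore_index=True)
        if out.duplicated(["horse_id", "day"]).any():
            raise ValueError("duplicate (horse_id, day) pairs in cohort")
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortData":
        """Build a cohort from a long-format table (horse_id, day, score, ...)."""
        required = {"horse_id", "day", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        dupes = df.duplicated(["horse_id", "day"])
        if dupes.any():
            row = df.loc[dupes.idxmax()]
            raise ValueError(
                f"duplicate visit row for horse {row['horse_id']!r} on day {row['day']}"
            )
        trajectories = []
        for horse_id, sub in df.groupby("horse_id", sort=False):
            sub = sub.sort_values("day")
            group = "unknown"
            if "group" in sub.columns:
                labels = sub["group"].unique()
                if len(labels) == 1 and labels[0] in ("fast", "slow", "unknown"):
                    group = labels[0]
            signs = None
            if all(c in sub.columns for c in SIGN_COLUMNS):
                signs = sub[list(SIGN_COLUMNS)].reset_index(drop=True)
            raw = sub["raw_score"].to_numpy() if "raw_score" in sub.columns else None
            obel = sub["obel_grade"].to_numpy() if "obel_grade" in sub.columns else None
            trajectories.append(
                Trajectory(
                    horse_id=str(horse_id),
                    days=sub["day"].to_numpy(),
                    scores=sub["score"].to_numpy(),
                    group=group,
                    raw_scores=raw,
                    signs=signs,
                    obel_grades=obel,
                )
            )
        return cls(trajectories)
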