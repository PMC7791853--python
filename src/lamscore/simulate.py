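"""Synthetic laminitis-improvement cohorts.

Generates score trajectories with the statistical structure the decay model
assumes: horse-level parameters drawn around the population values with
diagonal between-horse variances, an additive Gaussian residual, and scores
clipped to the 0-12 Meier scale and rounded to integers (clinical scores are
integers).  A configurable minority of "slow improvement" horses have a
slowed decay plus relapse bumps, producing waxing/waning trajectories with
mid-study (day 14) scores of 4-10.

The continuous, unclipped model draw behind every integer score is retained
(``Trajectory.raw_scores``) so model fitting can consume scores as
continuous values, which is how the clinical analysis treats them.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_DAYS,
    REFERENCE_PARAMS,
    SIGN_COLUMNS,
    CohortData,
    IndividualEffects,
    PopulationParams,
    Trajectory,
    decay_curve,
)
from .scoring import enumerate_attainable_totals

__all__ = [
    "sample_individual_params",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_slow_improver",
    "allocate_signs",
]

logger = logging.getLogger(__name__)

# Slow-improver mechanism: decay rate shrunk into this multiplier range, one
# Gaussian relapse bump with these amplitude / centre-day / width ranges.
_SLOW_RATE_RANGE = (0.05, 0.20)
_BUMP_AMPLITUDE_RANGE = (1.0, 3.0)
_BUMP_CENTRE_RANGE = (18.0, 34.0)
_BUMP_WIDTH_RANGE = (4.0, 8.0)
_MAX_RESAMPLES = 500


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_individual_params(
    pop: PopulationParams,
    n: int,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "horse",
) -> list[IndividualEffects]:
    """Draw ``n`` horses' ``(log theta0_i, log theta1_i, theta2_i)``.

    Each component is Normal around the population value with the matching
    omega variance.  ``theta2_i`` lives on the natural scale; non-positive
    draws (possible in principle for large ``omega2``) are resampled and the
    occurrence logged, keeping every simulated curve a genuine decay.
    """
    if n < 1:
        raise ValueError(f"need at least one horse, got n={n}")
    rng = _as_rng(seed)
    means = pop.fixed_effects
    sds = np.sqrt(pop.omegas)
    draws = means + rng.standard_normal((n, 3)) * sds
    n_resampled = 0
    bad = draws[:, 2] <= 0
    while bad.any():
        n_resampled += int(bad.sum())
        if n_resampled > _MAX_RESAMPLES:
            raise RuntimeError("too many non-positive theta2 draws; check omega2")
        draws[bad, 2] = means[2] + rng.standard_normal(int(bad.sum())) * sds[2]
        bad = draws[:, 2] <= 0
    if n_resampled:
        logger.info("resampled %d non-positive theta2 draws", n_resampled)
    width = max(3, len(str(n)))
    return [
        IndividualEffects(f"{id_prefix}{i + 1:0{width}d}", *draws[i]) for i in range(n)
    ]


def _finalize_scores(
    raw: np.ndarray, clip: bool, round_to_integer: bool
) -> np.ndarray:
    scores = raw.copy()
    if clip:
        scores = np.clip(scores, 0.0, 12.0)
    if round_to_integer:
        scores = np.rint(scores).astype(int)
    return scores


def simulate_trajectory(
    effects: IndividualEffects,
    days: Sequence[int] = DEFAULT_DAYS,
    sigma: float = REFERENCE_PARAMS.sigma,
    seed: int | np.random.Generator = 0,
    clip: bool = True,
    round_to_integer: bool = True,
) -> Trajectory:
    """Simulate one fast-improvement trajectory.

    The score at day ``t`` is the structural decay mean plus N(0, sigma^2)
    noise, optionally clipped to [0, 12] and rounded to the nearest integer.
    The continuous unclipped draw is kept in ``raw_scores``.
    """
    days = np.asarray(days)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _as_rng(seed)
    mean = decay_curve(effects.as_array, days.astype(float))
    raw = mean + rng.standard_normal(len(days)) * sigma
    return Trajectory(
        horse_id=effects.horse_id,
        days=days,
        scores=_finalize_scores(raw, clip, round_to_integer),
        group="fast",
        raw_scores=raw,
    )


def simulate_slow_improver(
    baseline: IndividualEffects,
    days: Sequence[int] = DEFAULT_DAYS,
    seed: int | np.random.Generator = 0,
    sigma: float = REFERENCE_PARAMS.sigma,
    clip: bool = True,
    round_to_integer: bool = True,
    rate_range: tuple[float, float] = _SLOW_RATE_RANGE,
    amplitude_range: tuple[float, float] = _BUMP_AMPLITUDE_RANGE,
    enforce_constraints: bool = True,
) -> Trajectory:
    """Simulate one slow-improvement (waxing/waning) trajectory.

    The horse's decay rate is shrunk by a factor in ``rate_range`` and a
    single Gaussian relapse bump with amplitude in ``amplitude_range`` is
    added, so scores remain elevated mid-study and rise again later.  Draws
    are redrawn until the day-14 score falls in [4, 10] (when day 14 is
    observed) and the sequence is non-monotone; with the relapse amplitude
    at 0 and the rate factor at 1 the mechanism degenerates to an ordinary
    decay trajectory (disable ``enforce_constraints`` in that case).
    """
    days = np.asarray(days)
    rng = _as_rng(seed)
    day14_idx = np.nonzero(days == 14)[0]
    for _ in range(_MAX_RESAMPLES):
        rate_factor = rng.uniform(*rate_range)
        amp = rng.uniform(*amplitude_range)
        centre = rng.uniform(*_BUMP_CENTRE_RANGE)
        width = rng.uniform(*_BUMP_WIDTH_RANGE)
        phi = baseline.as_array.copy()
        phi[1] += np.log(rate_factor)
        mean = decay_curve(phi, days.astype(float))
        bump = amp * np.exp(-0.5 * ((days - centre) / width) ** 2)
        raw = mean + bump + rng.standard_normal(len(days)) * sigma
        scores = _finalize_scores(raw, clip, round_to_integer)
        if enforce_constraints:
            if len(day14_idx) and not 4 <= scores[day14_idx[0]] <= 10:
                continue
            if not np.any(np.diff(scores.astype(float)) > 0):
                continue
        return Trajectory(
            horse_id=baseline.horse_id,
            days=days,
            scores=scores,
            group="slow",
            raw_scores=raw,
        )
    raise RuntimeError(
        f"could not draw an admissible slow-improvement trajectory for {baseline.horse_id}"
    )


def simulate_cohort(
    pop: PopulationParams = REFERENCE_PARAMS,
    n: int = 64,
    days: Sequence[int] = DEFAULT_DAYS,
    seed: int = 0,
    clip: bool = True,
    round_to_integer: bool = True,
    slow_fraction: float = 0.0,
    with_signs: bool = False,
    id_prefix: str = "horse",
) -> CohortData:
    """Simulate a cohort of ``n`` independent trajectories.

    By default all horses follow the fast-improvement decay pattern; with
    ``slow_fraction > 0`` the last ``round(n * slow_fraction)`` horses are
    generated as slow improvers.  ``with_signs`` additionally decomposes each
    integer total into the five Meier criterion points (requires
    ``round_to_integer`` and ``clip``).
    """
    if n < 1:
        raise ValueError(f"need at least one horse, got n={n}")
    if not 0.0 <= slow_fraction <= 1.0:
        raise ValueError("slow_fraction must be in [0, 1]")
    if with_signs and not (clip and round_to_integer):
        raise ValueError("per-sign allocation requires clipped integer scores")
    rng = np.random.default_rng(seed)
    effects = sample_individual_params(pop, n, rng, id_prefix=id_prefix)
    n_slow = int(round(n * slow_fraction))
    trajectories = []
    for i, eff in enumerate(effects):
        if i >= n - n_slow:
            traj = simulate_slow_improver(
                eff, days, rng, sigma=pop.sigma, clip=clip, round_to_integer=round_to_integer
            )
        else:
            traj = simulate_trajectory(
                eff, days, sigma=pop.sigma, seed=rng, clip=clip,
                round_to_integer=round_to_integer,
            )
        if with_signs:
            traj.signs = allocate_signs(traj, seed=rng)
        trajectories.append(traj)
    return CohortData(trajectories)


# Canonical decomposition of each total into (weight shifting, foot lift,
# walk, circle, pulse) points, encoding the clinical resolution order: as a
# horse improves and its total falls, weight shifting and foot lift zero out
# first, then the digital pulse, then gait at the walk, and gait at the
# circle last.  Each row is a valid rubric outcome (total 12 requires the
# severe-walk skip, so circle is 0 there).
_SIGN_DECOMPOSITION: dict[int, tuple[int, int, int, int, int]] = {
    12: (2, 2, 6, 0, 2),
    11: (2, 2, 2, 3, 2),
    10: (2, 1, 2, 3, 2),
    9: (0, 2, 2, 3, 2),
    8: (0, 1, 2, 3, 2),
    7: (0, 0, 2, 3, 2),
    6: (0, 0, 1, 3, 2),
    5: (0, 0, 1, 2, 2),
    4: (0, 0, 1, 1, 2),
    3: (0, 0, 1, 2, 0),
    2: (0, 0, 1, 1, 0),
    1: (0, 0, 0, 1, 0),
    0: (0, 0, 0, 0, 0),
}


def allocate_signs(trajectory: Trajectory, seed=None) -> pd.DataFrame:
    """Decompose each visit's integer total into the five criterion points.

    Uses a fixed decomposition per total, chosen from the decompositions
    attainable under the rubric (severe-walk skip rule included) so that
    late-resolving signs retain points longest as totals decline: gait at
    the circle persists to total 1, gait at the walk to total 2, the
    digital pulse to total 4, foot lift to total 8 and weight shifting to
    total 10.  The sum of the five parts equals the total at every visit.
    The mapping is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    totals = np.asarray(trajectory.scores)
    if not np.issubdtype(totals.dtype, np.integer):
        if not np.allclose(totals, np.rint(totals)):
            raise ValueError("per-sign allocation needs integer totals")
        totals = np.rint(totals).astype(int)
    attainable = enumerate_attainable_totals()
    rows = []
    for total in totals:
        t = int(total)
        if t not in attainable:
            raise ValueError(f"total {t} is not attainable under the Meier rubric")
        rows.append(_SIGN_DECOMPOSITION[t])
    return pd.DataFrame(rows, columns=list(SIGN_COLUMNS))
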