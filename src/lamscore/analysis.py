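"""Cohort-level descriptive summaries.

Fast/slow partition on the mid-study (day 14) score, median trajectories
with IQRs, per-sign medians and positivity percentages, and a Mann-Whitney U
comparison between groups (exact by enumeration for small samples, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .core import SIGN_COLUMNS, CohortData

__all__ = [
    "PartitionResult",
    "SignSummary",
    "partition_fast_slow",
    "median_trajectory",
    "sign_summary",
    "mann_whitney_u",
]


@dataclass
class PartitionResult:
    """Fast/slow split of a cohort on the partition-day score."""

    fast_ids: list[str]
    slow_ids: list[str]
    unassigned_ids: list[str]
    partition_day: int
    threshold: int
    fast_median: float
    fast_range: tuple[float, float] | None
    slow_median: float
    slow_range: tuple[float, float] | None

    @property
    def labels(self) -> pd.DataFrame:
        rows = (
            [(h, "fast") for h in self.fast_ids]
            + [(h, "slow") for h in self.slow_ids]
            + [(h, "unassigned") for h in self.unassigned_ids]
        )
        return pd.DataFrame(rows, columns=["horse_id", "group"])


@dataclass
class SignSummary:
    """Per-sign medians, positivity percentages and resolution days."""

    medians: pd.DataFrame  # index: sign, columns: day
    percent_positive: pd.DataFrame  # index: sign, columns: day
    resolution_day: pd.Series  # first day the sign's median reaches 0


def partition_fast_slow(
    cohort: CohortData, day: int = 14, threshold: int = 4
) -> PartitionResult:
    """Split horses into fast and slow improvers on the partition-day score.

    A horse whose score on ``day`` is at or above ``threshold`` is labelled
    slow, otherwise fast.  The defaults encode the clearest clinical
    separation: on day 14 fast improvers score 0-3 and slow improvers 4-10.
    Horses without a partition-day observation are reported unassigned.
    """
    fast, slow, unassigned = [], [], []
    fast_scores, slow_scores = [], []
    for traj in cohort:
        score = traj.score_on(day)
        if score is None:
            unassigned.append(traj.horse_id)
        elif score >= threshold:
            slow.append(traj.horse_id)
            slow_scores.append(score)
        else:
            fast.append(traj.horse_id)
            fast_scores.append(score)
    return PartitionResult(
        fast_ids=fast,
        slow_ids=slow,
        unassigned_ids=unassigned,
        partition_day=day,
        threshold=threshold,
        fast_median=float(np.median(fast_scores)) if fast_scores else np.nan,
        fast_range=(min(fast_scores), max(fast_scores)) if fast_scores else None,
        slow_median=float(np.median(slow_scores)) if slow_scores else np.nan,
        slow_range=(min(slow_scores), max(slow_scores)) if slow_scores else None,
    )


def median_trajectory(cohort: CohortData, score_col: str = "score") -> pd.DataFrame:
    """Per-day median and IQR of scores across the cohort.

    Even-count medians take the midpoint of the two central order
    statistics; quartiles use the inclusive (linear interpolation)
    convention.  When the cohort carries Obel grades, their medians are
    appended as an ``obel_median`` column.  Days with no observations are
    simply absent from the table.
    """
    frame = cohort.to_frame()
    if len(frame) == 0:
        return pd.DataFrame(columns=["n", "median", "q1", "q3"]).rename_axis("day")
    if score_col not in frame.columns:
        raise ValueError(f"cohort has no column {score_col!r}")
    grouped = frame.groupby("day")[score_col]
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "median": grouped.median(),
            "q1": grouped.quantile(0.25),
            "q3": grouped.quantile(0.75),
        }
    )
    if "obel_grade" in frame.columns:
        out["obel_median"] = frame.groupby("day")["obel_grade"].median()
    return out


def sign_summary(cohort: CohortData) -> SignSummary:
    """Per-sign, per-day medians and percent of horses with a positive score.

    Also reports each sign's resolution day: the first visit day on which
    the sign's median across horses reaches 0 (NaN if it never does).
    """
    if not cohort.has_signs:
        raise ValueError(
            "cohort has no per-sign columns; run allocate_signs or supply "
            f"columns {list(SIGN_COLUMNS)}"
        )
    frame = cohort.to_frame()
    med = frame.groupby("day")[list(SIGN_COLUMNS)].median().T
    pct = 100.0 * frame.groupby("day")[list(SIGN_COLUMNS)].agg(lambda s: (s > 0).mean()).T
    med.index.name = "sign"
    pct.index.name = "sign"
    resolution = {}
    for sign in SIGN_COLUMNS:
        zero_days = med.columns[(med.loc[sign] == 0).to_numpy()]
        resolution[sign] = float(zero_days[0]) if len(zero_days) else np.nan
    return SignSummary(
        medians=med,
        percent_positive=pct,
        resolution_day=pd.Series(resolution, name="resolution_day"),
    )


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test between two score samples.

    Returns ``(U, p)`` where U counts pairs in which a ``group_a`` value
    exceeds a ``group_b`` value (ties count one half).  ``method`` is
    ``"exact"`` (full enumeration of rank assignments, midranks for ties),
    ``"asymptotic"`` (normal approximation with tie correction) or
    ``"auto"`` (exact when both samples have at most 8 observations).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    if method == "asymptotic":
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    return _exact_mann_whitney(a, b)


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all assignments of pooled midranks."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - offset)
    us = np.fromiter(
        (sum(combo) - offset for combo in itertools.combinations(ranks, n_a)),
        dtype=float,
    )
    eps = 1e-9
    p_low = float(np.mean(us <= u_obs + eps))
    p_high = float(np.mean(us >= u_obs - eps))
    p = min(1.0, 2.0 * min(p_low, p_high))
    return u_obs, p
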