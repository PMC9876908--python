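"""Descriptive behavioral measures: moving-average reward and block RTs.

The reward learning curve is a 20-trial moving average taken in one-trial
steps.  The window is centered with ten elements before and nine after the
current trial (the even-window centering of the original analysis
environment's moving mean); at the series edges the window truncates and
the mean is taken over the available elements only.

Reaction times are summarized per 40-trial block, with stage-2 RTs split
by whether the preceding stage-1 transition was common or rare.  The first
trial of the session is excluded from all RT summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .task_env import TrialRecord


@dataclass
class MovingAverageSeries:
    values: np.ndarray  # per-trial mean reward (yen)
    window: int
    n_in_window: np.ndarray  # elements actually averaged at each trial
    centering: str = "before10_after9"


@dataclass
class RtBlockSummary:
    block: int
    rt1_mean: float
    rt2_common_mean: float
    rt2_rare_mean: float
    n_rt1: int
    n_rt2_common: int
    n_rt2_rare: int


def moving_average_reward(
    rewards: Sequence[float], window: int = 20, centering: str = "before10_after9"
) -> MovingAverageSeries:
    """Truncated centered moving average of per-trial rewards.

    With the default even-window centering, trial i (0-based) averages
    trials [i - window//2, i + window//2 - 1], clipped to the series.
    """
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("moving_average_reward requires at least one trial")
    if centering != "before10_after9" and centering != "symmetric":
        raise ValueError(f"unknown centering {centering!r}")
    half = window // 2
    before, after = (half, window - half - 1) if centering == "before10_after9" else (
        (window - 1) // 2, (window - 1) // 2)
    n = r.size
    csum = np.concatenate([[0.0], np.cumsum(r)])
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    counts = hi - lo
    values = (csum[hi] - csum[lo]) / counts
    return MovingAverageSeries(
        values=values, window=window, n_in_window=counts, centering=centering
    )


def rt_block_summaries(
    trials: Sequence[TrialRecord], block_size: int = 40
) -> list[RtBlockSummary]:
    """Per-block RT means; stage-2 split by transition type.

    Missing RTs are ignored in the means; a cell with no observations
    (e.g. a block without rare transitions) yields NaN, never zero.  The
    session's first trial is excluded.
    """
    n_blocks = len(trials) // block_size
    if n_blocks == 0:
        raise ValueError(f"need at least {block_size} trials, got {len(trials)}")
    out = []
    for k in range(n_blocks):
        block = trials[k * block_size : (k + 1) * block_size]
        rt1 = [t.rt1_ms for t in block if t.rt1_ms is not None and t.trial_index != 1]
        rt2c = [
            t.rt2_ms
            for t in block
            if t.rt2_ms is not None and t.trial_index != 1
            and t.transition_type == "common"
        ]
        rt2r = [
            t.rt2_ms
            for t in block
            if t.rt2_ms is not None and t.trial_index != 1
            and t.transition_type == "rare"
        ]
        out.append(
            RtBlockSummary(
                block=k + 1,
                rt1_mean=float(np.mean(rt1)) if rt1 else float("nan"),
                rt2_common_mean=float(np.mean(rt2c)) if rt2c else float("nan"),
                rt2_rare_mean=float(np.mean(rt2r)) if rt2r else float("nan"),
                n_rt1=len(rt1),
                n_rt2_common=len(rt2c),
                n_rt2_rare=len(rt2r),
            )
        )
    return out


def group_series_compare(
    series: Mapping[str, Sequence[float]],
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-trial two-sample Wilcoxon rank-sum tests between two groups.

    ``series`` maps participant id to a per-trial value series (e.g. the
    moving-average reward); ``groups`` maps participant id to a group
    label.  Returns one row per trial with the rank-sum statistic, p-value
    and an ``all_tied`` flag for degenerate trials (those get NaN
    statistics rather than a fabricated zero).
    """
    a = [np.asarray(series[pid], float) for pid in series if groups.get(pid) == group_a]
    b = [np.asarray(series[pid], float) for pid in series if groups.get(pid) == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 participants per group")
    a = np.vstack(a)
    b = np.vstack(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("participants have unequal numbers of trials")
    rows = []
    for i in range(a.shape[1]):
        xa, xb = a[:, i], b[:, i]
        tied = np.ptp(np.concatenate([xa, xb])) == 0.0
        if tied:
            stat, p = float("nan"), float("nan")
        else:
            res = ranksums(xa, xb)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"trial": i + 1, "statistic": stat, "pvalue": p, "all_tied": tied})
    return pd.DataFrame(rows)


# -- tidy long-format exports ---------------------------------------------


def tidy_rt_table(
    cohort: Mapping[str, Sequence[TrialRecord]],
    groups: Mapping[str, str] | None = None,
    block_size: int = 40,
) -> pd.DataFrame:
    """Long table (participant, trial, block, group, transition, rt1, rt2)
    ready for mixed-model routines; the session's first trial is dropped."""
    rows = []
    for pid, trials in cohort.items():
        for t in trials:
            if t.trial_index == 1:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "trial": t.trial_index,
                    "block": (t.trial_index - 1) // block_size + 1,
                    "group": groups.get(pid) if groups else None,
                    "transition": t.transition_type,
                    "rt1_ms": t.rt1_ms,
                    "rt2_ms": t.rt2_ms,
                }
            )
    return pd.DataFrame(rows)


def tidy_moving_average_table(
    cohort: Mapping[str, Sequence[TrialRecord]],
    groups: Mapping[str, str] | None = None,
    window: int = 20,
) -> pd.DataFrame:
    """Long table of per-trial moving-average reward per participant."""
    rows = []
    for pid, trials in cohort.items():
        ma = moving_average_reward([t.reward_yen for t in trials], window=window)
        for i, v in enumerate(ma.values, start=1):
            rows.append(
                {
                    "participant_id": pid,
                    "trial": i,
                    "group": groups.get(pid) if groups else None,
                    "reward_ma": v,
                }
            )
    return pd.DataFrame(rows)
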