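"""Y-maze trial logs: counterbalanced start sequences and learning scores.

In the appetitive Y-maze task a mouse starts from one of the two
non-target arms and must choose the rewarded arm.  Each mouse runs 10
trials per day — five starts from the left of the target arm and five from
the right, in pseudo-random order with no more than three consecutive
starts from the same side — and learning is scored as the first day on
which at least 80% of trials are rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "generate_start_sequence",
    "enumerate_valid_sequences",
    "days_to_criterion",
    "retention_percent",
    "simulate_learning_log",
    "GROUP_LABELS",
]

GROUP_LABELS = ("no-stim", "navigation", "throughout", "goal")


@dataclass(frozen=True)
class TrialRecord:
    mouse_id: str
    group: str
    day: int
    trial_index: int
    start_arm: Literal["left", "right"]
    rewarded: bool
    stimulated: bool
    goal_zone_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 1 <= self.trial_index <= 10:
            raise ValueError("trial_index must be 1-10")
        if self.day < 1:
            raise ValueError("day must be >= 1")


def _max_run(seq: tuple[int, ...]) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_valid_sequences(
    n: int = 10, n_left: int = 5, max_run: int = 3
) -> list[tuple[int, ...]]:
    """All left/right arrangements (1=left) meeting the run-length rule."""
    out = []
    for left_pos in combinations(range(n), n_left):
        seq = tuple(1 if i in left_pos else 0 for i in range(n))
        if _max_run(seq) <= max_run:
            out.append(seq)
    return out


def generate_start_sequence(
    n: int = 10,
    n_left: int = 5,
    max_run: int = 3,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """One pseudo-random counterbalanced start sequence.

    Uniform over all arrangements with exactly ``n_left`` left starts and
    no run of the same side longer than ``max_run``.  For the task's
    canonical size (10 trials) the valid set is enumerated exactly and one
    element drawn; larger sizes fall back to rejection sampling.
    """
    if not (0 <= n_left <= n):
        raise ValueError("need 0 <= n_left <= n")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    rng = np.random.default_rng(rng)
    if n <= 16:
        valid = enumerate_valid_sequences(n, n_left, max_run)
        if not valid:
            raise ValueError(
                f"no sequence of {n} trials with {n_left} lefts satisfies "
                f"max_run={max_run}"
            )
        seq = valid[rng.integers(len(valid))]
    else:
        for _ in range(100_000):
            perm = np.zeros(n, dtype=int)
            perm[rng.choice(n, n_left, replace=False)] = 1
            if _max_run(tuple(perm)) <= max_run:
                seq = tuple(perm)
                break
        else:
            raise ValueError("rejection sampling failed; constraints infeasible")
    return ["left" if s else "right" for s in seq]


def days_to_criterion(
    log: pd.DataFrame, criterion: float = 0.8
) -> pd.DataFrame:
    """First day per mouse with rewarded fraction >= criterion (inclusive).

    ``log`` is tidy with columns mouse_id, day, rewarded (plus anything
    else); days may be ragged across mice (6-10 training days).  Mice that
    never reach criterion get ``reached=False`` and a null day rather than
    a number.
    """
    if log.empty:
        raise ValueError("empty trial log")
    daily = (
        log.groupby(["mouse_id", "day"])["rewarded"].mean().rename("frac").reset_index()
    )
    rows = []
    for mouse, sub in daily.groupby("mouse_id"):
        sub = sub.sort_values("day")
        hit = sub[sub["frac"] >= criterion]
        rows.append(
            {
                "mouse_id": mouse,
                "reached": not hit.empty,
                "days_to_criterion": int(hit["day"].iloc[0]) if not hit.empty else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def retention_percent(log_retest: pd.DataFrame) -> pd.Series:
    """Percent rewarded trials on the retest day, per mouse."""
    if log_retest.empty:
        raise ValueError("no retest trials")
    return 100.0 * log_retest.groupby("mouse_id")["rewarded"].mean()


def simulate_learning_log(
    n_mice_per_group: int = 10,
    n_days: int = 7,
    group_mid_days: dict[str, float] | None = None,
    slope_per_day: float = 1.1,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Synthetic trial logs with logistic per-mouse learning curves.

    Each mouse's probability of a rewarded trial rises logistically in
    days around a group-specific midpoint (with per-mouse jitter); goal-
    zone stimulation is emulated simply as a later midpoint.  Defaults
    put the no-stimulation group near criterion on day ~3 and the goal
    group near day ~4.5, the contrast the task scoring is meant to
    resolve.
    """
    if group_mid_days is None:
        group_mid_days = {
            "no-stim": 2.0,
            "navigation": 2.2,
            "throughout": 2.8,
            "goal": 3.55,
        }
    rng = np.random.default_rng(rng)
    rows = []
    for group, mid in group_mid_days.items():
        for m in range(n_mice_per_group):
            mouse = f"{group}-{m:02d}"
            mouse_mid = mid + rng.normal(0, 0.5)
            for day in range(1, n_days + 1):
                p = 1 / 3 + (0.95 - 1 / 3) / (
                    1 + np.exp(-slope_per_day * (day - mouse_mid))
                )
                starts = generate_start_sequence(rng=rng)
                for t, arm in enumerate(starts, start=1):
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "group": group,
                            "day": day,
                            "trial_index": t,
                            "start_arm": arm,
                            "rewarded": bool(rng.random() < p),
                            "stimulated": group != "no-stim",
                        }
                    )
    return pd.DataFrame(rows)
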