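"""Operant sucrose self-administration: FR1 and PR session analysis.

Sessions are typed, time-ordered event streams (active press, inactive
press, reward delivery, receptacle nosepoke) exported with one timestamp per
event.  Under fixed ratio 1 (FR1) every active press earns one sucrose
pellet and sessions last 30 min; under progressive ratio (PR) the j-th
reward requires ``r_j = round(5 * exp(0.2 * j)) - 5`` presses
(1, 2, 4, 6, 9, 12, 15, 20, 25, ...) and a session ends when the rat fails
to earn the next reward within 30 min of the last.

Pacing measures follow the printed conventions:

* FR1 mean reward interval = (time of last reward - time of first reward)
  / (number of rewards - 1);
* PR mean lever-press interval = total test duration / number of active
  presses;
* cumulative reward curves in 1-s bins and times to each successive 10% of
  total rewards.

Press *bouts* are clusters of active presses separated by inter-press
intervals below a threshold.  The threshold is either the fixed 10 s used
for the published analyses (default) or found automatically from the
descending-sorted interval scree plot as the knee — the point of maximum
perpendicular distance to the chord joining the extremes of the
axis-normalized curve; the returned threshold is the midpoint between the
interval at the knee and the preceding (larger) interval, which places it
in the sparse region between the within-bout and between-bout interval
modes.  A gap exactly at the threshold starts a new bout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "OperantEvent",
    "OperantSession",
    "PRSchedule",
    "PressBoutSet",
    "FR1Metrics",
    "PRMetrics",
    "generate_pr_schedule",
    "fr1_metrics",
    "find_interval_threshold",
    "detect_press_bouts",
    "pr_metrics",
    "average_repeated_tests",
    "read_operant_log",
    "write_operant_log",
]

EVENT_KINDS = ("active_press", "inactive_press", "reward", "nosepoke")
FR1_SESSION_DURATION = 1800.0
PR_STOP_WINDOW = 1800.0  # session ends 30 min after the last reward
DEFAULT_BOUT_THRESHOLD = 10.0  # s, the fixed published threshold


class OperantLogError(ValueError):
    """Raised for malformed operant logs or schedule violations."""


@dataclass(frozen=True, order=True)
class OperantEvent:
    t: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise OperantLogError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise OperantLogError(f"negative timestamp {self.t}")


@dataclass(frozen=True)
class OperantSession:
    """One operant session: typed event stream plus schedule metadata."""

    subject: str
    schedule: Literal["FR1", "PR"]
    events: tuple[OperantEvent, ...]
    session_duration: Optional[float] = None
    virus: Optional[str] = None
    treatment: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.schedule not in ("FR1", "PR"):
            raise OperantLogError(f"unknown schedule {self.schedule!r}")
        ts = [e.t for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise OperantLogError("events must be time-ordered")

    def times_of(self, kind: str) -> np.ndarray:
        return np.array([e.t for e in self.events if e.kind == kind])

    @property
    def duration(self) -> float:
        if self.session_duration is not None:
            return self.session_duration
        if self.schedule == "FR1":
            return FR1_SESSION_DURATION
        return float(self.events[-1].t) if self.events else 0.0


@dataclass(frozen=True)
class PRSchedule:
    """Progressive-ratio response requirements (strictly increasing, r1 = 1)."""

    requirements: tuple[int, ...]

    def __post_init__(self) -> None:
        r = self.requirements
        if not r:
            raise OperantLogError("empty PR schedule")
        if r[0] != 1:
            raise OperantLogError("PR schedule must start at 1")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise OperantLogError("PR requirements must be strictly increasing")

    def __len__(self) -> int:
        return len(self.requirements)

    def __getitem__(self, j: int) -> int:
        return self.requirements[j]


def generate_pr_schedule(n: int) -> PRSchedule:
    """First *n* requirements of the exponential PR progression.

    ``r_j = round(5 * exp(0.2 * j)) - 5`` reproduces the standard printed
    prefix 1, 2, 4, 6, 9, 12, 15, 20, 25, 32, ... (rounding half away from
    zero, as the progression is conventionally tabulated).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    reqs = tuple(
        int(math.floor(5.0 * math.exp(0.2 * j) + 0.5)) - 5
        for j in range(1, n + 1)
    )
    return PRSchedule(requirements=reqs)


@dataclass(frozen=True)
class FR1Metrics:
    n_rewards: int
    n_active: int
    n_inactive: int
    mean_reward_interval: Optional[float]
    cumulative_curve: np.ndarray  # rewards accumulated in 1-s bins
    reward_decile_times: Optional[np.ndarray]  # time to each 10% of rewards


def fr1_metrics(session: OperantSession) -> FR1Metrics:
    """Reward counts and pacing measures of one FR1 session."""
    if session.schedule != "FR1":
        raise OperantLogError("fr1_metrics requires an FR1 session")
    rewards = session.times_of("reward")
    n = len(rewards)
    interval = (rewards[-1] - rewards[0]) / (n - 1) if n >= 2 else None
    return FR1Metrics(
        n_rewards=n,
        n_active=len(session.times_of("active_press")),
        n_inactive=len(session.times_of("inactive_press")),
        mean_reward_interval=float(interval) if interval is not None else None,
        cumulative_curve=cumulative_curve(rewards, session.duration),
        reward_decile_times=reward_decile_times(rewards),
    )


def cumulative_curve(event_times: np.ndarray, duration: float) -> np.ndarray:
    """Cumulative event count in 1-s bins: curve[k] = events with t <= k."""
    n_bins = int(math.ceil(duration)) + 1
    edges = np.arange(n_bins, dtype=float)
    return np.searchsorted(np.sort(event_times), edges, side="right").astype(int)


def reward_decile_times(reward_times: np.ndarray) -> Optional[np.ndarray]:
    """Time to each successive 10% of total rewards (None when no rewards).

    The k-th decile time is the timestamp of the ceil(0.1 * k * n)-th reward.
    """
    n = len(reward_times)
    if n == 0:
        return None
    rt = np.sort(reward_times)
    idx = np.ceil(np.arange(1, 11) * n / 10.0).astype(int) - 1
    return rt[idx]


def find_interval_threshold(
    intervals: Sequence[float],
    mode: Literal["fixed", "auto"] = "fixed",
    fixed: float = DEFAULT_BOUT_THRESHOLD,
) -> float:
    """Inter-bout interval threshold, fixed (default 10 s) or from the scree knee.

    In ``auto`` mode the intervals are sorted descending (a scree plot), both
    axes are normalized to [0, 1], and the knee is the point of maximum
    perpendicular distance to the chord joining the first and last points.
    Because that point sits where the scree slope matches the chord slope —
    for a flat within-bout tail this is a few ranks past the corner — the
    returned threshold is the midpoint of the steepest adjacent drop within
    a small rank window around the knee, which for bimodal interval data is
    the drop between the two modes.  Degenerate input (all intervals equal)
    falls back to the fixed threshold with a warning.
    """
    if mode == "fixed":
        return fixed
    y = np.sort(np.asarray(intervals, dtype=float))[::-1]
    n = len(y)
    if n < 3:
        raise ValueError("auto threshold requires at least 3 intervals")
    if y[0] == y[-1]:
        warnings.warn(
            "all inter-press intervals equal; no knee — using fixed threshold",
            stacklevel=2,
        )
        return fixed
    k = scree_knee_index(y)
    lo, hi = max(1, k - 3), min(n - 1, k + 3)
    drops = y[lo - 1 : hi] - y[lo : hi + 1]
    i = lo + int(np.argmax(drops))
    return float(0.5 * (y[i] + y[i - 1]))


def scree_knee_index(y_desc: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the chord of a scree curve.

    Coordinates are rank index vs. interval value, each normalized to [0, 1]
    so the knee is scale-invariant in both axes.
    """
    n = len(y_desc)
    x = np.arange(n, dtype=float) / (n - 1)
    y = (y_desc - y_desc[-1]) / (y_desc[0] - y_desc[-1])
    # chord runs (0, 1) -> (1, 0); distance ∝ |x + y - 1|
    return int(np.argmax(np.abs(x + y - 1.0)))


@dataclass(frozen=True)
class PressBoutSet:
    """Partition of press timestamps into bouts under a gap threshold."""

    bouts: tuple[tuple[float, ...], ...]
    threshold: float

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def n_presses(self) -> int:
        return sum(len(b) for b in self.bouts)

    @property
    def mean_presses_per_bout(self) -> Optional[float]:
        return self.n_presses / self.n_bouts if self.bouts else None


def detect_press_bouts(
    press_times: Sequence[float], threshold: float
) -> PressBoutSet:
    """Split sorted press timestamps into bouts at gaps >= threshold."""
    times = np.asarray(press_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("press timestamps must be sorted")
    if len(times) == 0:
        return PressBoutSet(bouts=(), threshold=threshold)
    bouts: list[tuple[float, ...]] = []
    current: list[float] = [float(times[0])]
    for prev, nxt in zip(times, times[1:]):
        if nxt - prev >= threshold:
            bouts.append(tuple(current))
            current = [float(nxt)]
        else:
            current.append(float(nxt))
    bouts.append(tuple(current))
    return PressBoutSet(bouts=tuple(bouts), threshold=threshold)


@dataclass(frozen=True)
class PRMetrics:
    n_rewards: int
    n_active: int
    n_inactive: int
    breakpoint: int  # requirement of the last obtained reward (0 if none)
    mean_press_interval: Optional[float]
    test_duration: float
    cumulative_curve: np.ndarray


def pr_metrics(session: OperantSession, schedule: PRSchedule) -> PRMetrics:
    """Breakpoint and pacing measures of one PR session.

    The recorded test duration is the time of the last reward plus the 30-min
    stop window, unless the log ends earlier, in which case the recorded end
    is used.  The mean press interval divides that duration by the number of
    active presses.
    """
    if session.schedule != "PR":
        raise OperantLogError("pr_metrics requires a PR session")
    rewards = session.times_of("reward")
    n_rewards = len(rewards)
    if n_rewards > len(schedule):
        raise OperantLogError(
            f"{n_rewards} rewards exceed the {len(schedule)}-step schedule"
        )
    breakpoint_ = schedule[n_rewards - 1] if n_rewards else 0
    recorded_end = session.duration
    if n_rewards:
        stop_time = float(rewards[-1]) + PR_STOP_WINDOW
        test_duration = min(recorded_end, stop_time)
    else:
        test_duration = min(recorded_end, PR_STOP_WINDOW)
    n_active = len(session.times_of("active_press"))
    interval = test_duration / n_active if n_active else None
    return PRMetrics(
        n_rewards=n_rewards,
        n_active=n_active,
        n_inactive=len(session.times_of("inactive_press")),
        breakpoint=breakpoint_,
        mean_press_interval=interval,
        test_duration=test_duration,
        cumulative_curve=cumulative_curve(rewards, test_duration),
    )


def average_repeated_tests(
    measures: pd.DataFrame,
    value: str,
    subject: str = "subject",
    treatment: str = "treatment",
) -> pd.DataFrame:
    """Average the two repeated tests per subject x treatment.

    FR1 outcome measures are variable across sessions, so each subject is
    tested twice per treatment and the per-subject value is the mean of the
    two.  A subject x treatment cell with a single test is kept and flagged
    (``n_tests`` column); more than two tests violates the design and raises.
    """
    for col in (subject, treatment, value):
        if col not in measures.columns:
            raise KeyError(f"missing column {col!r}")
    grouped = measures.groupby([subject, treatment])[value]
    counts = grouped.count()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise OperantLogError(f"more than two tests for cells {bad}")
    out = grouped.mean().rename(value).reset_index()
    out["n_tests"] = counts.values
    return out


def read_operant_log(
    path: str | Path,
    subject: str,
    schedule: Literal["FR1", "PR"],
    session_duration: Optional[float] = None,
) -> OperantSession:
    """Read an operant CSV (columns t_s, kind) into a session."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "kind"):
        if col not in df.columns:
            raise OperantLogError(f"{path}: missing column {col!r}")
    events = tuple(
        OperantEvent(t=float(r.t_s), kind=str(r.kind))
        for r in df.itertuples(index=False)
    )
    return OperantSession(
        subject=subject,
        schedule=schedule,
        events=events,
        session_duration=session_duration,
    )


def write_operant_log(session: OperantSession, path: str | Path) -> None:
    pd.DataFrame(
        {"t_s": [e.t for e in session.events], "kind": [e.kind for e in session.events]}
    ).to_csv(path, index=False)
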