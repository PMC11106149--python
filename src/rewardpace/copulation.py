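"""Mount-bout / time-out microstructure of male rat copulation.

Male rat copulation is organized in *ejaculation series*: runs of mounts and
intromissions culminating in an ejaculation, followed by a post-ejaculatory
interval (PEI) of inactivity before the next series.  Within a series the
copulatory events cluster in *mount bouts* — sequences of one or more
copulatory behaviors uninterrupted by any behavior that is not oriented
towards the female (genital autogrooming is exempt).  Whenever a
bout-breaking behavior (non-genital grooming, head away from the female)
occurs between two copulatory events, the earlier bout ends at the end of
its last copulatory behavior, the next bout starts at the onset of the next
copulatory behavior, and the gap between them is a *time-out*.

This module segments a validated behavior log into series, bouts and
time-outs and derives the standard outcome measures for the first series:
counts, intromission ratio (intromissions / (mounts + intromissions)), mean
bout composition, mean time-out duration, first PEI, censored latencies, and
percent-time budgets up to the first ejaculation.

Conventions chosen where annotation leaves slack (all events may be
intervals): latency to ejaculation runs from the onset of the first
mount/intromission to the onset of the ejaculation; the PEI runs from the
offset of the ejaculation to the onset of the next mount or intromission.
For point-annotated events the two conventions coincide.  A rat that reaches
no ejaculation is scored at the full test duration (1800 s), as is a rat
that shows no copulatory behavior at all for the latency to first behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .ethogram import BehaviorEvent, CopulationTestLog

__all__ = [
    "EjaculationSeries",
    "MountBout",
    "TimeOut",
    "CopulationMeasures",
    "partition_series",
    "segment_mount_bouts",
    "compute_measures",
]

_MOUNT_INTRO = ("mount", "intromission")


@dataclass(frozen=True)
class EjaculationSeries:
    """One ejaculation series: first mount/intromission up to the ejaculation.

    ``ejaculation_time`` is the onset of the terminating ejaculation, or
    ``None`` for a trailing incomplete series.  ``pei`` is the time from the
    ejaculation offset to the onset of the next series' first copulatory
    event, or ``None`` when either endpoint does not exist.
    """

    index: int  # 1-based
    start: float
    ejaculation_time: Optional[float] = None
    ejaculation_end: Optional[float] = None
    pei: Optional[float] = None

    @property
    def complete(self) -> bool:
        return self.ejaculation_time is not None


@dataclass(frozen=True)
class MountBout:
    """A maximal run of copulatory events not split by bout-breaking behavior."""

    events: tuple[BehaviorEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a mount bout has at least one copulatory member")

    @property
    def start(self) -> float:
        return self.events[0].start

    @property
    def end(self) -> float:
        return self.events[-1].end

    @property
    def span(self) -> float:
        return self.end - self.start

    def n_of(self, label: str) -> int:
        return sum(1 for e in self.events if e.behavior == label)


@dataclass(frozen=True)
class TimeOut:
    """Gap between two consecutive mount bouts of the same series."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def partition_series(log: CopulationTestLog) -> list[EjaculationSeries]:
    """Split a log into ejaculation series.

    A series starts at the first mount or intromission following the previous
    ejaculation and is terminated by the next ejaculation.  A trailing run of
    copulatory behavior without an ejaculation yields one incomplete series.
    A log with no copulatory events yields no series.
    """
    cop = log.copulatory_events()
    series: list[EjaculationSeries] = []
    start: Optional[float] = None
    ejac: Optional[BehaviorEvent] = None
    pending: Optional[dict] = None  # closed series awaiting its PEI endpoint
    for e in cop:
        if start is None:
            start = e.start
        if pending is not None and e.behavior in _MOUNT_INTRO:
            pending["pei"] = e.start - pending["ejaculation_end"]
            series.append(EjaculationSeries(**pending))
            pending = None
        if e.behavior == "ejaculation":
            ejac = e
            if pending is not None:  # E with no M/I in between: PEI undefined
                series.append(EjaculationSeries(**pending))
                pending = None
            pending = dict(
                index=len(series) + 1,
                start=start,
                ejaculation_time=ejac.start,
                ejaculation_end=ejac.end,
                pei=None,
            )
            start = None
    if pending is not None:
        series.append(EjaculationSeries(**pending))
        pending = None
    elif start is not None:
        series.append(EjaculationSeries(index=len(series) + 1, start=start))
    return series


def _series_events(
    log: CopulationTestLog, series: EjaculationSeries
) -> tuple[BehaviorEvent, ...]:
    """Copulatory events belonging to *series* (ejaculation inclusive)."""
    hi = series.ejaculation_time if series.complete else math.inf
    return tuple(
        e
        for e in log.copulatory_events()
        if series.start <= e.start <= hi
    )


def segment_mount_bouts(
    log: CopulationTestLog, series: EjaculationSeries
) -> tuple[list[MountBout], list[TimeOut]]:
    """Segment one series into mount bouts and the time-outs between them.

    For each consecutive pair of copulatory events the open gap between the
    end of the earlier and the start of the later is scanned: if any
    bout-breaking event intersects it, the bout is closed and the gap is a
    time-out.  Bout-neutral events (genital grooming and female-oriented
    behaviors) never split a bout.  The ejaculation terminates the final
    bout of its series.  The interval before the first copulatory behavior
    and the PEI are never time-outs.
    """
    cop = _series_events(log, series)
    if not cop:
        return [], []
    breaking = log.events_of(*log.vocabulary.bout_breaking)
    bouts: list[MountBout] = []
    timeouts: list[TimeOut] = []
    current: list[BehaviorEvent] = [cop[0]]
    for prev, nxt in zip(cop, cop[1:]):
        if _gap_is_broken(prev.end, nxt.start, breaking):
            bouts.append(MountBout(tuple(current)))
            timeouts.append(TimeOut(start=prev.end, end=nxt.start))
            current = [nxt]
        else:
            current.append(nxt)
    bouts.append(MountBout(tuple(current)))
    return bouts, timeouts


def _gap_is_broken(
    gap_start: float, gap_end: float, breaking: tuple[BehaviorEvent, ...]
) -> bool:
    """True iff a bout-breaking event intersects the open gap.

    An interval event intersects when it covers any part of the open gap; a
    point event must fall strictly inside.  Events wholly within a copulatory
    event cannot intersect (the gap is empty or disjoint from them).
    """
    if gap_end <= gap_start:
        return False
    for b in breaking:
        if b.start < gap_end and b.end > gap_start:
            return True
        if b.start == b.end and gap_start < b.start < gap_end:
            return True
    return False


@dataclass(frozen=True)
class CopulationMeasures:
    """Outcome measures of one copulation test (series-1 unless noted).

    Counts exclude the ejaculation itself; ratios are ``None`` when their
    denominator is zero (never reported as 0).  Latencies are censored at
    the test duration.  Percent-time budgets are relative to the time from
    test start to the first ejaculation (full test if none is reached).
    """

    subject: str
    n_ejaculations: int
    n_mounts: int
    n_intromissions: int
    n_mount_bouts: int
    intromission_ratio: Optional[float]
    mean_mounts_per_bout: Optional[float]
    mean_intromissions_per_bout: Optional[float]
    mean_timeout_duration: Optional[float]
    pei_1: Optional[float]
    latency_to_ejaculation: float
    latency_to_first_copulatory_behavior: float
    percent_time: dict[str, float]
    percent_non_copulation_oriented: float

    def to_row(self) -> dict:
        row = {
            k: v
            for k, v in self.__dict__.items()
            if k != "percent_time"
        }
        for label, pct in sorted(self.percent_time.items()):
            row[f"pct_{label}"] = pct
        return row


def compute_measures(log: CopulationTestLog) -> CopulationMeasures:
    """All copulation outcome measures for one test log."""
    series = partition_series(log)
    n_ejaculations = len(log.events_of("ejaculation"))
    duration = log.test_duration

    if series:
        s1 = series[0]
        bouts, touts = segment_mount_bouts(log, s1)
        s1_events = _series_events(log, s1)
        n_mounts = sum(1 for e in s1_events if e.behavior == "mount")
        n_intromissions = sum(
            1 for e in s1_events if e.behavior == "intromission"
        )
        n_bouts = len(bouts)
        denom = n_mounts + n_intromissions
        intromission_ratio = n_intromissions / denom if denom else None
        mean_m = n_mounts / n_bouts if n_bouts else None
        mean_i = n_intromissions / n_bouts if n_bouts else None
        mean_to = (
            sum(t.duration for t in touts) / len(touts) if touts else None
        )
        pei_1 = s1.pei
        latency_first = s1.start
        latency_ejac = (
            s1.ejaculation_time - s1.start if s1.complete else duration
        )
        first_ejac = s1.ejaculation_time if s1.complete else None
    else:
        n_mounts = n_intromissions = n_bouts = 0
        intromission_ratio = mean_m = mean_i = mean_to = pei_1 = None
        latency_first = duration
        latency_ejac = duration
        first_ejac = None

    horizon = first_ejac if first_ejac is not None else duration
    percent_time = _percent_time(log, horizon)
    pct_noncop = sum(
        percent_time.get(label, 0.0)
        for label in log.vocabulary.bout_breaking
    )

    return CopulationMeasures(
        subject=log.subject,
        n_ejaculations=n_ejaculations,
        n_mounts=n_mounts,
        n_intromissions=n_intromissions,
        n_mount_bouts=n_bouts,
        intromission_ratio=intromission_ratio,
        mean_mounts_per_bout=mean_m,
        mean_intromissions_per_bout=mean_i,
        mean_timeout_duration=mean_to,
        pei_1=pei_1,
        latency_to_ejaculation=latency_ejac,
        latency_to_first_copulatory_behavior=latency_first,
        percent_time=percent_time,
        percent_non_copulation_oriented=pct_noncop,
    )


def _percent_time(log: CopulationTestLog, horizon: float) -> dict[str, float]:
    """Percent of [0, horizon] spent on each behavior (events clipped)."""
    if horizon <= 0:
        return {label: 0.0 for label in log.vocabulary.labels}
    budget: dict[str, float] = {label: 0.0 for label in log.vocabulary.labels}
    for e in log.events:
        lo, hi = max(e.start, 0.0), min(e.end, horizon)
        if hi > lo:
            budget[e.behavior] = budget.get(e.behavior, 0.0) + (hi - lo)
    return {label: 100.0 * t / horizon for label, t in budget.items()}
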