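"""Synthetic input streams with exact ground truth.

Every pipeline stage consumes one of four input streams that are not
publicly deposited for real experiments: copulation ethograms, operant
session logs, arena tracking traces, and stained-section images.  The
generators here emulate each stream with a structure whose ground truth is
known exactly, so segmentation and counting can be validated end to end.

The copulation generator is an explicit semi-Markov chain over macro-states
{mount bout, time-out, post-ejaculatory interval}: bouts emit copulatory
events separated by short within-bout intervals (optionally filled with
bout-neutral behavior), time-outs always contain at least one bout-breaking
event (otherwise they would not be time-outs by definition), and an
ejaculation fires when the intromission count reaches a threshold, followed
by a long PEI.  Default scales are chosen to resemble published
figure-scale magnitudes for sexually experienced male rats (within-bout
inter-copulatory intervals ~12 s, time-outs ~45 s, PEI ~5 min, ~8
intromissions to ejaculation); no claim of distributional fidelity is made.

The operant generator emits press bouts with within-bout inter-press
intervals stochastically smaller than between-bout intervals (a validated
invariant), replaying the FR1 trial structure (press -> reward -> nosepoke)
or a PR schedule with its 30-min stop rule.  The arena generator is a
semi-Markov dwell model over {female zone, male zone, elsewhere} whose
per-sample occupancy ledger is exact for the analyzer.  The image generator
plants non-overlapping disks on a noisy background.

Per-design-cell effect multipliers (e.g. longer time-outs under Gi x CNO)
support effect-recovery validation of the statistics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ethogram import (
    DEFAULT_VOCABULARY,
    BehaviorEvent,
    BehaviorVocabulary,
    CopulationTestLog,
)
from .motivation import Rect, TrackingTrace, ZoneSpec
from .operant import OperantEvent, OperantSession, PRSchedule, generate_pr_schedule

__all__ = [
    "CopulationSimParams",
    "CopulationGroundTruth",
    "simulate_copulation",
    "OperantSimParams",
    "OperantGroundTruth",
    "simulate_operant",
    "ArenaSimParams",
    "TraceGroundTruth",
    "simulate_trace",
    "ImageSimParams",
    "simulate_section_image",
    "simulate_design_outcomes",
]


# --------------------------------------------------------------------------
# copulation


@dataclass(frozen=True)
class CopulationSimParams:
    """Semi-Markov copulation generator parameters (times in seconds)."""

    test_duration: float = 1800.0
    initial_latency_mean: float = 60.0  # exponential, before the first bout
    event_duration: tuple[float, float] = (1.0, 3.0)  # mount/intromission
    ejaculation_duration: tuple[float, float] = (3.0, 6.0)
    within_ici_mu: float = math.log(12.0)  # log-normal within-bout interval
    within_ici_sigma: float = 0.5
    p_continue_bout: float = 0.6  # else the bout ends in a time-out
    p_intromission: float = 0.5  # per copulatory event
    intromission_threshold: float = 8  # intromissions to ejaculation (inf ok)
    timeout_mu: float = math.log(45.0)
    timeout_sigma: float = 0.4
    pei_mu: float = math.log(300.0)
    pei_sigma: float = 0.25
    p_neutral_filler: float = 0.7  # chance a within-bout gap holds a filler
    timeout_scale: float = 1.0  # effect-injection multipliers
    pei_scale: float = 1.0
    vocabulary: BehaviorVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        if not (0 <= self.p_continue_bout < 1):
            raise ValueError("p_continue_bout must be in [0, 1)")
        if not (0 <= self.p_intromission <= 1):
            raise ValueError("p_intromission must be in [0, 1]")
        for name in ("initial_latency_mean", "timeout_scale", "pei_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_effects(self, **multipliers: float) -> "CopulationSimParams":
        return replace(self, **multipliers)


@dataclass(frozen=True)
class GroundTruthBout:
    series_index: int
    start: float
    end: float
    n_mounts: int
    n_intromissions: int
    n_events: int


@dataclass(frozen=True)
class GroundTruthTimeOut:
    series_index: int
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class GroundTruthSeries:
    index: int
    start: float
    ejaculation_time: Optional[float]
    pei: Optional[float]


@dataclass(frozen=True)
class CopulationGroundTruth:
    series: tuple[GroundTruthSeries, ...]
    bouts: tuple[GroundTruthBout, ...]
    timeouts: tuple[GroundTruthTimeOut, ...]

    def bouts_of_series(self, index: int) -> tuple[GroundTruthBout, ...]:
        return tuple(b for b in self.bouts if b.series_index == index)

    def timeouts_of_series(self, index: int) -> tuple[GroundTruthTimeOut, ...]:
        return tuple(t for t in self.timeouts if t.series_index == index)


def simulate_copulation(
    params: CopulationSimParams,
    seed: int | np.random.Generator,
    subject: str = "sim",
) -> tuple[CopulationTestLog, CopulationGroundTruth]:
    """Generate one copulation test log plus its exact ground truth.

    Every generated time-out contains at least one bout-breaking event
    strictly inside the gap, and within-bout gaps contain at most
    bout-neutral fillers, so the mount-bout segmenter recovers the emitted
    bout/time-out structure exactly.
    """
    rng = np.random.default_rng(seed)
    p = params
    voc = p.vocabulary
    events: list[BehaviorEvent] = []
    bouts: list[GroundTruthBout] = []
    timeouts: list[GroundTruthTimeOut] = []
    series: list[GroundTruthSeries] = []

    breaking_labels = sorted(voc.bout_breaking)
    neutral_labels = sorted(voc.bout_neutral)

    def filler(label: str, lo: float, hi: float) -> None:
        """Append a filler event strictly inside the open gap (lo, hi)."""
        span = hi - lo
        start = lo + 0.1 * span
        end = lo + 0.1 * span + 0.6 * span
        events.append(BehaviorEvent(start=start, end=min(end, hi - 1e-6 * span), behavior=label))

    t = float(rng.exponential(p.initial_latency_mean))
    if t > 1e-9:
        filler(str(rng.choice(breaking_labels)), 0.0, min(t, p.test_duration))

    series_idx = 1
    series_start: Optional[float] = None
    pending_series: Optional[dict] = None  # closed series awaiting its PEI
    pending_timeout: Optional[float] = None  # start of a gap awaiting next bout
    current: list[BehaviorEvent] = []
    n_intro = 0

    def close_bout() -> None:
        nonlocal current
        if current:
            bouts.append(
                GroundTruthBout(
                    series_index=series_idx,
                    start=current[0].start,
                    end=current[-1].end,
                    n_mounts=sum(e.behavior == "mount" for e in current),
                    n_intromissions=sum(
                        e.behavior == "intromission" for e in current
                    ),
                    n_events=len(current),
                )
            )
            current = []

    while True:
        # decide the next copulatory event
        if n_intro >= p.intromission_threshold:
            label = "ejaculation"
            dur = float(rng.uniform(*p.ejaculation_duration))
        else:
            label = (
                "intromission"
                if rng.random() < p.p_intromission
                else "mount"
            )
            dur = float(rng.uniform(*p.event_duration))
        if t + dur > p.test_duration:
            break
        ev = BehaviorEvent(start=t, end=t + dur, behavior=label)
        if pending_series is not None:
            series.append(
                GroundTruthSeries(
                    pei=ev.start - pending_series.pop("ejaculation_end"),
                    **pending_series,
                )
            )
            pending_series = None
        if pending_timeout is not None:
            timeouts.append(
                GroundTruthTimeOut(
                    series_index=series_idx, start=pending_timeout, end=ev.start
                )
            )
            pending_timeout = None
        events.append(ev)
        current.append(ev)
        if series_start is None:
            series_start = ev.start

        if label == "ejaculation":
            close_bout()
            pending_series = dict(
                index=series_idx,
                start=series_start,
                ejaculation_time=ev.start,
                ejaculation_end=ev.end,
            )
            series_idx += 1
            series_start = None
            n_intro = 0
            pei = float(rng.lognormal(p.pei_mu, p.pei_sigma)) * p.pei_scale
            gap_end = min(ev.end + pei, p.test_duration)
            if gap_end > ev.end:
                filler(str(rng.choice(breaking_labels)), ev.end, gap_end)
            t = ev.end + pei
            continue

        n_intro += label == "intromission"
        if rng.random() < p.p_continue_bout:
            gap = float(rng.lognormal(p.within_ici_mu, p.within_ici_sigma))
            gap_end = min(ev.end + gap, p.test_duration)
            if gap_end > ev.end and rng.random() < p.p_neutral_filler:
                filler(str(rng.choice(neutral_labels)), ev.end, gap_end)
            t = ev.end + gap
        else:
            close_bout()
            gap = (
                float(rng.lognormal(p.timeout_mu, p.timeout_sigma))
                * p.timeout_scale
            )
            gap_end = min(ev.end + gap, p.test_duration)
            if gap_end > ev.end:
                filler(str(rng.choice(breaking_labels)), ev.end, gap_end)
            pending_timeout = ev.end
            t = ev.end + gap

    close_bout()
    if pending_series is not None:
        pending_series.pop("ejaculation_end")
        series.append(GroundTruthSeries(pei=None, **pending_series))
    elif series_start is not None:
        series.append(
            GroundTruthSeries(
                index=series_idx,
                start=series_start,
                ejaculation_time=None,
                pei=None,
            )
        )

    log = CopulationTestLog(
        subject=subject,
        events=tuple(sorted(events)),
        test_duration=p.test_duration,
        vocabulary=voc,
    )
    truth = CopulationGroundTruth(
        series=tuple(series), bouts=tuple(bouts), timeouts=tuple(timeouts)
    )
    return log, truth


# --------------------------------------------------------------------------
# operant


@dataclass(frozen=True)
class OperantSimParams:
    """Press-bout generator for FR1 / PR sessions (times in seconds)."""

    schedule: str = "FR1"
    session_duration: float = 1800.0  # FR1 fixed length
    initial_latency_mean: float = 30.0
    bout_size_mean: float = 5.0  # geometric, >= 1
    within_mu: float = math.log(1.5)  # within-bout inter-press interval
    within_sigma: float = 0.3
    between_mu: float = math.log(60.0)  # between-bout interval
    between_sigma: float = 0.3
    nosepoke_delay: tuple[float, float] = (0.3, 0.8)
    inactive_rate: float = 0.003  # inactive presses per second
    pr_n_requirements: int = 12
    pr_max_rewards: int = 8  # the rat quits after this many PR rewards
    interval_scale: float = 1.0  # effect injection: slows all pressing

    def __post_init__(self) -> None:
        if self.schedule not in ("FR1", "PR"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.bout_size_mean < 1:
            raise ValueError("bout_size_mean must be >= 1")
        if math.exp(self.between_mu) <= math.exp(self.within_mu):
            raise ValueError(
                "between-bout intervals must be stochastically larger than "
                "within-bout intervals"
            )
        if self.interval_scale <= 0:
            raise ValueError("interval_scale must be positive")

    def with_effects(self, **multipliers: float) -> "OperantSimParams":
        return replace(self, **multipliers)


@dataclass(frozen=True)
class OperantGroundTruth:
    press_times: np.ndarray
    bout_labels: np.ndarray  # bout id per active press
    n_bouts: int
    breakpoint: int  # PR only; 0 under FR1
    test_duration: float


def simulate_operant(
    params: OperantSimParams,
    seed: int | np.random.Generator,
    subject: str = "sim",
) -> tuple[OperantSession, OperantGroundTruth]:
    """Generate one operant session plus ground-truth bout membership."""
    rng = np.random.default_rng(seed)
    p = params
    if p.schedule == "FR1":
        return _simulate_fr1(p, rng, subject)
    return _simulate_pr(p, rng, subject)


def _bout_sizes(p: OperantSimParams, rng: np.random.Generator) -> int:
    if p.bout_size_mean == 1:
        return 1
    if math.isinf(p.bout_size_mean):  # bouts never end: one bout per session
        return 10**9
    return int(rng.geometric(1.0 / p.bout_size_mean))


def _merge_inactive(
    events: list[OperantEvent],
    p: OperantSimParams,
    rng: np.random.Generator,
    duration: float,
) -> tuple[OperantEvent, ...]:
    n_inactive = int(rng.poisson(p.inactive_rate * duration))
    for t in rng.uniform(0.0, duration, size=n_inactive):
        events.append(OperantEvent(t=float(t), kind="inactive_press"))
    return tuple(sorted(events, key=lambda e: e.t))


def _simulate_fr1(
    p: OperantSimParams, rng: np.random.Generator, subject: str
) -> tuple[OperantSession, OperantGroundTruth]:
    events: list[OperantEvent] = []
    press_times: list[float] = []
    bout_labels: list[int] = []
    t = float(rng.exponential(p.initial_latency_mean))
    bout_id = 0
    done = False
    while not done:
        size = _bout_sizes(p, rng)
        for k in range(size):
            if t > p.session_duration:
                done = True
                break
            events.append(OperantEvent(t=t, kind="active_press"))
            events.append(OperantEvent(t=t, kind="reward"))
            press_times.append(t)
            bout_labels.append(bout_id)
            gap = (
                float(rng.lognormal(p.within_mu, p.within_sigma))
                * p.interval_scale
            )
            npk = t + min(float(rng.uniform(*p.nosepoke_delay)), 0.8 * gap)
            if npk <= p.session_duration:
                events.append(OperantEvent(t=npk, kind="nosepoke"))
            t += gap
        if done:
            break
        t += (
            float(rng.lognormal(p.between_mu, p.between_sigma))
            * p.interval_scale
        )
        bout_id += 1
    all_events = _merge_inactive(events, p, rng, p.session_duration)
    session = OperantSession(
        subject=subject,
        schedule="FR1",
        events=all_events,
        session_duration=p.session_duration,
    )
    labels = np.asarray(bout_labels, dtype=int)
    truth = OperantGroundTruth(
        press_times=np.asarray(press_times),
        bout_labels=labels,
        n_bouts=len(np.unique(labels)) if len(labels) else 0,
        breakpoint=0,
        test_duration=p.session_duration,
    )
    return session, truth


def _simulate_pr(
    p: OperantSimParams, rng: np.random.Generator, subject: str
) -> tuple[OperantSession, OperantGroundTruth]:
    from .operant import PR_STOP_WINDOW

    schedule: PRSchedule = generate_pr_schedule(p.pr_n_requirements)
    target = min(p.pr_max_rewards, len(schedule))
    events: list[OperantEvent] = []
    press_times: list[float] = []
    bout_labels: list[int] = []
    t = float(rng.exponential(p.initial_latency_mean))
    bout_id = 0
    rewards = 0
    since_reward = 0
    last_reward_t = 0.0
    remaining = _bout_sizes(p, rng)
    while rewards < target:
        events.append(OperantEvent(t=t, kind="active_press"))
        press_times.append(t)
        bout_labels.append(bout_id)
        since_reward += 1
        remaining -= 1
        rewarded = since_reward == schedule[rewards]
        if rewarded:
            events.append(OperantEvent(t=t, kind="reward"))
            last_reward_t = t
            rewards += 1
            since_reward = 0
            gap = (
                float(rng.lognormal(p.within_mu, p.within_sigma))
                * p.interval_scale
            )
            npk = t + min(float(rng.uniform(*p.nosepoke_delay)), 0.8 * gap)
            events.append(OperantEvent(t=npk, kind="nosepoke"))
            t += gap
            continue
        if remaining <= 0:
            t += (
                float(rng.lognormal(p.between_mu, p.between_sigma))
                * p.interval_scale
            )
            bout_id += 1
            remaining = _bout_sizes(p, rng)
        else:
            t += (
                float(rng.lognormal(p.within_mu, p.within_sigma))
                * p.interval_scale
            )
    test_duration = (
        last_reward_t + PR_STOP_WINDOW if rewards else PR_STOP_WINDOW
    )
    all_events = _merge_inactive(events, p, rng, test_duration)
    session = OperantSession(
        subject=subject,
        schedule="PR",
        events=all_events,
        session_duration=test_duration,
    )
    labels = np.asarray(bout_labels, dtype=int)
    truth = OperantGroundTruth(
        press_times=np.asarray(press_times),
        bout_labels=labels,
        n_bouts=len(np.unique(labels)) if len(labels) else 0,
        breakpoint=schedule[rewards - 1] if rewards else 0,
        test_duration=test_duration,
    )
    return session, truth


# --------------------------------------------------------------------------
# arena traces


@dataclass(frozen=True)
class ArenaSimParams:
    """Semi-Markov dwell model over {female zone, male zone, elsewhere}."""

    zones: ZoneSpec = field(default_factory=ZoneSpec.default)
    duration: float = 600.0  # the 10-min SIM test
    sample_rate: float = 10.0  # Hz
    dwell_probs: tuple[float, float] = (0.45, 0.20)  # female, male
    dwell_mean: float = 15.0  # s per visit (exponential)
    step_sigma: float = 1.0  # cm random-walk step
    margin: float = 2.0  # cm kept clear of zone edges

    def __post_init__(self) -> None:
        if sum(self.dwell_probs) > 1.0:
            raise ValueError("dwell probabilities must sum to <= 1")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("duration and sample rate must be positive")


@dataclass(frozen=True)
class TraceGroundTruth:
    states: np.ndarray  # per-sample region name
    time_in_zone: dict[str, float]
    entries: dict[str, int]
    preference_score: Optional[float]


def _neutral_region(zones: ZoneSpec, margin: float) -> Rect:
    """A rectangle inside the arena, disjoint from every stimulus zone."""
    arena = zones.arena
    x_lo = max(z.x1 for z in zones.zones.values() if z.x0 == arena.x0) \
        if any(z.x0 == arena.x0 for z in zones.zones.values()) else arena.x0
    x_hi = min(z.x0 for z in zones.zones.values() if z.x1 == arena.x1) \
        if any(z.x1 == arena.x1 for z in zones.zones.values()) else arena.x1
    rect = Rect(
        x_lo + margin, arena.y0 + margin, x_hi - margin, arena.y1 - margin
    )
    for z in zones.zones.values():
        if not rect.disjoint(z):
            raise ValueError("cannot build a neutral region for these zones")
    return rect


def simulate_trace(
    params: ArenaSimParams, seed: int | np.random.Generator
) -> tuple[TrackingTrace, TraceGroundTruth]:
    """Generate a tracking trace plus the generator's own occupancy ledger.

    Positions stay strictly inside the current region (zones shrunk by the
    margin), so the analyzer's half-open zone membership agrees with the
    state sequence sample for sample and the ledger is exact.
    """
    rng = np.random.default_rng(seed)
    p = params
    zone_names = list(p.zones.zones)
    n = int(round(p.duration * p.sample_rate)) + 1
    t = np.arange(n) / p.sample_rate

    regions: dict[str, Rect] = {}
    for name, z in p.zones.zones.items():
        regions[name] = Rect(
            z.x0 + p.margin, z.y0 + p.margin, z.x1 - p.margin, z.y1 - p.margin
        )
    regions["elsewhere"] = _neutral_region(p.zones, p.margin)

    probs = list(p.dwell_probs) + [1.0 - sum(p.dwell_probs)]
    choices = zone_names + ["elsewhere"]

    states = np.empty(n, dtype=object)
    i = 0
    while i < n:
        state = str(rng.choice(choices, p=probs))
        dwell = max(1, int(round(rng.exponential(p.dwell_mean) * p.sample_rate)))
        states[i : i + dwell] = state
        i += dwell

    x = np.empty(n)
    y = np.empty(n)
    pos = None
    for k in range(n):
        rect = regions[states[k]]
        if pos is None or states[k] != states[k - 1]:
            pos = np.array(
                [rng.uniform(rect.x0, rect.x1), rng.uniform(rect.y0, rect.y1)]
            )
        else:
            pos = pos + rng.normal(0.0, p.step_sigma, size=2)
            pos[0] = min(max(pos[0], rect.x0), np.nextafter(rect.x1, rect.x0))
            pos[1] = min(max(pos[1], rect.y0), np.nextafter(rect.y1, rect.y0))
        x[k], y[k] = pos

    dt = np.diff(t)
    time_in_zone: dict[str, float] = {}
    entries: dict[str, int] = {}
    for name in zone_names:
        inside = states == name
        time_in_zone[name] = float(dt[inside[:-1]].sum())
        entries[name] = int(inside[0]) + int(
            np.count_nonzero(inside[1:] & ~inside[:-1])
        )
    t_f = time_in_zone.get("female_zone", 0.0)
    t_m = time_in_zone.get("male_zone", 0.0)
    pref = t_f / (t_f + t_m) if (t_f + t_m) > 0 else None

    trace = TrackingTrace(t=t, x=x, y=y)
    truth = TraceGroundTruth(
        states=states,
        time_in_zone=time_in_zone,
        entries=entries,
        preference_score=pref,
    )
    return trace, truth


# --------------------------------------------------------------------------
# section images


@dataclass(frozen=True)
class ImageSimParams:
    """Planted-disk section image: non-overlapping bright disks on noise."""

    shape: tuple[int, int] = (384, 384)
    n_disks: int = 25
    radius_range: tuple[float, float] = (5.0, 15.0)
    background: float = 40.0
    foreground: float = 200.0
    noise_sigma: float = 8.0
    min_gap: float = 4.0  # px clearance between disk rims
    roi_margin: int = 24  # disks stay this far from the image border

    def __post_init__(self) -> None:
        if self.n_disks < 0:
            raise ValueError("n_disks must be >= 0")
        if self.foreground <= self.background:
            raise ValueError("foreground must exceed background")


def simulate_section_image(
    params: ImageSimParams, seed: int | np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic section image and its planted-particle table.

    Returns an 8-bit image and a table with one row per disk (row, col,
    radius, area in pixels).  Any threshold between the background-noise
    ceiling and the disk intensity separates all disks.
    """
    from skimage.draw import disk as sk_disk

    rng = np.random.default_rng(seed)
    p = params
    img = rng.normal(p.background, p.noise_sigma, size=p.shape)
    rows: list[dict] = []
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < p.n_disks:
        attempts += 1
        if attempts > 10000 * max(1, p.n_disks):
            raise RuntimeError("could not place non-overlapping disks; "
                               "reduce n_disks or radii")
        r = float(rng.uniform(p.radius_range[0], p.radius_range[1]))
        lo = p.roi_margin + math.ceil(r)
        cy = float(rng.uniform(lo, p.shape[0] - lo))
        cx = float(rng.uniform(lo, p.shape[1] - lo))
        if any(
            math.hypot(cy - oy, cx - ox) < r + orad + p.min_gap
            for oy, ox, orad in placed
        ):
            continue
        placed.append((cy, cx, r))
        rr, cc = sk_disk((cy, cx), r, shape=p.shape)
        img[rr, cc] = p.foreground
        rows.append({"row": cy, "col": cx, "radius": r, "area_px": len(rr)})
    img = np.clip(img, 0, 255).astype(np.uint8)
    table = pd.DataFrame(rows, columns=["row", "col", "radius", "area_px"])
    return img, table


# --------------------------------------------------------------------------
# design-level outcome simulation (for the statistics layer)


def simulate_design_outcomes(
    n_per_group: int = 12,
    effect_d: Optional[dict[str, float]] = None,
    baseline: float = 10.0,
    sigma_between: float = 2.0,
    sigma_diff: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a subject-level outcome table for the post-hoc contrast layer.

    Each subject contributes a VEH and a CNO measurement around a random
    subject intercept.  ``effect_d`` maps virus groups to the CNO - VEH
    shift in units of the within-subject difference SD (``sigma_diff``), so
    ``effect_d={"Gi": 1.0}`` injects a 1-SD within-subject effect for the
    Gi group and leaves the others at the null.
    """
    rng = np.random.default_rng(seed)
    effect_d = effect_d or {}
    noise_sd = sigma_diff / math.sqrt(2.0)
    records = []
    for virus in ("Sham", "Gi", "Gq"):
        shift = effect_d.get(virus, 0.0) * sigma_diff
        for k in range(n_per_group):
            intercept = baseline + rng.normal(0.0, sigma_between)
            subject = f"{virus}-{k:02d}"
            records.append(
                {
                    "subject": subject,
                    "virus": virus,
                    "treatment": "VEH",
                    "value": intercept + rng.normal(0.0, noise_sd),
                }
            )
            records.append(
                {
                    "subject": subject,
                    "virus": virus,
                    "treatment": "CNO",
                    "value": intercept + shift + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame.from_records(records)
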