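"""Sexual incentive motivation (SIM) test: zone occupancy and locomotion.

In the SIM test the subject explores a rectangular arena (100 x 50 cm) with
a receptive female and a control male each confined behind wire mesh at
opposite corners.  Virtual stimulus zones (30 x 21 cm) are defined in front
of each stimulus cage; the subject is in a zone whenever its tracked center
of gravity is.  The preference score is the time in the female zone divided
by the total time in both incentive zones; chance level is 0.5.

Zone membership uses half-open rectangles [x0, x1) x [y0, y1) so a point on
a shared edge belongs to at most one zone.  Occupancy time attributes each
inter-sample interval to the zone containing the earlier sample (tracker
exports are sample-based; no sub-sample interpolation of crossings).  An
entry is counted at each outside-to-inside transition, including the first
sample when it already lies inside the zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Rect",
    "ZoneSpec",
    "TrackingTrace",
    "ZoneOccupancy",
    "SimMeasures",
    "zone_occupancy",
    "preference_score",
    "locomotion",
    "analyze_trace",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; membership is half-open: [x0,x1) x [y0,y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("rectangle must have positive extent")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def within(self, other: "Rect") -> bool:
        return (
            self.x0 >= other.x0
            and self.y0 >= other.y0
            and self.x1 <= other.x1
            and self.y1 <= other.y1
        )

    def disjoint(self, other: "Rect") -> bool:
        return (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class ZoneSpec:
    """Named stimulus zones inside an arena rectangle (disjoint, contained)."""

    zones: dict[str, Rect]
    arena: Rect

    def __post_init__(self) -> None:
        names = list(self.zones)
        for name, z in self.zones.items():
            if not z.within(self.arena):
                raise ValueError(f"zone {name!r} extends beyond the arena")
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if not self.zones[a].disjoint(self.zones[b]):
                    raise ValueError(f"zones {a!r} and {b!r} overlap")

    @classmethod
    def default(cls) -> "ZoneSpec":
        """100 x 50 cm arena with 30 x 21 cm zones at opposite long sides."""
        return cls(
            zones={
                "female_zone": Rect(0.0, 29.0, 30.0, 50.0),
                "male_zone": Rect(70.0, 0.0, 100.0, 21.0),
            },
            arena=Rect(0.0, 0.0, 100.0, 50.0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ZoneSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        arena = Rect(**cfg["arena"])
        zones = {name: Rect(**r) for name, r in cfg["zones"].items()}
        return cls(zones=zones, arena=arena)

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "arena": vars(self.arena).copy(),
            "zones": {n: vars(r).copy() for n, r in self.zones.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)


@dataclass(frozen=True)
class TrackingTrace:
    """Time-stamped 2-D center-of-gravity positions (t strictly increasing)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackingTrace":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("t_s", "x_cm", "y_cm"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(
            t=df["t_s"].to_numpy(), x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy()
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ZoneOccupancy:
    time_s: float
    entries: int


@dataclass(frozen=True)
class SimMeasures:
    """Per-test SIM outcome measures."""

    occupancy: dict[str, ZoneOccupancy]
    preference_score: Optional[float]
    distance_moved: float
    mean_velocity: float

    def to_row(self) -> dict:
        row: dict = {
            "preference_score": self.preference_score,
            "distance_moved_cm": self.distance_moved,
            "mean_velocity_cm_s": self.mean_velocity,
        }
        for name, occ in sorted(self.occupancy.items()):
            row[f"time_{name}_s"] = occ.time_s
            row[f"entries_{name}"] = occ.entries
        return row


def zone_occupancy(
    trace: TrackingTrace, zones: ZoneSpec
) -> dict[str, ZoneOccupancy]:
    """Per-zone occupancy time and entry counts for one trace.

    Each inter-sample interval accrues to the zone containing the earlier
    sample (left-constant interpolation); entries count outside-to-inside
    transitions, with the first in-zone sample counting as an entry.
    """
    if len(trace) == 0:
        raise ValueError("empty tracking trace")
    dt = np.diff(trace.t)
    out: dict[str, ZoneOccupancy] = {}
    for name, rect in zones.zones.items():
        inside = rect.contains(trace.x, trace.y)
        time_s = float(dt[inside[:-1]].sum()) if len(trace) > 1 else 0.0
        entries = int(inside[0]) + int(
            np.count_nonzero(inside[1:] & ~inside[:-1])
        )
        out[name] = ZoneOccupancy(time_s=time_s, entries=entries)
    return out


def preference_score(t_female: float, t_male: float) -> Optional[float]:
    """Female-zone time over total incentive-zone time; None when both 0."""
    if t_female < 0 or t_male < 0:
        raise ValueError("zone times must be non-negative")
    total = t_female + t_male
    if total == 0:
        return None
    return t_female / total


def locomotion(trace: TrackingTrace) -> tuple[float, float]:
    """Total path length (cm) and mean velocity (cm/s) of a trace."""
    if len(trace) < 2:
        raise ValueError("locomotion requires at least two samples")
    steps = np.hypot(np.diff(trace.x), np.diff(trace.y))
    distance = float(steps.sum())
    return distance, distance / trace.duration


def analyze_trace(
    trace: TrackingTrace,
    zones: ZoneSpec | None = None,
    female_zone: str = "female_zone",
    male_zone: str = "male_zone",
) -> SimMeasures:
    """Full SIM readout: occupancy, preference score, locomotion."""
    zones = zones or ZoneSpec.default()
    occ = zone_occupancy(trace, zones)
    pref = preference_score(occ[female_zone].time_s, occ[male_zone].time_s)
    distance, velocity = locomotion(trace)
    return SimMeasures(
        occupancy=occ,
        preference_score=pref,
        distance_moved=distance,
        mean_velocity=velocity,
    )
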