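"""Annotated behavior event streams from copulation tests.

A copulation test is scored from video as a stream of labeled, timestamped
behavior events.  The vocabulary splits into three functional classes that
drive all downstream segmentation:

* **copulatory** — mount, intromission, ejaculation: the events that form
  mount bouts and terminate ejaculation series;
* **bout-breaking** — self-grooming of non-genital regions and any behavior
  with the head oriented away from the female: an occurrence between two
  copulatory events splits the mount bout and opens a time-out;
* **bout-neutral** — genital grooming and female-oriented behaviors
  (anogenital sniffing, chasing, head towards female): these may fill the
  gap between copulatory events without breaking the bout.

Events are intervals ``[start, end]`` in seconds from test start; point
events are stored with ``end == start``.  Copulatory events must not overlap
each other; no gap-free coverage of non-copulatory time is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

__all__ = [
    "EthogramError",
    "BehaviorVocabulary",
    "DEFAULT_VOCABULARY",
    "BehaviorEvent",
    "CopulationTestLog",
    "Violation",
    "read_ethogram",
    "write_ethogram",
    "validate_log",
]

DEFAULT_TEST_DURATION = 1800.0  # 30-min copulation test


class EthogramError(ValueError):
    """Raised for malformed ethogram files or invalid event data."""


@dataclass(frozen=True)
class BehaviorVocabulary:
    """Closed behavior vocabulary with functional class membership.

    The three classes must be disjoint; together they are the ethogram.
    """

    copulatory: frozenset[str]
    bout_breaking: frozenset[str]
    bout_neutral: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.copulatory, self.bout_breaking, self.bout_neutral]
        total = sum(len(s) for s in sets)
        if len(self.labels) != total:
            raise EthogramError("vocabulary classes must be disjoint")
        if "ejaculation" in self.labels and "ejaculation" not in self.copulatory:
            raise EthogramError("ejaculation must be a copulatory behavior")

    @property
    def labels(self) -> frozenset[str]:
        return self.copulatory | self.bout_breaking | self.bout_neutral

    def class_of(self, label: str) -> str:
        if label in self.copulatory:
            return "copulatory"
        if label in self.bout_breaking:
            return "bout_breaking"
        if label in self.bout_neutral:
            return "bout_neutral"
        raise EthogramError(f"unknown behavior label: {label!r}")

    @classmethod
    def default(cls) -> "BehaviorVocabulary":
        return cls(
            copulatory=frozenset({"mount", "intromission", "ejaculation"}),
            bout_breaking=frozenset({"other_grooming", "head_not_towards_female"}),
            bout_neutral=frozenset(
                {
                    "genital_grooming",
                    "anogenital_sniffing",
                    "chasing",
                    "head_towards_female",
                }
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BehaviorVocabulary":
        """Load a label -> class mapping (YAML) into a vocabulary."""
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise EthogramError("vocabulary YAML must map label -> class")
        classes: dict[str, set[str]] = {
            "copulatory": set(),
            "bout_breaking": set(),
            "bout_neutral": set(),
        }
        for label, cls_name in mapping.items():
            if cls_name not in classes:
                raise EthogramError(
                    f"label {label!r} assigned to unknown class {cls_name!r}"
                )
            classes[cls_name].add(str(label))
        return cls(
            copulatory=frozenset(classes["copulatory"]),
            bout_breaking=frozenset(classes["bout_breaking"]),
            bout_neutral=frozenset(classes["bout_neutral"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        mapping = {label: self.class_of(label) for label in sorted(self.labels)}
        with open(path, "w") as fh:
            yaml.safe_dump(mapping, fh, sort_keys=True)


DEFAULT_VOCABULARY = BehaviorVocabulary.default()


@dataclass(frozen=True, order=True)
class BehaviorEvent:
    """One annotated behavior: a label over ``[start, end]`` seconds.

    Ordering is by (start, end, behavior) so event lists sort by onset.
    """

    start: float
    end: float
    behavior: str = field(compare=True)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise EthogramError(
                f"event {self.behavior!r}: end {self.end} < start {self.start}"
            )
        if self.start < 0:
            raise EthogramError(f"event {self.behavior!r}: negative start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class CopulationTestLog:
    """Validated, time-sorted behavior log of one copulation test."""

    subject: str
    events: tuple[BehaviorEvent, ...]
    test_duration: float = DEFAULT_TEST_DURATION
    vocabulary: BehaviorVocabulary = DEFAULT_VOCABULARY
    virus: Optional[str] = None
    treatment: Optional[str] = None
    condition: Optional[str] = None
    excluded: bool = False  # manual exclusion (e.g. non-receptive female)

    def copulatory_events(self) -> tuple[BehaviorEvent, ...]:
        voc = self.vocabulary.copulatory
        return tuple(e for e in self.events if e.behavior in voc)

    def events_of(self, *labels: str) -> tuple[BehaviorEvent, ...]:
        wanted = set(labels)
        return tuple(e for e in self.events if e.behavior in wanted)

    def with_events(self, events: Iterable[BehaviorEvent]) -> "CopulationTestLog":
        return replace(self, events=tuple(sorted(events)))


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_log`."""

    code: str
    message: str
    index: Optional[int] = None


_REQUIRED_COLUMNS = ("subject", "behavior", "start_s", "end_s")


def read_ethogram(
    path: str | Path,
    vocabulary: BehaviorVocabulary | None = None,
    test_duration: float = DEFAULT_TEST_DURATION,
    subject: Optional[str] = None,
) -> CopulationTestLog:
    """Read one subject's ethogram CSV (columns subject,behavior,start_s,end_s).

    Rows are validated against the vocabulary and the test duration; the
    returned log is sorted by event onset.  Raises :class:`EthogramError`
    naming the offending row on the first violation.
    """
    vocabulary = vocabulary or DEFAULT_VOCABULARY
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EthogramError(f"{path}: missing columns {missing}")
    if df.empty:
        if subject is None:
            raise EthogramError(f"{path}: no rows and no subject given")
        return CopulationTestLog(
            subject=subject, events=(), test_duration=test_duration,
            vocabulary=vocabulary,
        )
    subjects = df["subject"].astype(str).unique()
    if len(subjects) > 1:
        raise EthogramError(
            f"{path}: expected one subject per file, found {list(subjects)}"
        )
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = str(row.behavior)
        if label not in vocabulary.labels:
            raise EthogramError(f"{path} row {i}: unknown behavior {label!r}")
        start, end = float(row.start_s), float(row.end_s)
        if end < start:
            raise EthogramError(f"{path} row {i}: end_s {end} < start_s {start}")
        if start < 0:
            raise EthogramError(f"{path} row {i}: negative start_s {start}")
        if end > test_duration:
            raise EthogramError(
                f"{path} row {i}: end_s {end} beyond test duration {test_duration}"
            )
        events.append(BehaviorEvent(start=start, end=end, behavior=label))
    events.sort()
    _check_copulatory_overlap(events, vocabulary, path)
    return CopulationTestLog(
        subject=str(subjects[0]),
        events=tuple(events),
        test_duration=test_duration,
        vocabulary=vocabulary,
    )


def _check_copulatory_overlap(
    events: list[BehaviorEvent], vocabulary: BehaviorVocabulary, path
) -> None:
    cop = [e for e in events if e.behavior in vocabulary.copulatory]
    for a, b in zip(cop, cop[1:]):
        if b.start < a.end:
            raise EthogramError(
                f"{path}: copulatory events overlap "
                f"({a.behavior} [{a.start},{a.end}] and {b.behavior} "
                f"[{b.start},{b.end}])"
            )


def write_ethogram(log: CopulationTestLog, path: str | Path) -> None:
    """Write a log back to the ethogram CSV dialect (round-trips with read)."""
    df = pd.DataFrame(
        {
            "subject": [log.subject] * len(log.events),
            "behavior": [e.behavior for e in log.events],
            "start_s": [e.start for e in log.events],
            "end_s": [e.end for e in log.events],
        }
    )
    # %.17g guarantees float round-trip through the CSV dialect
    df.to_csv(path, index=False, float_format="%.17g")


def validate_log(log: CopulationTestLog) -> list[Violation]:
    """Report every invariant violation in *log* (empty list iff valid)."""
    out: list[Violation] = []
    voc = log.vocabulary
    for i, e in enumerate(log.events):
        if e.behavior not in voc.labels:
            out.append(Violation("unknown_label", f"unknown label {e.behavior!r}", i))
        if e.start < 0:
            out.append(Violation("negative_time", f"start {e.start} < 0", i))
        if e.end < e.start:
            out.append(Violation("inverted", f"end {e.end} < start {e.start}", i))
        if e.end > log.test_duration:
            out.append(
                Violation(
                    "beyond_duration",
                    f"end {e.end} beyond test duration {log.test_duration}",
                    i,
                )
            )
    for i, (a, b) in enumerate(zip(log.events, log.events[1:])):
        if b.start < a.start:
            out.append(
                Violation("unsorted", f"event {i + 1} starts before event {i}", i + 1)
            )
    cop_idx = [
        i for i, e in enumerate(log.events) if e.behavior in voc.copulatory
    ]
    for i, j in zip(cop_idx, cop_idx[1:]):
        a, b = log.events[i], log.events[j]
        if min(a.start, b.start) == b.start and a.start > b.start:
            continue  # ordering violation already reported
        if b.start < a.end:
            out.append(
                Violation(
                    "copulatory_overlap",
                    f"copulatory events {i} and {j} overlap",
                    j,
                )
            )
    return out
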