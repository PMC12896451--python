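"""Threshold-driven segmentation of 1-Hz presence series into behavioral bouts.

A *bout* is a temporally contiguous episode of one behavior class.  It
opens when the class has been present for at least a class-specific
minimum number of consecutive seconds (the onset threshold: 5 s for
aggression, 3 s for ear and tail biting) and closes when the class has
been absent for at least the termination gap (5 s for every class).
Absences shorter than the termination gap are *bridged*: they interrupt
neither the bout nor its duration clock, so brief detector dropouts do
not fragment one biological episode into many.

Intervals are half-open ``[start_s, end_s)`` seconds-of-day, so a run of
exactly 5 present seconds yields a bout of duration 5.  Duration is the
timestamp difference ``end_s - start_s`` and therefore includes bridged
gap seconds.  Sub-threshold presence runs that precede the first
qualifying run are discarded — the bout starts only when the onset
criterion is first met — but once a bout is open any presence, even a
single second, extends it until a full termination gap elapses.

Two independent implementations are provided.  :func:`find_bouts` scans
the series second-by-second with hysteresis counters (mirroring an
online detector); :func:`find_bouts_oracle` works offline on maximal
presence runs.  They are equivalent, and the test suite enforces this
exhaustively on short vectors and statistically on day-length ones.
Classes are segmented independently: bouts of different classes may
overlap freely.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detection_io import SECONDS_PER_DAY, BehaviorClass, PresenceSeries

__all__ = [
    "BoutCriteria",
    "Bout",
    "find_bouts",
    "find_bouts_oracle",
    "read_bout_csv",
    "write_bout_csv",
    "bouts_to_frame",
]

#: Onset thresholds of the ethogram, seconds of consecutive presence.
DEFAULT_ONSET_MIN_S: Mapping[BehaviorClass, int] = MappingProxyType(
    {
        BehaviorClass.AGGRESSIVE: 5,
        BehaviorClass.EAR_BITING: 3,
        BehaviorClass.TAIL_BITING: 3,
    }
)

#: Termination gap shared by all classes, seconds of consecutive absence.
DEFAULT_TERMINATION_GAP_S = 5


@dataclass(frozen=True)
class BoutCriteria:
    """Per-class onset thresholds and the shared termination gap."""

    onset_min_s: Mapping[BehaviorClass, int] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_MIN_S)
    )
    termination_gap_s: int = DEFAULT_TERMINATION_GAP_S

    def __post_init__(self) -> None:
        for cls, onset in self.onset_min_s.items():
            if onset < 1:
                raise ValueError(f"onset_min_s[{cls}] must be >= 1, got {onset}")
        if self.termination_gap_s < 1:
            raise ValueError(
                f"termination_gap_s must be >= 1, got {self.termination_gap_s}"
            )

    @classmethod
    def default(cls) -> "BoutCriteria":
        return cls()


@dataclass(frozen=True, slots=True)
class Bout:
    """One class-labelled behavioral episode, half-open in seconds-of-day."""

    class_label: BehaviorClass
    date: dt.date
    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s <= SECONDS_PER_DAY:
            raise ValueError(
                f"need 0 <= start_s < end_s <= {SECONDS_PER_DAY}, "
                f"got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    def overlap_s(self, other: "Bout") -> int:
        """Shared seconds with ``other`` (0 if different dates)."""
        if self.date != other.date:
            return 0
        return max(0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


def _scan_intervals(
    presence: Sequence[int], onset_min_s: int, termination_gap_s: int
) -> list[tuple[int, int]]:
    """Online hysteresis scan: half-open (start, end) intervals."""
    intervals: list[tuple[int, int]] = []
    streak = 0  # consecutive present seconds ending at t
    absent = 0  # consecutive absent seconds ending at t (only while in a bout)
    in_bout = False
    start = 0
    last_present = -1
    for t, v in enumerate(presence):
        if v:
            streak += 1
            absent = 0
            last_present = t
            if not in_bout and streak >= onset_min_s:
                in_bout = True
                start = t - onset_min_s + 1
        else:
            streak = 0
            if in_bout:
                absent += 1
                if absent >= termination_gap_s:
                    intervals.append((start, last_present + 1))
                    in_bout = False
    if in_bout:  # day boundary truncates an open bout
        intervals.append((start, last_present + 1))
    return intervals


def _runs(presence: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start, length), via run-length grouping."""
    runs = []
    pos = 0
    for value, group in itertools.groupby(presence):
        n = sum(1 for _ in group)
        if value:
            runs.append((pos, n))
        pos += n
    return runs


def _oracle_intervals(
    presence: Sequence[int], onset_min_s: int, termination_gap_s: int
) -> list[tuple[int, int]]:
    """Offline run/block construction, independent of the online scan."""
    runs = _runs(presence)
    intervals: list[tuple[int, int]] = []
    block: list[tuple[int, int]] = []

    def flush(block: list[tuple[int, int]]) -> None:
        for start, length in block:
            if length >= onset_min_s:
                block_end = block[-1][0] + block[-1][1]
                intervals.append((start, block_end))
                return  # a block yields at most one bout

    for run in runs:
        if block and run[0] - (block[-1][0] + block[-1][1]) >= termination_gap_s:
            flush(block)
            block = []
        block.append(run)
    if block:
        flush(block)
    return intervals


def find_bouts(
    series: PresenceSeries, criteria: BoutCriteria | None = None
) -> list[Bout]:
    """Segment a presence series into bouts (online hysteresis scan).

    Returns bouts sorted by start, pairwise disjoint, each satisfying
    the onset criterion and separated from its neighbours by at least
    the termination gap.
    """
    criteria = criteria or BoutCriteria.default()
    onset = criteria.onset_min_s[series.class_label]
    intervals = _scan_intervals(
        series.presence.tolist(), onset, criteria.termination_gap_s
    )
    return [
        Bout(series.class_label, series.date, start, end) for start, end in intervals
    ]


def find_bouts_oracle(
    series: PresenceSeries, criteria: BoutCriteria | None = None
) -> list[Bout]:
    """Reference implementation of :func:`find_bouts` via run merging.

    Maximal presence runs separated by gaps shorter than the termination
    gap are merged into blocks; a block produces one bout starting at
    its earliest run that meets the onset threshold and ending one past
    the block's last present second; blocks with no qualifying run are
    dropped.
    """
    criteria = criteria or BoutCriteria.default()
    onset = criteria.onset_min_s[series.class_label]
    intervals = _oracle_intervals(
        series.presence.tolist(), onset, criteria.termination_gap_s
    )
    return [
        Bout(series.class_label, series.date, start, end) for start, end in intervals
    ]


# ---------------------------------------------------------------------------
# Bout table I/O: CSV `class,date,start_s,end_s,duration_s`

def bouts_to_frame(bouts: Iterable[Bout]) -> pd.DataFrame:
    rows = [
        {
            "class": b.class_label.value,
            "date": b.date.isoformat(),
            "start_s": b.start_s,
            "end_s": b.end_s,
            "duration_s": b.duration_s,
        }
        for b in bouts
    ]
    frame = pd.DataFrame(rows, columns=["class", "date", "start_s", "end_s", "duration_s"])
    return frame.sort_values(["date", "class", "start_s"], ignore_index=True)


def write_bout_csv(bouts: Iterable[Bout], path: str | Path) -> None:
    bouts_to_frame(bouts).to_csv(path, index=False)


def read_bout_csv(path: str | Path) -> list[Bout]:
    frame = pd.read_csv(
        path, dtype={"class": str, "date": str, "start_s": int, "end_s": int}
    )
    return [
        Bout(
            BehaviorClass(row["class"]),
            dt.date.fromisoformat(row["date"]),
            int(row["start_s"]),
            int(row["end_s"]),
        )
        for _, row in frame.iterrows()
    ]
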