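"""Reading, writing, filtering and rasterising per-frame detection streams.

An overhead camera samples each pen at 1 frame per second and a detector
emits, for every frame, zero or more class-labelled detections of
agonistic behavior (aggression, ear biting, tail biting).  The log is a
CSV with one row per detection::

    channel,date,timestamp_s,class,confidence[,x_min,y_min,x_max,y_max]

``channel`` identifies the house (10 = enriched/treatment, 11 =
control), ``date`` is ISO-8601, ``timestamp_s`` is the integer
second-of-day of the frame, and ``confidence`` is the detector score in
[0, 1].  Bounding-box columns are optional because the production log
stores only per-class presence.

Downstream bout segmentation works on a per-second *binary* presence
series per behavior class and day, so this module collapses detection
multiplicities: a class is present in a second iff at least one
detection of that class survives the confidence filter in that second.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BehaviorClass",
    "BoundingBox",
    "DetectionRecord",
    "PresenceSeries",
    "DetectionParseError",
    "read_detection_csv",
    "write_detection_csv",
    "filter_by_confidence",
    "to_presence_series",
    "SECONDS_PER_DAY",
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "TREATMENT_CHANNEL",
    "CONTROL_CHANNEL",
]

SECONDS_PER_DAY = 86400

#: Detector operating point used when converting raw detections to presence.
DEFAULT_CONFIDENCE_THRESHOLD = 0.45

TREATMENT_CHANNEL = 10
CONTROL_CHANNEL = 11


class BehaviorClass(str, enum.Enum):
    """The three agonistic behavior classes of the ethogram.

    Aggression covers head/body knocking, chasing and mounting; ear and
    tail biting cover sucking, biting and chewing directed at the
    respective body part of a pen mate.
    """

    AGGRESSIVE = "aggressive"
    EAR_BITING = "ear_biting"
    TAIL_BITING = "tail_biting"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, slots=True)
class BoundingBox:
    """Axis-aligned pixel box, origin top-left, corners (min, max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "x_max", "y_max"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"box coordinates must be >= 0, got {self}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"box must have positive extent, got {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True, slots=True)
class DetectionRecord:
    """One detection of one behavior class in one 1-fps frame."""

    channel: int
    date: dt.date
    timestamp_s: int
    class_label: BehaviorClass
    confidence: float
    box: BoundingBox | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.timestamp_s < SECONDS_PER_DAY:
            raise ValueError(
                f"timestamp_s must be in [0, {SECONDS_PER_DAY - 1}], got {self.timestamp_s}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PresenceSeries:
    """Binary per-second presence of one behavior class over one day.

    ``presence[t] == 1`` iff the class was detected in the frame sampled
    at second ``t`` of the day.  Length is exactly 86 400 (24 h at 1 Hz).
    """

    date: dt.date
    class_label: BehaviorClass
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.presence, dtype=np.uint8)
        if arr.shape != (SECONDS_PER_DAY,):
            raise ValueError(
                f"presence must have shape ({SECONDS_PER_DAY},), got {arr.shape}"
            )
        if arr.max(initial=0) > 1:
            raise ValueError("presence values must be binary")
        arr.setflags(write=False)
        object.__setattr__(self, "presence", arr)

    @property
    def total_present_s(self) -> int:
        return int(self.presence.sum())


class DetectionParseError(ValueError):
    """A detection CSV row could not be parsed; the message names the line."""


_HEADER = ["channel", "date", "timestamp_s", "class", "confidence"]
_BOX_HEADER = ["x_min", "y_min", "x_max", "y_max"]

_SORT_KEY = lambda r: (r.date, r.timestamp_s, r.class_label.value)  # noqa: E731


def read_detection_csv(path: str | Path) -> list[DetectionRecord]:
    """Read a detection stream, returning records sorted by (date, timestamp).

    Raises
    ------
    DetectionParseError
        On a malformed header or row; the message includes the 1-based
        line number of the offending row.
    """
    path = Path(path)
    records: list[DetectionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DetectionParseError(f"{path}: empty file, expected a header")
        has_boxes = [h.strip() for h in header] == _HEADER + _BOX_HEADER
        if not has_boxes and [h.strip() for h in header] != _HEADER:
            raise DetectionParseError(
                f"{path}: line 1: unrecognised header {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                records.append(_parse_row(row, has_boxes))
            except (ValueError, IndexError) as exc:
                raise DetectionParseError(f"{path}: line {lineno}: {exc}") from exc
    records.sort(key=_SORT_KEY)
    return records


def _parse_row(row: Sequence[str], has_boxes: bool) -> DetectionRecord:
    channel = int(row[0])
    date = dt.date.fromisoformat(row[1].strip())
    timestamp_s = int(row[2])
    try:
        class_label = BehaviorClass(row[3].strip())
    except ValueError:
        raise ValueError(
            f"unknown class label {row[3]!r}; expected one of "
            f"{[c.value for c in BehaviorClass]}"
        )
    confidence = float(row[4])
    box = None
    if has_boxes and len(row) > 5 and any(cell.strip() for cell in row[5:9]):
        box = BoundingBox(*(float(c) for c in row[5:9]))
    return DetectionRecord(channel, date, timestamp_s, class_label, confidence, box)


def write_detection_csv(
    records: Iterable[DetectionRecord], path: str | Path
) -> None:
    """Write records in the standard dialect, sorted by (date, timestamp).

    The output round-trips: ``read_detection_csv(path)`` returns records
    equal to the (sorted) input.  Box columns are emitted only when at
    least one record carries a box.
    """
    records = sorted(records, key=_SORT_KEY)
    has_boxes = any(r.box is not None for r in records)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER + _BOX_HEADER if has_boxes else _HEADER)
        for r in records:
            row = [
                r.channel,
                r.date.isoformat(),
                r.timestamp_s,
                r.class_label.value,
                repr(r.confidence),
            ]
            if has_boxes:
                if r.box is None:
                    row += ["", "", "", ""]
                else:
                    row += [
                        repr(r.box.x_min),
                        repr(r.box.y_min),
                        repr(r.box.x_max),
                        repr(r.box.y_max),
                    ]
            writer.writerow(row)


def filter_by_confidence(
    records: Sequence[DetectionRecord], tau: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> list[DetectionRecord]:
    """Keep records with confidence >= ``tau`` (inclusive), order preserved."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return [r for r in records if r.confidence >= tau]


def to_presence_series(
    records: Iterable[DetectionRecord],
    date: dt.date,
    class_label: BehaviorClass,
) -> PresenceSeries:
    """Rasterise detections of one class on one day to 1-Hz binary presence.

    Records of other dates or classes are ignored; multiple detections
    in the same second collapse to a single presence.  Records are
    expected to be confidence-filtered already (see
    :func:`filter_by_confidence`).
    """
    presence = np.zeros(SECONDS_PER_DAY, dtype=np.uint8)
    idx = [
        r.timestamp_s
        for r in records
        if r.date == date and r.class_label is class_label
    ]
    if idx:
        presence[idx] = 1
    return PresenceSeries(date=date, class_label=class_label, presence=presence)
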