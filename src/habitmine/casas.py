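"""Reading, labelling and writing CASAS-dialect ambient sensor logs.

A CASAS log is a whitespace-delimited text file with one sensor event per
line::

    2010-11-04 00:03:50.209589 M003 ON Sleeping begin
    2010-11-04 00:03:57.399391 M003 OFF

The first four fields (date, time, sensor id, value) are mandatory; the
optional trailing fields annotate the start or end of an activity episode.
Both the spaced form ``Sleeping begin`` and the fused form ``Sleeping=begin``
occur in the wild and both are accepted.

This module is the single I/O boundary of the pipeline: everything
downstream consumes the ``(SensorEvent, ActivityAnnotation | None)`` records
it produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: Reserved label for events outside every annotated activity interval.
OTHER_LABEL = "Other"

BEGIN = "begin"
END = "end"

_TS_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")


@dataclass(frozen=True, slots=True)
class SensorEvent:
    """One timestamped sensor reading: (timestamp, sensor id, value)."""

    timestamp: datetime
    sensor_id: str
    value: str

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")
        if not self.value:
            raise ValueError("value must be non-empty")


@dataclass(frozen=True, slots=True)
class ActivityAnnotation:
    """Marks a sensor event as the start or end of an activity episode."""

    activity: str
    boundary: str  # BEGIN or END

    def __post_init__(self) -> None:
        if self.boundary not in (BEGIN, END):
            raise ValueError(f"boundary must be '{BEGIN}' or '{END}', got {self.boundary!r}")


#: One parsed log line.
Record = tuple[SensorEvent, Optional[ActivityAnnotation]]


@dataclass
class EventLog:
    """Result of parsing a CASAS log file."""

    records: list[Record] = field(default_factory=list)
    skipped: int = 0          # malformed lines that were dropped
    reordered: bool = False   # True if a timestamp sort changed the order

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def events(self) -> list[SensorEvent]:
        return [ev for ev, _ in self.records]


def _parse_timestamp(date_s: str, time_s: str) -> datetime:
    text = f"{date_s} {time_s}"
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp {text!r}")


def _parse_annotation(tail: list[str]) -> Optional[ActivityAnnotation]:
    """Normalise the trailing annotation fields of a log line.

    Accepts ``["Sleeping", "begin"]`` and the fused ``["Sleeping=begin"]``.
    Activity names containing spaces (rare, but present in some dumps) are
    re-joined. Returns None for an unrecognised tail.
    """
    if not tail:
        return None
    if len(tail) == 1 and "=" in tail[0]:
        activity, _, boundary = tail[0].partition("=")
    else:
        activity, boundary = " ".join(tail[:-1]), tail[-1]
    boundary = boundary.lower()
    if boundary not in (BEGIN, END) or not activity:
        return None
    return ActivityAnnotation(activity, boundary)


def parse_line(line: str) -> Optional[Record]:
    """Parse a single log line; raises ValueError on malformed input."""
    fields = line.split()
    if len(fields) < 4:
        raise ValueError(f"expected >=4 fields, got {len(fields)}")
    ts = _parse_timestamp(fields[0], fields[1])
    event = SensorEvent(ts, fields[2], fields[3])
    annotation = _parse_annotation(fields[4:])
    return event, annotation


def read_events(path: str | Path, *, sort: bool = True) -> EventLog:
    """Read a CASAS-dialect log file.

    Blank lines and ``#`` comment lines are ignored. Malformed lines are
    skipped with a warning and counted in :attr:`EventLog.skipped`. When
    ``sort`` is true (default), records are stable-sorted by timestamp and
    :attr:`EventLog.reordered` reports whether the file was out of order.

    Raises OSError if the file cannot be read.
    """
    path = Path(path)
    log = EventLog()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                log.records.append(parse_line(line))
            except ValueError as exc:
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
                log.skipped += 1
    if sort:
        ordered = sorted(log.records, key=lambda r: r[0].timestamp)
        if [r[0].timestamp for r in ordered] != [r[0].timestamp for r in log.records]:
            log.reordered = True
            logger.warning("%s: events were out of order; stable-sorted by timestamp", path)
        log.records = ordered
    return log


def write_events(records: Iterable[Record], path: str | Path, *, header: str | None = None) -> None:
    """Write records as a CASAS-dialect log (microsecond timestamps).

    Round-trips with :func:`read_events` field-for-field.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for event, annotation in records:
            line = (
                f"{event.timestamp:%Y-%m-%d %H:%M:%S.%f} "
                f"{event.sensor_id} {event.value}"
            )
            if annotation is not None:
                line += f" {annotation.activity} {annotation.boundary}"
            fh.write(line + "\n")


def label_events(records: Iterable[Record]) -> list[tuple[SensorEvent, str]]:
    """Assign an activity label to every event.

    Every event between an activity's ``begin`` and its matching ``end``
    (both inclusive) carries that activity; events outside all intervals
    carry :data:`OTHER_LABEL`. When intervals overlap, the innermost (most
    recently begun) interval wins. An ``end`` without a matching ``begin``
    is ignored with a warning; a ``begin`` left open at end-of-stream is
    auto-closed at the last event with a warning.
    """
    labelled: list[tuple[SensorEvent, str]] = []
    open_stack: list[str] = []  # innermost last
    for event, annotation in records:
        if annotation is not None and annotation.boundary == BEGIN:
            open_stack.append(annotation.activity)
        label = open_stack[-1] if open_stack else OTHER_LABEL
        labelled.append((event, label))
        if annotation is not None and annotation.boundary == END:
            # close the most recently begun matching interval
            for i in range(len(open_stack) - 1, -1, -1):
                if open_stack[i] == annotation.activity:
                    del open_stack[i]
                    break
            else:
                logger.warning(
                    "end annotation for %r at %s has no matching begin; ignored",
                    annotation.activity, event.timestamp,
                )
    if open_stack:
        logger.warning(
            "unclosed activity interval(s) at end of stream: %s (auto-closed at last event)",
            ", ".join(open_stack),
        )
    return labelled
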