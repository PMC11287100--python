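"""Event-level activity records from a thigh-worn accelerometer.

A recording is an ordered, gap-free sequence of posture/stepping events
per subject, in the style of activPAL event exports.  Five activity labels
are legal:

* ``primary_lying`` — time in bed; never counted as sedentary time,
* ``sedentary``    — secondary lying, i.e. awake sitting or lying,
* ``standing``,
* ``stepping``     — carries a total (both-feet) step count,
* ``nonwear``      — monitor off the body.

The on-disk dialect is UTF-8 CSV with header
``subject_id,start,duration_s,activity,steps``; ``start`` is ISO 8601
``YYYY-MM-DDTHH:MM:SS`` at second precision.  Nonwear and primary lying are
explicit labels rather than inferred from gaps so that a series round-trips
losslessly and wear/sedentary definitions stay testable.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

ACTIVITY_LABELS: tuple[str, ...] = (
    "primary_lying",
    "sedentary",
    "standing",
    "stepping",
    "nonwear",
)
UPRIGHT_LABELS = frozenset({"standing", "stepping"})

EVENTS_HEADER = ["subject_id", "start", "duration_s", "activity", "steps"]
TIMESTAMP_FMT = "%Y-%m-%dT%H:%M:%S"

#: tolerance, in seconds, for the end-of-event == start-of-next check
CONTIGUITY_TOL_S = 1e-6


class EventParseError(ValueError):
    """A CSV row could not be parsed (arity, timestamp, or number)."""


class VocabularyError(ValueError):
    """An activity label outside the five-label vocabulary."""


class ContiguityError(ValueError):
    """Consecutive events of one subject overlap or leave a gap."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EventRecord:
    """One contiguous interval of a single activity."""

    subject_id: str
    start: datetime
    duration_s: float
    activity: str
    steps: int = 0

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)

    def validate(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise VocabularyError(
                f"unknown activity label {self.activity!r}; "
                f"expected one of {ACTIVITY_LABELS}"
            )
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.steps < 0:
            raise ValueError(f"steps must be non-negative, got {self.steps}")
        if self.activity != "stepping" and self.steps != 0:
            raise ValueError(
                f"steps must be 0 for activity {self.activity!r}, got {self.steps}"
            )
        if self.activity == "stepping" and self.steps < 2:
            raise ValueError(
                f"a stepping event contains at least one stride (2 steps), "
                f"got {self.steps}"
            )


@dataclass
class EventSeries:
    """The full recording of one subject: events tile time with no gaps."""

    subject_id: str
    events: list[EventRecord] = field(default_factory=list)

    def validate(self) -> None:
        for ev in self.events:
            if ev.subject_id != self.subject_id:
                raise ValueError(
                    f"event subject_id {ev.subject_id!r} does not match "
                    f"series {self.subject_id!r}"
                )
            ev.validate()
        for prev, cur in zip(self.events, self.events[1:]):
            gap = (cur.start - prev.end).total_seconds()
            if abs(gap) > CONTIGUITY_TOL_S:
                kind = "gap" if gap > 0 else "overlap"
                raise ContiguityError(
                    f"subject {self.subject_id!r}: {kind} of {abs(gap):.6f} s "
                    f"between event ending {prev.end.isoformat()} and event "
                    f"starting {cur.start.isoformat()}"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(ev.duration_s for ev in self.events)

    @property
    def total_steps(self) -> int:
        return sum(ev.steps for ev in self.events)


@dataclass
class DayPartition:
    """Events of one series clipped to a single calendar day.

    Clipped stepping pieces carry steps prorated by clipped duration
    fraction (rounded half-up), so a piece may hold fewer than 2 steps;
    per-record step minima apply to raw series, not to clipped pieces.
    """

    date: date
    events: list[EventRecord]

    @property
    def total_s(self) -> float:
        return sum(ev.duration_s for ev in self.events)


def read_event_series(path: str | Path) -> list[EventSeries]:
    """Read the events CSV dialect into one validated series per subject.

    Rows are grouped by subject and sorted by start time.  Raises
    :class:`EventParseError` (with the 1-based line number),
    :class:`VocabularyError`, or :class:`ContiguityError`.
    """
    path = Path(path)
    per_subject: dict[str, list[EventRecord]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != EVENTS_HEADER:
            raise EventParseError(
                f"{path}: bad header {header!r}; expected {EVENTS_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise EventParseError(
                    f"{path}:{lineno}: expected 5 fields, got {len(row)}"
                )
            sid, start_s, dur_s, activity, steps_s = row
            try:
                start = datetime.strptime(start_s, TIMESTAMP_FMT)
            except ValueError as exc:
                raise EventParseError(
                    f"{path}:{lineno}: bad timestamp {start_s!r}: {exc}"
                ) from None
            try:
                duration = float(dur_s)
                steps = int(steps_s)
            except ValueError as exc:
                raise EventParseError(f"{path}:{lineno}: bad number: {exc}") from None
            if activity not in ACTIVITY_LABELS:
                raise VocabularyError(
                    f"{path}:{lineno}: unknown activity label {activity!r}"
                )
            ev = EventRecord(sid, start, duration, activity, steps)
            try:
                ev.validate()
            except ValueError as exc:
                raise EventParseError(f"{path}:{lineno}: {exc}") from None
            per_subject.setdefault(sid, []).append(ev)

    out = []
    for sid, events in per_subject.items():
        events.sort(key=lambda ev: ev.start)
        series = EventSeries(sid, events)
        series.validate()
        out.append(series)
    return out


def write_event_series(series: list[EventSeries] | EventSeries, path: str | Path) -> None:
    """Write series to the events CSV dialect; exact inverse of reading.

    Timestamps are serialized at second precision, so event starts must
    fall on whole seconds (sub-second starts would corrupt contiguity on
    re-read and are rejected).
    """
    if isinstance(series, EventSeries):
        series = [series]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENTS_HEADER)
        for s in series:
            for ev in s.events:
                if ev.start.microsecond != 0:
                    raise ValueError(
                        f"subject {s.subject_id!r}: event start {ev.start!r} has "
                        "sub-second precision; the dialect stores whole seconds"
                    )
                writer.writerow(
                    [
                        ev.subject_id,
                        ev.start.strftime(TIMESTAMP_FMT),
                        repr(float(ev.duration_s)),
                        ev.activity,
                        ev.steps,
                    ]
                )


def _split_event_at_midnights(ev: EventRecord) -> list[EventRecord]:
    spans: list[tuple[datetime, float]] = []
    t, remaining = ev.start, float(ev.duration_s)
    while True:
        next_midnight = datetime.combine(t.date() + timedelta(days=1), time.min)
        span = (next_midnight - t).total_seconds()
        if remaining <= span + CONTIGUITY_TOL_S:
            spans.append((t, remaining))
            break
        spans.append((t, span))
        remaining -= span
        t = next_midnight
    if len(spans) == 1:
        return [ev]
    pieces = []
    for t, dur in spans:
        steps = (
            _round_half_up(ev.steps * dur / ev.duration_s)
            if ev.activity == "stepping"
            else 0
        )
        pieces.append(dataclasses.replace(ev, start=t, duration_s=dur, steps=steps))
    return pieces


def partition_days(series: EventSeries) -> list[DayPartition]:
    """Clip a series to calendar days (local wall-clock midnights).

    Durations are conserved exactly; steps of stepping events crossing
    midnight are prorated by clipped duration and rounded half-up, which
    conserves the series total to within one step per midnight crossing.
    """
    buckets: dict[date, list[EventRecord]] = {}
    for ev in series.events:
        for piece in _split_event_at_midnights(ev):
            buckets.setdefault(piece.start.date(), []).append(piece)
    return [DayPartition(day, evs) for day, evs in sorted(buckets.items())]
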