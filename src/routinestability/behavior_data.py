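"""Domain records and minute-level binning for passively sensed behavior.

A behavior stream is a sequence of timestamped events: instantaneous ones
(a message, an ambient sensor reading) carry an explicit magnitude, while
period events (a call, a still period) contribute one unit per covered
minute of local clock time.  Binning turns a stream into per-day activity
vectors of length 1440 — the ``A_b^d(x)`` amounts that the stability
metrics consume.

Minute indexing is 1-based in the mathematical notation (minute ``x``
covers ``[x-1, x)`` minutes after local midnight); arrays returned here are
0-based, so ``amounts[x-1]`` is minute ``x``.  Days are local calendar
days; periods crossing midnight are split across the two days.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .behaviors import BEHAVIORS, MINUTES_PER_DAY

logger = logging.getLogger(__name__)

_BEHAVIOR_SET = frozenset(BEHAVIORS)


class ValidationError(ValueError):
    """Raised for malformed records; carries per-row diagnostics."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


@dataclass(frozen=True)
class BehaviorEvent:
    """One sensed occurrence: instantaneous if ``end == start``, else a period."""

    participant_id: str
    behavior: str
    start: datetime
    end: datetime
    magnitude: float

    def __post_init__(self) -> None:
        if self.behavior not in _BEHAVIOR_SET:
            raise ValidationError(f"unknown behavior {self.behavior!r}")
        if self.end < self.start:
            raise ValidationError(f"event end {self.end} precedes start {self.start}")
        if not math.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValidationError(f"negative or non-finite magnitude {self.magnitude}")

    @property
    def instantaneous(self) -> bool:
        return self.end == self.start


@dataclass(frozen=True)
class CoverageRecord:
    """Hours of sensing coverage for one participant-day."""

    participant_id: str
    date: date
    sensed_hours: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensed_hours <= 24.0:
            raise ValidationError(
                f"sensed_hours {self.sensed_hours} outside [0, 24] "
                f"for {self.participant_id} on {self.date}"
            )


@dataclass(frozen=True)
class EmaResponse:
    """A 10-item momentary self-report (items scored 0-3).

    Items 1-5 are negative symptoms, items 6-10 positive ones; the composite
    is the negative sum minus the positive sum and ranges over [-15, 15],
    higher meaning greater symptom severity.
    """

    participant_id: str
    date: date
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValidationError(f"expected 10 EMA items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if v not in (0, 1, 2, 3):
                raise ValidationError(f"EMA item {i} value {v!r} outside 0..3")

    @property
    def composite(self) -> int:
        return int(sum(self.items[:5]) - sum(self.items[5:]))


@dataclass
class DayActivityVector:
    """Minute-by-minute activity amounts for one (participant, behavior, day).

    Length is 1440 for real days; shorter toy lengths are permitted so that
    exhaustive oracle checks can run on tiny instances.
    """

    participant_id: str
    behavior: str
    date: date
    amounts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.amounts.ndim != 1 or len(self.amounts) < 1:
            raise ValidationError(
                f"day vector must be a non-empty 1-d array, got shape {self.amounts.shape}"
            )
        if np.any(~np.isfinite(self.amounts)) or np.any(self.amounts < 0):
            raise ValidationError("day vector amounts must be finite and non-negative")

    @property
    def total(self) -> float:
        return float(self.amounts.sum())


def _rasterize_interval(amounts: np.ndarray, start_min: float, end_min: float) -> None:
    """Add one unit per minute over [start_min, end_min) with fractional ends."""
    if end_min <= start_min:
        return
    i0 = int(math.floor(start_min))
    i1 = int(math.ceil(end_min))
    if i1 - i0 == 1:
        amounts[i0] += end_min - start_min
        return
    amounts[i0] += (i0 + 1) - start_min
    amounts[i0 + 1 : i1 - 1] += 1.0
    amounts[i1 - 1] += end_min - (i1 - 1)


def bin_events_by_day(events: Iterable[BehaviorEvent]) -> dict[date, np.ndarray]:
    """Rasterize a homogeneous event stream into per-day amount vectors.

    Instantaneous events add their magnitude to the minute containing the
    timestamp; periods contribute one unit per fully covered minute and a
    proportional fraction at the boundaries, split across calendar days when
    they cross midnight.
    """
    by_day: dict[date, np.ndarray] = {}

    def vec(d: date) -> np.ndarray:
        if d not in by_day:
            by_day[d] = np.zeros(MINUTES_PER_DAY)
        return by_day[d]

    for ev in events:
        if ev.instantaneous:
            d = ev.start.date()
            midnight = datetime.combine(d, time())
            minute = int((ev.start - midnight).total_seconds() // 60)
            vec(d)[minute] += ev.magnitude
            continue
        d = ev.start.date()
        while d <= ev.end.date():
            day_start = datetime.combine(d, time())
            day_end = day_start + timedelta(days=1)
            s = max(ev.start, day_start)
            e = min(ev.end, day_end)
            if e > s:
                s_min = (s - day_start).total_seconds() / 60.0
                e_min = (e - day_start).total_seconds() / 60.0
                _rasterize_interval(vec(d), s_min, min(e_min, float(MINUTES_PER_DAY)))
            d = d + timedelta(days=1)
    return by_day


def bin_events_to_day_vectors(
    events: Iterable[BehaviorEvent],
    participant_id: str,
    behavior: str,
    day: date,
) -> DayActivityVector:
    """Bin the events of one participant/behavior that touch ``day``.

    Events for other participants or behaviors are rejected rather than
    silently dropped, since passing them is almost certainly a caller bug.
    """
    events = list(events)
    for ev in events:
        if ev.participant_id != participant_id or ev.behavior != behavior:
            raise ValidationError(
                f"event for ({ev.participant_id}, {ev.behavior}) passed to binning of "
                f"({participant_id}, {behavior})"
            )
    by_day = bin_events_by_day(events)
    amounts = by_day.get(day, np.zeros(MINUTES_PER_DAY))
    return DayActivityVector(participant_id, behavior, day, amounts)


# ---------------------------------------------------------------------------
# CSV I/O.  Schemas:
#   streams.csv:  participant_id,behavior,start,end,magnitude  (ISO-8601 local)
#   coverage.csv: participant_id,date,sensed_hours
#   ema.csv:      participant_id,date,item1..item10
# ---------------------------------------------------------------------------

STREAM_COLUMNS = ["participant_id", "behavior", "start", "end", "magnitude"]
COVERAGE_COLUMNS = ["participant_id", "date", "sensed_hours"]
EMA_COLUMNS = ["participant_id", "date"] + [f"item{i}" for i in range(1, 11)]


def _check_header(header: Sequence[str] | None, required: Sequence[str], path: Path) -> None:
    if header is None:
        raise ValidationError(f"{path}: empty file, expected header {required}")
    missing = [c for c in required if c not in header]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _read_rows(path: str | Path, required: Sequence[str]):
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, required, path)
        # line 1 is the header, so data rows start at line 2
        yield from ((lineno, row) for lineno, row in enumerate(reader, start=2))


def read_streams(path: str | Path) -> list[BehaviorEvent]:
    events: list[BehaviorEvent] = []
    errors: list[str] = []
    for lineno, row in _read_rows(path, STREAM_COLUMNS):
        try:
            events.append(
                BehaviorEvent(
                    participant_id=row["participant_id"],
                    behavior=row["behavior"],
                    start=datetime.fromisoformat(row["start"]),
                    end=datetime.fromisoformat(row["end"]),
                    magnitude=float(row["magnitude"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s)", errors)
    logger.info("read %d events from %s", len(events), path)
    return events


def write_streams(events: Iterable[BehaviorEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(STREAM_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    ev.participant_id,
                    ev.behavior,
                    ev.start.isoformat(),
                    ev.end.isoformat(),
                    repr(float(ev.magnitude)),
                ]
            )


def read_coverage(path: str | Path) -> list[CoverageRecord]:
    records: list[CoverageRecord] = []
    errors: list[str] = []
    for lineno, row in _read_rows(path, COVERAGE_COLUMNS):
        try:
            records.append(
                CoverageRecord(
                    participant_id=row["participant_id"],
                    date=date.fromisoformat(row["date"]),
                    sensed_hours=float(row["sensed_hours"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s)", errors)
    return records


def write_coverage(records: Iterable[CoverageRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COVERAGE_COLUMNS)
        for rec in records:
            writer.writerow([rec.participant_id, rec.date.isoformat(), repr(float(rec.sensed_hours))])


def read_ema(path: str | Path) -> list[EmaResponse]:
    responses: list[EmaResponse] = []
    errors: list[str] = []
    for lineno, row in _read_rows(path, EMA_COLUMNS):
        try:
            items = tuple(int(row[f"item{i}"]) for i in range(1, 11))
            responses.append(
                EmaResponse(
                    participant_id=row["participant_id"],
                    date=date.fromisoformat(row["date"]),
                    items=items,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s)", errors)
    return responses


def write_ema(responses: Iterable[EmaResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EMA_COLUMNS)
        for r in responses:
            writer.writerow([r.participant_id, r.date.isoformat(), *r.items])
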