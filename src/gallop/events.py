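"""Domain model and CSV I/O for horses, exercise events, and fracture cases.

An exercise history is a dated sequence of high-speed events — races and
official timed works — each with a distance in furlongs.  Careers are
truncated at an *index date* (the fracture date for cases, the matched
event's date for controls) before any workload variable is computed.

CSV schemas (comma-separated, header required, ISO-8601 dates):

* ``events.csv``  — horse_id, date, event_type (race|work), distance,
  finish_top3 (races only, optional), earnings (races only, optional)
* ``horses.csv``  — horse_id, sex (female|male|unknown), birth_date
* ``cases.csv``   — horse_id, fracture_date, location (PSG|nonPSG),
  sublocation (axial|central|abaxial, non-PSG only), limb (left|right),
  end (forelimb|hindlimb), condyle (lateral|medial), repair_date (optional)
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from gallop.config import AnalysisConfig, DEFAULT_CONFIG

EVENT_TYPES = ("race", "work")
SEXES = ("female", "male", "unknown")
LOCATIONS = ("PSG", "nonPSG")
SUBLOCATIONS = ("axial", "central", "abaxial")
LIMBS = ("left", "right")
ENDS = ("forelimb", "hindlimb")
CONDYLES = ("lateral", "medial")

EVENT_COLUMNS = ["horse_id", "date", "event_type", "distance", "finish_top3", "earnings"]
HORSE_COLUMNS = ["horse_id", "sex", "birth_date"]
CASE_COLUMNS = [
    "horse_id",
    "fracture_date",
    "location",
    "sublocation",
    "limb",
    "end",
    "condyle",
    "repair_date",
]


class ValidationError(ValueError):
    """Raised when an input file or record violates the domain contract."""


@dataclass(frozen=True)
class EventRecord:
    """One dated race or official timed work.

    ``finish_top3`` and ``earnings`` apply to races only; works never carry
    either.  Distance is in furlongs and must be positive.
    """

    horse_id: str
    date: dt.date
    event_type: str
    distance: float
    finish_top3: Optional[bool] = None
    earnings: Optional[float] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"unknown event_type {self.event_type!r} (expected one of {EVENT_TYPES})"
            )
        if not self.distance > 0:
            raise ValidationError(f"distance must be positive, got {self.distance!r}")
        if self.earnings is not None and self.earnings < 0:
            raise ValidationError(f"earnings must be non-negative, got {self.earnings!r}")
        if self.event_type == "work" and (
            self.finish_top3 is not None or self.earnings is not None
        ):
            raise ValidationError("finish_top3/earnings are race-only fields")

    @property
    def is_race(self) -> bool:
        return self.event_type == "race"


@dataclass(frozen=True)
class HorseRecord:
    """A horse and its full (untruncated) event history, sorted by date."""

    horse_id: str
    sex: str = "unknown"
    birth_date: Optional[dt.date] = None
    events: tuple[EventRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} (expected one of {SEXES})")
        dates = [e.date for e in self.events]
        if dates != sorted(dates):
            object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.date)))
        if self.birth_date is not None and self.events:
            first = self.events[0].date
            if first < self.birth_date:
                raise ValidationError(
                    f"horse {self.horse_id}: event on {first} precedes birth {self.birth_date}"
                )


@dataclass(frozen=True)
class CaseRecord:
    """A condylar-fracture case annotation for one horse."""

    horse_id: str
    fracture_date: dt.date
    location: str
    limb: str
    end: str
    condyle: str
    sublocation: Optional[str] = None
    repair_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown location {self.location!r}")
        if self.limb not in LIMBS:
            raise ValidationError(f"unknown limb {self.limb!r}")
        if self.end not in ENDS:
            raise ValidationError(f"unknown end {self.end!r}")
        if self.condyle not in CONDYLES:
            raise ValidationError(f"unknown condyle {self.condyle!r}")
        if self.sublocation is not None:
            if self.location != "nonPSG":
                raise ValidationError("sublocation applies to non-PSG fractures only")
            if self.sublocation not in SUBLOCATIONS:
                raise ValidationError(f"unknown sublocation {self.sublocation!r}")
        if self.repair_date is not None and self.repair_date < self.fracture_date:
            raise ValidationError("repair_date precedes fracture_date")


@dataclass(frozen=True)
class CareerTimeline:
    """A horse's event record truncated at an index date.

    The index date is the fracture date for cases and the matched event's
    date for controls.  An empty timeline (no event on or before the index)
    is permitted but flagged: downstream workload variables become missing.
    """

    horse_id: str
    index_date: dt.date
    events: tuple[EventRecord, ...] = ()

    def __post_init__(self) -> None:
        for e in self.events:
            if e.date > self.index_date:
                raise ValidationError(
                    f"timeline {self.horse_id}: event on {e.date} after index {self.index_date}"
                )
        dates = [e.date for e in self.events]
        if dates != sorted(dates):
            object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.date)))

    @property
    def is_empty(self) -> bool:
        return len(self.events) == 0

    @property
    def first_event_date(self) -> Optional[dt.date]:
        return self.events[0].date if self.events else None

    @property
    def last_event_date(self) -> Optional[dt.date]:
        return self.events[-1].date if self.events else None


def truncate_career(
    horse: HorseRecord,
    index_date: dt.date,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CareerTimeline:
    """Truncate a horse's event record at ``index_date``.

    Events dated exactly on the index date are retained by default
    (``config.include_index_day_event``); the fracture typically occurs
    during the final event.  The input record is not modified.
    """

    if horse.birth_date is not None and index_date < horse.birth_date:
        raise ValidationError(
            f"horse {horse.horse_id}: index {index_date} precedes birth {horse.birth_date}"
        )
    if config.include_index_day_event:
        kept = tuple(e for e in horse.events if e.date <= index_date)
    else:
        kept = tuple(e for e in horse.events if e.date < index_date)
    return CareerTimeline(horse_id=horse.horse_id, index_date=index_date, events=kept)


# ---------------------------------------------------------------------------
# CSV parsing helpers


def _parse_date(raw: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw.strip())
    except ValueError as exc:
        raise ValidationError(f"row {row}: malformed {column} {raw!r} (expected ISO-8601)") from exc


def _parse_optional_date(raw: str, row: int, column: str) -> Optional[dt.date]:
    raw = (raw or "").strip()
    return _parse_date(raw, row, column) if raw else None


def _parse_bool(raw: str, row: int, column: str) -> Optional[bool]:
    raw = (raw or "").strip().lower()
    if not raw:
        return None
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    raise ValidationError(f"row {row}: malformed {column} {raw!r}")


def _require_columns(fieldnames: Sequence[str] | None, required: Iterable[str], path) -> None:
    have = set(fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_events(
    path: str | Path,
    horses: Optional[Mapping[str, HorseRecord]] = None,
) -> dict[str, HorseRecord]:
    """Read an event CSV into one HorseRecord per horse_id, events sorted.

    If a roster from :func:`read_horses` is supplied, sex and birth date are
    attached; roster horses without events are preserved with empty event
    lists.  Row counts are conserved: every CSV row becomes exactly one
    event.  Malformed rows raise :class:`ValidationError` naming the row
    (1-based, excluding the header).
    """

    path = Path(path)
    per_horse: dict[str, list[EventRecord]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["horse_id", "date", "event_type", "distance"], path)
        for i, row in enumerate(reader, start=1):
            horse_id = (row["horse_id"] or "").strip()
            if not horse_id:
                raise ValidationError(f"row {i}: empty horse_id")
            date = _parse_date(row["date"], i, "date")
            event_type = (row["event_type"] or "").strip()
            try:
                distance = float(row["distance"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {i}: malformed distance {row['distance']!r}") from exc
            finish = _parse_bool(row.get("finish_top3", ""), i, "finish_top3")
            raw_earn = (row.get("earnings") or "").strip()
            earnings = None
            if raw_earn:
                try:
                    earnings = float(raw_earn)
                except ValueError as exc:
                    raise ValidationError(f"row {i}: malformed earnings {raw_earn!r}") from exc
            try:
                event = EventRecord(horse_id, date, event_type, distance, finish, earnings)
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            per_horse.setdefault(horse_id, []).append(event)

    out: dict[str, HorseRecord] = {}
    ids = set(per_horse)
    if horses:
        ids |= set(horses)
    for horse_id in sorted(ids):
        events = tuple(sorted(per_horse.get(horse_id, []), key=lambda e: e.date))
        base = horses.get(horse_id) if horses else None
        if base is not None:
            out[horse_id] = replace(base, events=events)
        else:
            out[horse_id] = HorseRecord(horse_id=horse_id, events=events)
    return out


def read_horses(path: str | Path) -> dict[str, HorseRecord]:
    """Read the horse roster CSV (no events attached)."""

    path = Path(path)
    out: dict[str, HorseRecord] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, HORSE_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            horse_id = (row["horse_id"] or "").strip()
            if not horse_id:
                raise ValidationError(f"row {i}: empty horse_id")
            if horse_id in out:
                raise ValidationError(f"row {i}: duplicate horse_id {horse_id!r}")
            try:
                out[horse_id] = HorseRecord(
                    horse_id=horse_id,
                    sex=(row["sex"] or "unknown").strip() or "unknown",
                    birth_date=_parse_optional_date(row["birth_date"], i, "birth_date"),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return out


def read_cases(path: str | Path) -> list[CaseRecord]:
    """Read the case roster CSV."""

    path = Path(path)
    out: list[CaseRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(
            reader.fieldnames,
            ["horse_id", "fracture_date", "location", "limb", "end", "condyle"],
            path,
        )
        for i, row in enumerate(reader, start=1):
            try:
                out.append(
                    CaseRecord(
                        horse_id=(row["horse_id"] or "").strip(),
                        fracture_date=_parse_date(row["fracture_date"], i, "fracture_date"),
                        location=(row["location"] or "").strip(),
                        sublocation=((row.get("sublocation") or "").strip() or None),
                        limb=(row["limb"] or "").strip(),
                        end=(row["end"] or "").strip(),
                        condyle=(row["condyle"] or "").strip(),
                        repair_date=_parse_optional_date(
                            row.get("repair_date", ""), i, "repair_date"
                        ),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip safe)


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_events(horses: Mapping[str, HorseRecord], path: str | Path) -> None:
    """Write all events of a HorseRecord collection; read_events round-trips."""

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for horse_id in sorted(horses):
            for e in horses[horse_id].events:
                writer.writerow(
                    [
                        e.horse_id,
                        e.date.isoformat(),
                        e.event_type,
                        _fmt_float(e.distance),
                        "" if e.finish_top3 is None else str(e.finish_top3).lower(),
                        _fmt_float(e.earnings),
                    ]
                )


def write_horses(horses: Mapping[str, HorseRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HORSE_COLUMNS)
        for horse_id in sorted(horses):
            h = horses[horse_id]
            writer.writerow(
                [h.horse_id, h.sex, "" if h.birth_date is None else h.birth_date.isoformat()]
            )


def write_cases(cases: Iterable[CaseRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CASE_COLUMNS)
        for c in cases:
            writer.writerow(
                [
                    c.horse_id,
                    c.fracture_date.isoformat(),
                    c.location,
                    c.sublocation or "",
                    c.limb,
                    c.end,
                    c.condyle,
                    "" if c.repair_date is None else c.repair_date.isoformat(),
                ]
            )


def validate_case_against_horse(case: CaseRecord, horse: HorseRecord) -> None:
    """Check cross-record invariants between a case and its horse."""

    if horse.events and case.fracture_date < horse.events[0].date:
        raise ValidationError(
            f"case {case.horse_id}: fracture {case.fracture_date} precedes first event "
            f"{horse.events[0].date}"
        )
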