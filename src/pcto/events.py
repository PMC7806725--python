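"""Canonical longitudinal event model: records, code maps, timelines, I/O.

Every downstream stage consumes the types defined here.  An event table is
a flat, date-ordered list of :class:`EventRecord`; :func:`build_timelines`
folds it into per-patient :class:`PatientTimeline` objects with medication
start/stop events resolved into half-open active intervals.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical CSV column order used by the reader and writer
CANONICAL_COLUMNS = [
    "patient_id",
    "event_date",
    "event_kind",
    "code",
    "value",
    "unit",
    "action",
]


class EventKind(str, Enum):
    ENCOUNTER = "encounter"
    MEASUREMENT = "measurement"
    MEDICATION = "medication"
    DIAGNOSIS = "diagnosis"


class MedAction(str, Enum):
    START = "start"
    STOP = "stop"


class SchemaError(ValueError):
    """A mandatory column is missing or the header cannot be mapped."""


class MappingError(ValueError):
    """Event codes not covered by the supplied CodeMap (strict mode)."""


@dataclass(frozen=True)
class EventRecord:
    """One dated clinical fact for one patient."""

    patient_id: str
    event_date: dt.date
    event_kind: EventKind
    code: str
    value: Optional[float] = None
    unit: Optional[str] = None
    action: Optional[MedAction] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not isinstance(self.event_date, dt.date):
            raise ValueError("event_date must be a datetime.date")
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.event_kind is EventKind.MEASUREMENT and self.value is None:
            raise ValueError("measurement records must carry a value")
        if self.event_kind is EventKind.MEDICATION and self.action is None:
            raise ValueError("medication records must carry an action")


@dataclass
class CodeMap:
    """Abstract vocabulary maps (stand-ins for RxNorm/LOINC/ICD lookups).

    ``medication_map`` maps an ingredient code to ``(class_label,
    ingredient_label)``; ``diagnosis_map`` maps a diagnosis code to a
    disease-category label; ``measurement_map`` maps a measurement code to
    ``(analyte_name, unit)``.
    """

    medication_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    diagnosis_map: dict[str, str] = field(default_factory=dict)
    measurement_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate_events(self, events: Sequence[EventRecord]) -> None:
        """Raise :class:`MappingError` listing every unmapped code."""
        missing: set[tuple[str, str]] = set()
        for ev in events:
            if ev.event_kind is EventKind.MEDICATION and ev.code not in self.medication_map:
                missing.add(("medication", ev.code))
            elif ev.event_kind is EventKind.DIAGNOSIS and ev.code not in self.diagnosis_map:
                missing.add(("diagnosis", ev.code))
            elif ev.event_kind is EventKind.MEASUREMENT and ev.code not in self.measurement_map:
                missing.add(("measurement", ev.code))
        if missing:
            listing = ", ".join(f"{k}:{c}" for k, c in sorted(missing))
            raise MappingError(f"codes missing from CodeMap: {listing}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "medication_map": {k: list(v) for k, v in self.medication_map.items()},
            "diagnosis_map": dict(self.diagnosis_map),
            "measurement_map": {k: list(v) for k, v in self.measurement_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            medication_map={k: tuple(v) for k, v in payload.get("medication_map", {}).items()},
            diagnosis_map=dict(payload.get("diagnosis_map", {})),
            measurement_map={k: tuple(v) for k, v in payload.get("measurement_map", {}).items()},
        )


@dataclass
class MedInterval:
    """Half-open active-medication interval [start, stop); stop None = open."""

    start: dt.date
    stop: Optional[dt.date] = None

    def covers(self, day: dt.date) -> bool:
        if day < self.start:
            return False
        return self.stop is None or day < self.stop


def _event_sort_key(ev: EventRecord) -> tuple:
    return (ev.event_date, ev.event_kind.value, ev.code)


@dataclass
class PatientTimeline:
    """Date-ordered events for one patient plus derived medication intervals."""

    patient_id: str
    events: list[EventRecord]
    intervals: dict[str, list[MedInterval]] = field(default_factory=dict)
    attributes: dict[str, object] = field(default_factory=dict)

    def active_ingredients(self, day: dt.date) -> set[str]:
        """Ingredient codes with an interval covering ``day``."""
        return {
            code
            for code, ivals in self.intervals.items()
            if any(iv.covers(day) for iv in ivals)
        }

    def events_of_kind(self, kind: EventKind) -> list[EventRecord]:
        return [ev for ev in self.events if ev.event_kind is kind]

    def measurements(self, analyte: str) -> list[EventRecord]:
        return [
            ev
            for ev in self.events
            if ev.event_kind is EventKind.MEASUREMENT and ev.code == analyte
        ]


@dataclass
class ReadReport:
    """Row accounting for :func:`read_events`."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)


_DEFAULT_DIALECT: dict[str, str] = {c: c for c in CANONICAL_COLUMNS}


def read_events(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    strict: bool = False,
    report: Optional[ReadReport] = None,
) -> list[EventRecord]:
    """Read an event table from a delimited file.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Mapping of canonical field name -> column name in the file.
        Defaults to the canonical schema.
    strict
        If True, any malformed row raises instead of being rejected.
    report
        Optional accounting object filled with row counts and rejection
        reasons.
    """
    dialect = dict(_DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = ["patient_id", "event_date", "event_kind", "code"]
    for fld in mandatory:
        if dialect[fld] not in df.columns:
            raise SchemaError(f"missing mandatory column {dialect[fld]!r} in {path}")

    if report is None:
        report = ReadReport()
    report.n_rows = len(df)

    records: list[EventRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            records.append(_parse_row(row_d, dialect))
        except (ValueError, KeyError) as exc:
            if strict:
                raise
            report.rejected.append((idx, str(exc)))
            logger.warning("rejected row %d of %s: %s", idx, path, exc)
    report.n_accepted = len(records)
    return records


def _parse_row(row: Mapping[str, str], dialect: Mapping[str, str]) -> EventRecord:
    def get(fld: str) -> str:
        col = dialect.get(fld, fld)
        return str(row.get(col, "") or "").strip()

    date_s = get("event_date")
    try:
        event_date = dt.date.fromisoformat(date_s)
    except ValueError as exc:
        raise ValueError(f"unparseable date {date_s!r}") from exc
    value_s = get("value")
    action_s = get("action")
    return EventRecord(
        patient_id=get("patient_id"),
        event_date=event_date,
        event_kind=EventKind(get("event_kind")),
        code=get("code"),
        value=float(value_s) if value_s else None,
        unit=get("unit") or None,
        action=MedAction(action_s) if action_s else None,
    )


def write_events(events: Iterable[EventRecord], path: str | Path) -> None:
    """Write events in the canonical schema (stable order and formatting)."""
    rows = []
    for ev in sorted(events, key=lambda e: (e.patient_id, *_event_sort_key(e))):
        rows.append(
            {
                "patient_id": ev.patient_id,
                "event_date": ev.event_date.isoformat(),
                "event_kind": ev.event_kind.value,
                "code": ev.code,
                "value": "" if ev.value is None else repr(float(ev.value)),
                "unit": ev.unit or "",
                "action": ev.action.value if ev.action else "",
            }
        )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df.to_csv(path, index=False)


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Tabular view of an event list (dates as datetime64)."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "event_date": pd.to_datetime([e.event_date for e in events]),
            "event_kind": [e.event_kind.value for e in events],
            "code": [e.code for e in events],
            "value": [e.value for e in events],
            "unit": [e.unit for e in events],
            "action": [e.action.value if e.action else None for e in events],
        }
    )


def build_timelines(
    events: Sequence[EventRecord],
    codes: Optional[CodeMap] = None,
    strict: bool = False,
    attributes: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> dict[str, PatientTimeline]:
    """Fold a validated event table into per-patient timelines.

    Medication start/stop events are paired in date order into half-open
    intervals; a stop with no open interval is logged and ignored, and a
    same-day start/stop (empty interval) is logged and dropped.  When
    ``codes`` is given and ``strict`` is set, unmapped codes raise
    :class:`MappingError`.

    ``attributes`` optionally maps patient_id -> static attributes
    (demographics) attached to each timeline.
    """
    if codes is not None and strict:
        codes.validate_events(events)

    by_patient: dict[str, list[EventRecord]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    timelines: dict[str, PatientTimeline] = {}
    for pid, evs in by_patient.items():
        evs_sorted = sorted(evs, key=_event_sort_key)
        intervals = _fold_intervals(pid, evs_sorted)
        timelines[pid] = PatientTimeline(
            patient_id=pid,
            events=evs_sorted,
            intervals=intervals,
            attributes=dict((attributes or {}).get(pid, {})),
        )
    return timelines


def _fold_intervals(pid: str, evs_sorted: Sequence[EventRecord]) -> dict[str, list[MedInterval]]:
    intervals: dict[str, list[MedInterval]] = {}
    open_starts: dict[str, dt.date] = {}
    for ev in evs_sorted:
        if ev.event_kind is not EventKind.MEDICATION:
            continue
        if ev.action is MedAction.START:
            if ev.code in open_starts:
                # repeated start while active: keep the earlier start
                logger.info("patient %s: duplicate start of %s on %s ignored", pid, ev.code, ev.event_date)
                continue
            open_starts[ev.code] = ev.event_date
        else:
            start = open_starts.pop(ev.code, None)
            if start is None:
                logger.info("patient %s: stop of %s on %s with no open interval ignored", pid, ev.code, ev.event_date)
                continue
            if start == ev.event_date:
                logger.info("patient %s: empty interval for %s on %s dropped", pid, ev.code, start)
                continue
            intervals.setdefault(ev.code, []).append(MedInterval(start, ev.event_date))
    for code, start in open_starts.items():
        intervals.setdefault(code, []).append(MedInterval(start, None))
    for ivals in intervals.values():
        ivals.sort(key=lambda iv: iv.start)
    return intervals
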