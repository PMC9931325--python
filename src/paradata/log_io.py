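"""Reading and writing the event-log and EMR file formats.

Event logs are JSON Lines, one UI event per line; EMR form submissions are
CSV.  All timestamps carry an explicit UTC offset and are serialized
ISO-8601.  MongoDB extended-JSON dates (``{"$date": ...}``) are accepted on
read, since event-log servers are commonly backed by MongoDB; plain ISO-8601
is always written.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "LOCAL_TZ",
    "GeoPoint",
    "EventLog",
    "EmrSubmission",
    "EventFlags",
    "EventCatalog",
    "DEFAULT_CATALOG",
    "LoadReport",
    "SchemaError",
    "read_event_logs",
    "write_event_logs",
    "read_emr_csv",
    "write_emr_csv",
    "write_tables",
    "load_catalog",
]

#: Study timezone. The cohort operates in a single timezone (East Africa
#: Time, UTC+03:00); all "local" dates and clock times are evaluated here.
LOCAL_TZ = timezone(timedelta(hours=3), "EAT")


class SchemaError(ValueError):
    """A record violates the event-log or EMR schema."""


def local_date(ts: datetime) -> date:
    """Calendar date of a timestamp in the study's local timezone."""
    return ts.astimezone(LOCAL_TZ).date()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GeoPoint:
    """GPS fix attached to an event: position plus the GPS timestamp.

    The GPS timestamp comes from the satellite clock, so unlike the device
    timestamp it is immune to a wrongly set device clock, and unlike the
    server timestamp it is not delayed by transmission.
    """

    lat: float
    lon: float
    ts: datetime


@dataclass(slots=True)
class EventLog:
    """One UI navigation/action event — the paradata atom.

    Three timestamps are recorded per event: the device clock reading
    (``device_timestamp``), the event time as stamped by the application
    (``event_timestamp``, normally equal to the device clock), and the time
    the event-log server received the record (``server_timestamp``).
    """

    log_uid: str
    event_type: str
    ui_page_id: str
    device_id: str
    user_id: str
    device_timestamp: datetime
    event_timestamp: datetime
    server_timestamp: datetime
    geo: GeoPoint | None = None
    patient_id: str | None = None
    record_id: str | None = None


@dataclass(frozen=True, slots=True)
class EmrSubmission:
    """One completed clinical form as stored in the EMR."""

    provider_id: str
    patient_id: str
    form_uid: str
    encounter_datetime: datetime
    submission_datetime: datetime


@dataclass(frozen=True, slots=True)
class EventFlags:
    """Semantics of one event type, as used by cleaning and sessionization."""

    encounter_related: bool = False
    opens_form: bool = False
    completes_form: bool = False
    drafts_form: bool = False
    registers_patient: bool = False


class EventCatalog:
    """Map from event type to :class:`EventFlags`.

    The catalog is data, not code: the default below covers the common
    navigation vocabulary of a point-of-care app, and a fuller vocabulary
    (the real application logs 76 distinct types) can be supplied from YAML
    via :func:`load_catalog`.
    """

    def __init__(self, entries: Mapping[str, EventFlags]):
        for etype, flags in entries.items():
            if flags.completes_form and not flags.encounter_related:
                raise SchemaError(f"{etype}: completes_form implies encounter_related")
            if flags.opens_form and not flags.encounter_related:
                raise SchemaError(f"{etype}: opens_form implies encounter_related")
        self._entries = dict(entries)

    def __contains__(self, event_type: str) -> bool:
        return event_type in self._entries

    def __getitem__(self, event_type: str) -> EventFlags:
        return self._entries[event_type]

    def get(self, event_type: str, default: EventFlags | None = None) -> EventFlags | None:
        return self._entries.get(event_type, default)

    def flags(self, event_type: str) -> EventFlags:
        """Flags for a type; unknown types get all-False flags."""
        return self._entries.get(event_type, _UNKNOWN_FLAGS)

    @property
    def entries(self) -> dict[str, EventFlags]:
        return dict(self._entries)


_UNKNOWN_FLAGS = EventFlags()

DEFAULT_CATALOG = EventCatalog(
    {
        "login": EventFlags(),
        "logout": EventFlags(),
        "sync": EventFlags(),
        "app_background": EventFlags(),
        "view_client_list": EventFlags(),
        "view_form_list": EventFlags(),
        "search_client": EventFlags(),
        "view_patient_summary": EventFlags(encounter_related=True),
        "open_registration_form": EventFlags(
            encounter_related=True, opens_form=True, registers_patient=True
        ),
        "open_encounter_form": EventFlags(encounter_related=True, opens_form=True),
        "save_draft_form": EventFlags(encounter_related=True, drafts_form=True),
        "save_complete_encounter_form": EventFlags(
            encounter_related=True, completes_form=True
        ),
    }
)


def load_catalog(path: str | Path) -> EventCatalog:
    """Load an event catalog from YAML: ``{event_type: {flag: bool, ...}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return EventCatalog({etype: EventFlags(**(flags or {})) for etype, flags in raw.items()})


@dataclass
class LoadReport:
    """Audit trail of one ingest: lines read, skipped, and unknown types."""

    n_read: int = 0
    n_skipped: int = 0
    unknown_types: dict[str, int] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Timestamp (de)serialization
# ---------------------------------------------------------------------------

def parse_timestamp(value) -> datetime:
    """Parse ISO-8601 (with offset) or MongoDB extended-JSON dates."""
    if isinstance(value, dict):
        # {"$date": "..."} or {"$date": epoch-milliseconds}
        inner = value.get("$date")
        if inner is None:
            raise SchemaError(f"not a timestamp: {value!r}")
        if isinstance(inner, (int, float)):
            return datetime.fromtimestamp(inner / 1000.0, tz=timezone.utc)
        value = inner
    if not isinstance(value, str):
        raise SchemaError(f"not a timestamp: {value!r}")
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        raise SchemaError(f"timestamp lacks a UTC offset: {value!r}")
    return ts


def format_timestamp(ts: datetime) -> str:
    return ts.isoformat()


# Canonical JSONL field names for the event-log export.
_JSONL_FIELDS = {
    "log_uid": "logUid",
    "event_type": "eventType",
    "ui_page_id": "uiPageId",
    "device_id": "deviceId",
    "user_id": "userId",
    "patient_id": "patientUuid",
    "record_id": "recordUuid",
    "device_timestamp": "deviceTimestamp",
    "event_timestamp": "eventTimestamp",
    "server_timestamp": "serverTimestamp",
}
_REQUIRED_JSONL = [
    "logUid", "eventType", "uiPageId", "deviceId", "userId",
    "deviceTimestamp", "eventTimestamp", "serverTimestamp",
]


def _log_to_obj(log: EventLog) -> dict:
    obj = {
        "logUid": log.log_uid,
        "eventType": log.event_type,
        "uiPageId": log.ui_page_id,
        "deviceId": log.device_id,
        "userId": log.user_id,
        "deviceTimestamp": format_timestamp(log.device_timestamp),
        "eventTimestamp": format_timestamp(log.event_timestamp),
        "serverTimestamp": format_timestamp(log.server_timestamp),
    }
    if log.geo is not None:
        obj["geo"] = {
            "lat": log.geo.lat,
            "lon": log.geo.lon,
            "ts": format_timestamp(log.geo.ts),
        }
    if log.patient_id is not None:
        obj["patientUuid"] = log.patient_id
    if log.record_id is not None:
        obj["recordUuid"] = log.record_id
    return obj


def _obj_to_log(obj: dict, field_map: Mapping[str, str]) -> EventLog:
    missing = [k for k in _REQUIRED_JSONL if field_map.get(k, k) not in obj]
    if missing:
        raise SchemaError(f"missing fields: {', '.join(missing)}")
    get = lambda k: obj.get(field_map.get(k, k))
    geo = None
    if get("geo") is not None:
        g = get("geo")
        geo = GeoPoint(lat=float(g["lat"]), lon=float(g["lon"]), ts=parse_timestamp(g["ts"]))
    return EventLog(
        log_uid=str(get("logUid")),
        event_type=str(get("eventType")),
        ui_page_id=str(get("uiPageId")),
        device_id=str(get("deviceId")),
        user_id=str(get("userId")),
        device_timestamp=parse_timestamp(get("deviceTimestamp")),
        event_timestamp=parse_timestamp(get("eventTimestamp")),
        server_timestamp=parse_timestamp(get("serverTimestamp")),
        geo=geo,
        patient_id=None if get("patientUuid") is None else str(get("patientUuid")),
        record_id=None if get("recordUuid") is None else str(get("recordUuid")),
    )


# ---------------------------------------------------------------------------
# Event-log JSONL I/O
# ---------------------------------------------------------------------------

def read_event_logs(
    path: str | Path,
    catalog: EventCatalog = DEFAULT_CATALOG,
    strict: bool = False,
    field_map: Mapping[str, str] | None = None,
) -> tuple[list[EventLog], LoadReport]:
    """Read a JSON Lines event-log file, preserving record order.

    Unknown event types are retained but counted in the load report.  A
    malformed line raises :class:`SchemaError` (with the line number) in
    strict mode and is skipped and counted otherwise.

    ``field_map`` remaps canonical JSONL field names to the names used by a
    real export, e.g. ``{"patientUuid": "patient_uuid"}``.
    """
    field_map = dict(field_map or {})
    logs: list[EventLog] = []
    report = LoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                log = _obj_to_log(obj, field_map)
            except (json.JSONDecodeError, SchemaError, KeyError, ValueError, TypeError) as exc:
                if strict:
                    raise SchemaError(f"{path}:{lineno}: {exc}") from exc
                report.n_skipped += 1
                report.errors.append(f"line {lineno}: {exc}")
                continue
            if log.event_type not in catalog:
                report.unknown_types[log.event_type] = (
                    report.unknown_types.get(log.event_type, 0) + 1
                )
            logs.append(log)
            report.n_read += 1
    return logs, report


def write_event_logs(logs: Iterable[EventLog], path: str | Path) -> None:
    """Write event logs as JSON Lines (canonical field names, ISO-8601)."""
    with open(path, "w") as fh:
        for log in logs:
            fh.write(json.dumps(_log_to_obj(log), separators=(",", ":")) + "\n")


# ---------------------------------------------------------------------------
# EMR CSV I/O
# ---------------------------------------------------------------------------

EMR_HEADER = ["provider_id", "patient_id", "form_uid", "encounter_datetime", "submission_datetime"]


def read_emr_csv(path: str | Path) -> list[EmrSubmission]:
    """Read EMR form submissions from CSV, validating per-row invariants.

    Raises :class:`SchemaError` naming the offending row when a form is
    dated after its own submission or a form uid repeats.
    """
    subs: list[EmrSubmission] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                sub = EmrSubmission(
                    provider_id=row["provider_id"],
                    patient_id=row["patient_id"],
                    form_uid=row["form_uid"],
                    encounter_datetime=parse_timestamp(row["encounter_datetime"]),
                    submission_datetime=parse_timestamp(row["submission_datetime"]),
                )
            except (KeyError, SchemaError, ValueError) as exc:
                raise SchemaError(f"{path}: row {rownum}: {exc}") from exc
            if sub.encounter_datetime > sub.submission_datetime:
                raise SchemaError(
                    f"{path}: row {rownum}: encounter_datetime after submission_datetime"
                )
            if sub.form_uid in seen:
                raise SchemaError(f"{path}: row {rownum}: duplicate form_uid {sub.form_uid}")
            seen.add(sub.form_uid)
            subs.append(sub)
    return subs


def write_emr_csv(subs: Iterable[EmrSubmission], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EMR_HEADER)
        for s in subs:
            writer.writerow(
                [
                    s.provider_id,
                    s.patient_id,
                    s.form_uid,
                    format_timestamp(s.encounter_datetime),
                    format_timestamp(s.submission_datetime),
                ]
            )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_tables(summaries: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named DataFrame as ``<out_dir>/<name>.csv``.

    Empty frames yield header-only CSVs; paths written are returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in summaries.items():
        dest = out_dir / f"{name}.csv"
        frame.to_csv(dest, index=False)
        written.append(dest)
    return written
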