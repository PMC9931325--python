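"""Transform cleaned event logs into patient-provider encounter records.

An encounter is the app session in which a provider records one patient's
clinical form: it starts at the form-open event, ends at the form-save (or,
for forms never saved complete, at the last event touching that form), and
is keyed on the form-instance id when the client supplies one.  Older
clients may omit the form id, in which case contiguous activity on the same
patient is grouped by time proximity instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Literal

import pandas as pd

from .log_io import DEFAULT_CATALOG, EventCatalog, EventLog, local_date

__all__ = ["EncounterRecord", "SessionRules", "build_encounters", "encounter_intervals", "encounters_to_frame"]


@dataclass
class SessionRules:
    """Session-boundary policy.

    ``resume_gap_max_hours`` — a draft reopened after a longer silence starts
    a new active segment; an encounter's duration is the sum of its active
    segments, not the wall-clock span, so a form drafted on Monday and
    finished on Thursday does not become a three-day encounter.
    ``fallback_gap_minutes`` — when the client sent no form id, events on the
    same patient separated by no more than this gap are one encounter.
    ``orphan_policy`` — what to do with a form-save that has no preceding
    form-open ("keep": a zero-duration complete record; "drop": discard).
    """

    resume_gap_max_hours: float = 12.0
    fallback_gap_minutes: float = 30.0
    orphan_policy: Literal["keep", "drop"] = "keep"

    def __post_init__(self) -> None:
        if self.resume_gap_max_hours <= 0:
            raise ValueError("resume_gap_max_hours must be positive")


@dataclass(frozen=True, slots=True)
class EncounterRecord:
    """One reconstructed patient-provider form session."""

    provider_id: str
    patient_id: str | None
    record_id: str | None
    start_ts: datetime
    end_ts: datetime
    duration_minutes: float
    complete: bool
    work_date: date
    device_id: str
    n_events: int


def _active_minutes(times: list[datetime], max_gap: timedelta) -> float:
    """Sum of active-segment spans; a gap > max_gap splits segments."""
    total = timedelta()
    seg_start = prev = times[0]
    for t in times[1:]:
        if t - prev > max_gap:
            total += prev - seg_start
            seg_start = t
        prev = t
    total += prev - seg_start
    return total.total_seconds() / 60.0


def _make_record(provider: str, group: list[EventLog], catalog: EventCatalog,
                 rules: SessionRules) -> EncounterRecord:
    group = sorted(group, key=lambda l: l.event_timestamp)
    opens = [l for l in group if catalog.flags(l.event_type).opens_form]
    completes = [l for l in group if catalog.flags(l.event_type).completes_form]
    start = opens[0].event_timestamp if opens else group[0].event_timestamp
    if completes:
        end = completes[-1].event_timestamp
        complete = True
    else:
        end = group[-1].event_timestamp
        complete = False
    if end < start:  # orphan save arriving before a stray open; clamp
        start = end
    times = [l.event_timestamp for l in group if start <= l.event_timestamp <= end]
    duration = _active_minutes(times, timedelta(hours=rules.resume_gap_max_hours))
    patient = next((l.patient_id for l in group if l.patient_id is not None), None)
    record_id = next((l.record_id for l in group if l.record_id is not None), None)
    return EncounterRecord(
        provider_id=provider,
        patient_id=patient,
        record_id=record_id,
        start_ts=start,
        end_ts=end,
        duration_minutes=duration,
        complete=complete,
        work_date=local_date(end),
        device_id=group[0].device_id,
        n_events=len(group),
    )


def build_encounters(
    logs: Iterable[EventLog],
    catalog: EventCatalog = DEFAULT_CATALOG,
    rules: SessionRules | None = None,
) -> list[EncounterRecord]:
    """Group encounter-related logs into one record per form session.

    Logs are attributed to at most one record each: by (provider, form id)
    when the form id is present, otherwise to a time-contiguous run of
    activity on the same patient.  Encounter-related logs carrying neither a
    form id nor a patient id cannot be attributed and are ignored.  The
    result is sorted by provider, then start time.
    """
    rules = rules or SessionRules()
    keyed: dict[tuple[str, str], list[EventLog]] = {}
    orphan: dict[tuple[str, str], list[EventLog]] = {}
    for l in logs:
        flags = catalog.flags(l.event_type)
        if not flags.encounter_related:
            continue
        if l.record_id is not None:
            keyed.setdefault((l.user_id, l.record_id), []).append(l)
        elif l.patient_id is not None:
            orphan.setdefault((l.user_id, l.patient_id), []).append(l)

    records: list[EncounterRecord] = []
    for (provider, _), group in keyed.items():
        if rules.orphan_policy == "drop":
            has_open = any(catalog.flags(l.event_type).opens_form for l in group)
            has_complete = any(catalog.flags(l.event_type).completes_form for l in group)
            if has_complete and not has_open:
                continue  # form-save with no form-open, dropped by policy
        records.append(_make_record(provider, group, catalog, rules))

    # fallback grouping for clients that sent no form-instance id
    max_gap = timedelta(minutes=rules.fallback_gap_minutes)
    for (provider, _), group in orphan.items():
        group.sort(key=lambda l: l.event_timestamp)
        run: list[EventLog] = [group[0]]
        for l in group[1:]:
            if l.event_timestamp - run[-1].event_timestamp > max_gap:
                records.append(_make_record(provider, run, catalog, rules))
                run = [l]
            else:
                run.append(l)
        records.append(_make_record(provider, run, catalog, rules))

    records.sort(key=lambda r: (r.provider_id, r.start_ts, r.record_id or ""))
    return records


def encounter_intervals(records: Iterable[EncounterRecord]) -> list[tuple[str, float]]:
    """Gaps between consecutive same-provider same-day encounters, minutes.

    The gap is the idle time from the end of one record to the start of the
    next; overlapping records report a gap of 0.
    """
    by_day: dict[tuple[str, date], list[EncounterRecord]] = {}
    for r in records:
        by_day.setdefault((r.provider_id, r.work_date), []).append(r)
    gaps: list[tuple[str, float]] = []
    for (provider, _), recs in sorted(by_day.items()):
        recs.sort(key=lambda r: r.start_ts)
        for prev, nxt in zip(recs, recs[1:]):
            gap = (nxt.start_ts - prev.end_ts).total_seconds() / 60.0
            gaps.append((provider, max(gap, 0.0)))
    return gaps


def encounters_to_frame(records: Iterable[EncounterRecord]) -> pd.DataFrame:
    """EncounterRecords as a DataFrame with documented CSV headers."""
    cols = ["provider_id", "patient_id", "record_id", "start_ts", "end_ts",
            "duration_minutes", "complete", "work_date", "device_id", "n_events"]
    rows = [
        [r.provider_id, r.patient_id, r.record_id, r.start_ts.isoformat(),
         r.end_ts.isoformat(), r.duration_minutes, r.complete,
         r.work_date.isoformat(), r.device_id, r.n_events]
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)
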