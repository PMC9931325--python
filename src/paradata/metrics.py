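"""Work-performance metrics from reconstructed encounter records.

Four headline metrics — days worked, patients seen per day, work hours, and
encounter length — plus two usage-pattern indicators: after-hours entry
(form completion outside the official 08:00-17:00 Monday-Friday schedule)
and retrospective entry (rapid runs of very short form sessions, the
signature of batch data entry after the fact instead of point-of-care use).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, time
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .log_io import DEFAULT_CATALOG, EventCatalog, EventLog, LOCAL_TZ
from .sessionize import EncounterRecord, encounter_intervals

__all__ = [
    "WorkSchedule",
    "ProviderDaySummary",
    "MetricsReport",
    "percentage",
    "days_worked",
    "day_of_week_distribution",
    "patients_per_day",
    "work_hours",
    "after_hours",
    "flag_retrospective",
    "summarize",
    "save_plots",
]

WEEKDAY_NAMES = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]


def percentage(part: float, total: float) -> float:
    """Share of ``part`` in ``total`` as a percentage, 1 decimal place."""
    if total == 0:
        return 0.0
    return round(100.0 * part / total, 1)


@dataclass(frozen=True)
class WorkSchedule:
    """Official working hours; the after-hours boundary."""

    workday_start: time = time(8, 0)
    workday_end: time = time(17, 0)
    workweek: frozenset[int] = frozenset({0, 1, 2, 3, 4})  # Mon-Fri

    def __post_init__(self) -> None:
        if self.workday_start >= self.workday_end:
            raise ValueError("workday_start must be before workday_end")

    def is_after_hours(self, ts: datetime) -> bool:
        local = ts.astimezone(LOCAL_TZ)
        if local.weekday() not in self.workweek:
            return True
        # half-open interval: completion at exactly 17:00 is after hours
        return not (self.workday_start <= local.time() < self.workday_end)


@dataclass
class ProviderDaySummary:
    """Per-provider per-date aggregates."""

    provider_id: str
    work_date: date
    patients_seen: int = 0
    encounters: int = 0
    first_activity: datetime | None = None
    last_activity: datetime | None = None
    wall_clock_span_hours: float = 0.0
    active_minutes: float = 0.0
    after_hours_encounters: int = 0


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def days_worked(records: Iterable[EncounterRecord]) -> dict[str, set[date]]:
    """Workdays per provider.

    A workday is any date with evidence of at least one patient-encounter
    record — complete or not; an opened-but-never-finished form still counts
    as work done that day.
    """
    out: dict[str, set[date]] = {}
    for r in records:
        out.setdefault(r.provider_id, set()).add(r.work_date)
    return out


def day_of_week_distribution(workdays: Mapping[str, set[date]]) -> dict[str, int]:
    """Total provider-days worked, by day of week (Monday..Sunday)."""
    counts = dict.fromkeys(WEEKDAY_NAMES, 0)
    for days in workdays.values():
        for d in days:
            counts[WEEKDAY_NAMES[d.weekday()]] += 1
    return counts


def patients_per_day(records: Iterable[EncounterRecord]) -> list[ProviderDaySummary]:
    """Distinct patients seen per provider per workday.

    A patient "seen" is any patient registered or whose encounter data were
    recorded that day; several encounters with one patient count once.
    """
    patients: dict[tuple[str, date], set[str]] = {}
    encounters: dict[tuple[str, date], int] = {}
    for r in records:
        key = (r.provider_id, r.work_date)
        encounters[key] = encounters.get(key, 0) + 1
        if r.patient_id is not None:
            patients.setdefault(key, set()).add(r.patient_id)
    return [
        ProviderDaySummary(
            provider_id=prov,
            work_date=day,
            patients_seen=len(patients.get((prov, day), ())),
            encounters=n,
        )
        for (prov, day), n in sorted(encounters.items())
    ]


def work_hours(
    records: Iterable[EncounterRecord],
    logs: Iterable[EventLog] = (),
    catalog: EventCatalog = DEFAULT_CATALOG,
) -> list[ProviderDaySummary]:
    """Per provider-day: first/last encounter-related activity, wall-clock
    span, and active time (sum of encounter durations).

    Wall-clock span answers "over how long a stretch was the app in use";
    active time answers "how long was the provider actually recording".
    When raw logs are supplied, first/last activity come from every
    encounter-related log of that provider-day, which can widen the span
    beyond the records alone.
    """
    summaries: dict[tuple[str, date], ProviderDaySummary] = {}

    def bump(key: tuple[str, date], first: datetime, last: datetime) -> ProviderDaySummary:
        s = summaries.get(key)
        if s is None:
            s = summaries[key] = ProviderDaySummary(provider_id=key[0], work_date=key[1])
            s.first_activity, s.last_activity = first, last
        else:
            s.first_activity = min(s.first_activity, first)
            s.last_activity = max(s.last_activity, last)
        return s

    records = list(records)
    for r in records:
        s = bump((r.provider_id, r.work_date), r.start_ts, r.end_ts)
        s.encounters += 1
        s.active_minutes += r.duration_minutes
    for l in logs:
        if catalog.flags(l.event_type).encounter_related:
            key = (l.user_id, l.event_timestamp.astimezone(LOCAL_TZ).date())
            if key in summaries:  # only days already evidenced by a record
                bump(key, l.event_timestamp, l.event_timestamp)
    for s in summaries.values():
        s.wall_clock_span_hours = (
            (s.last_activity - s.first_activity).total_seconds() / 3600.0
        )
    return [summaries[k] for k in sorted(summaries)]


def after_hours(
    records: Iterable[EncounterRecord],
    schedule: WorkSchedule | None = None,
) -> tuple[list[EncounterRecord], int, float]:
    """Encounters completed outside official hours.

    A record is after-hours iff its completion time falls outside
    [workday_start, workday_end) local time or on a non-working weekday.
    Returns (flagged records, count, fraction of all records).
    """
    schedule = schedule or WorkSchedule()
    records = list(records)
    flagged = [r for r in records if schedule.is_after_hours(r.end_ts)]
    frac = len(flagged) / len(records) if records else 0.0
    return flagged, len(flagged), frac


def flag_retrospective(
    records: Iterable[EncounterRecord],
    duration_max_minutes: float = 3.0,
    gap_max_minutes: float = 2.0,
    run_min: int = 3,
) -> set[tuple[str, str | None, datetime]]:
    """Flag encounters that look like retrospective batch entry.

    A maximal same-provider same-day run of at least ``run_min`` consecutive
    records, each no longer than ``duration_max_minutes`` and separated by
    gaps of at most ``gap_max_minutes``, is flagged: real patient encounters
    take longer and do not chain back-to-back at that pace.  Returns the
    identities (provider, form id, start) of flagged records.
    """
    by_day: dict[tuple[str, date], list[EncounterRecord]] = {}
    for r in records:
        by_day.setdefault((r.provider_id, r.work_date), []).append(r)

    flagged: set[tuple[str, str | None, datetime]] = set()
    for _, recs in by_day.items():
        recs.sort(key=lambda r: r.start_ts)
        run: list[EncounterRecord] = []
        prev_end: datetime | None = None

        def close_run() -> None:
            if len(run) >= run_min:
                flagged.update((r.provider_id, r.record_id, r.start_ts) for r in run)

        for r in recs:
            short = r.duration_minutes <= duration_max_minutes
            gap_ok = (
                prev_end is not None
                and (r.start_ts - prev_end).total_seconds() / 60.0 <= gap_max_minutes
            )
            if short and (not run or gap_ok):
                run.append(r)
            else:
                close_run()
                run = [r] if short else []
            prev_end = r.end_ts
        close_run()
    return flagged


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Cohort-level summary of all derived metrics."""

    days_worked_per_provider: dict[str, int] = dc_field(default_factory=dict)
    day_of_week_totals: dict[str, int] = dc_field(default_factory=dict)
    patients_per_provider: dict[str, int] = dc_field(default_factory=dict)
    total_encounters: int = 0
    patients_per_day_mean: float = 0.0
    patients_per_day_min: int = 0
    patients_per_day_max: int = 0
    after_hours_count: int = 0
    after_hours_pct: float = 0.0
    weekend_working_providers: int = 0
    duration_summary: dict[str, float] = dc_field(default_factory=dict)
    gap_summary: dict[str, float] = dc_field(default_factory=dict)
    retrospective_count: int = 0
    retrospective_pct: float = 0.0

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Report as named DataFrames ready for :func:`log_io.write_tables`."""
        return {
            "days_worked_per_provider": pd.DataFrame(
                sorted(self.days_worked_per_provider.items()),
                columns=["provider_id", "days_worked"],
            ),
            "workdays_by_weekday": pd.DataFrame(
                [(d, self.day_of_week_totals.get(d, 0)) for d in WEEKDAY_NAMES],
                columns=["weekday", "provider_days"],
            ),
            "patients_per_provider": pd.DataFrame(
                sorted(self.patients_per_provider.items()),
                columns=["provider_id", "total_patients_seen"],
            ),
            "cohort_summary": pd.DataFrame(
                [
                    ("total_encounters", self.total_encounters),
                    ("patients_per_day_mean", self.patients_per_day_mean),
                    ("patients_per_day_min", self.patients_per_day_min),
                    ("patients_per_day_max", self.patients_per_day_max),
                    ("after_hours_count", self.after_hours_count),
                    ("after_hours_pct", self.after_hours_pct),
                    ("weekend_working_providers", self.weekend_working_providers),
                    ("retrospective_count", self.retrospective_count),
                    ("retrospective_pct", self.retrospective_pct),
                ],
                columns=["metric", "value"],
            ),
            "encounter_durations": pd.DataFrame(
                sorted(self.duration_summary.items()), columns=["stat", "minutes"]
            ),
            "encounter_gaps": pd.DataFrame(
                sorted(self.gap_summary.items()), columns=["stat", "minutes"]
            ),
        }


def _dist_summary(values: list[float]) -> dict[str, float]:
    if not values:
        return {"n": 0.0}
    arr = np.asarray(values, dtype=float)
    return {
        "n": float(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "p25": float(np.percentile(arr, 25)),
        "p75": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
    }


def save_plots(
    report: MetricsReport,
    out_dir,
    records: Iterable[EncounterRecord] | None = None,
) -> list:
    """Optional PNG plots: days worked per provider, workdays by weekday,
    and (when records are given) encounter-duration and gap histograms.

    Requires matplotlib; returns the paths written.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def bar(data: Mapping[str, float], title: str, name: str) -> None:
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.bar(list(data.keys()), list(data.values()), color="#4878a8")
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        dest = out_dir / name
        fig.savefig(dest, dpi=120)
        plt.close(fig)
        written.append(dest)

    bar(report.days_worked_per_provider, "Days worked per provider", "days_worked.png")
    bar(report.day_of_week_totals, "Provider-days by day of week", "workdays_by_weekday.png")

    if records is not None:
        records = list(records)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].hist([r.duration_minutes for r in records], bins=40, color="#4878a8")
        axes[0].set_title("Encounter duration (min)")
        axes[1].hist([g for _, g in encounter_intervals(records)], bins=40, color="#a85848")
        axes[1].set_title("Gap between encounters (min)")
        fig.tight_layout()
        dest = out_dir / "durations_and_gaps.png"
        fig.savefig(dest, dpi=120)
        plt.close(fig)
        written.append(dest)
    return written


def summarize(
    records: Iterable[EncounterRecord],
    logs: Iterable[EventLog] = (),
    schedule: WorkSchedule | None = None,
    catalog: EventCatalog = DEFAULT_CATALOG,
    retro_duration_max: float = 3.0,
    retro_gap_max: float = 2.0,
    retro_run_min: int = 3,
) -> MetricsReport:
    """Compute the full metrics report for a cohort of encounter records."""
    records = list(records)
    schedule = schedule or WorkSchedule()
    report = MetricsReport()

    workdays = days_worked(records)
    report.days_worked_per_provider = {p: len(d) for p, d in sorted(workdays.items())}
    report.day_of_week_totals = day_of_week_distribution(workdays)
    report.weekend_working_providers = sum(
        1 for days in workdays.values() if any(d.weekday() >= 5 for d in days)
    )

    # per-provider totals are sums of daily distinct-patient counts (a
    # patient revisiting on another day is another day's work), so provider
    # totals and per-day counts reconcile exactly
    day_summaries = patients_per_day(records)
    per_provider: dict[str, int] = {}
    for s in day_summaries:
        per_provider[s.provider_id] = per_provider.get(s.provider_id, 0) + s.patients_seen
    report.patients_per_provider = dict(sorted(per_provider.items()))
    report.total_encounters = len(records)
    counts = [s.patients_seen for s in day_summaries if s.patients_seen > 0]
    if counts:
        report.patients_per_day_mean = round(float(np.mean(counts)), 1)
        report.patients_per_day_min = int(min(counts))
        report.patients_per_day_max = int(max(counts))

    _, n_after, _ = after_hours(records, schedule)
    report.after_hours_count = n_after
    report.after_hours_pct = percentage(n_after, len(records))

    report.duration_summary = _dist_summary([r.duration_minutes for r in records])
    gaps = encounter_intervals(records)
    report.gap_summary = _dist_summary([g for _, g in gaps])

    flagged = flag_retrospective(records, retro_duration_max, retro_gap_max, retro_run_min)
    report.retrospective_count = len(flagged)
    report.retrospective_pct = percentage(len(flagged), len(records))
    return report
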