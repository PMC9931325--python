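"""Synthetic cohort generator: usage logs, matching EMR submissions, truth.

Emulates the statistical structure of a rural chronic-disease program where
nurses and clinical officers record hypertension encounters on tablets: a
couple of heavy users dominate volume, many providers work only a handful of
days, some work weekends and evenings, and a substantial share of forms is
entered retrospectively in short evening batches rather than at the point of
care.  The generator also injects the messiness the cleaning stage must
undo — duplicate records, test users, wrongly set device clocks, and events
outside the study window — and records everything it did in a ground-truth
object so downstream stages can be tested for exact recovery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .log_io import LOCAL_TZ, EmrSubmission, EventLog, GeoPoint

__all__ = ["SimulationConfig", "TrueEncounter", "CohortGroundTruth", "generate_cohort", "inject_noise"]


class SimulationConfig(BaseModel):
    """Parameters of the simulated cohort.

    Defaults emulate the study design the package targets: 13 active
    providers over the 91-day window 2019-12-02..2020-03-02, heterogeneous
    daily workload with a cohort mean near 14.5 patients per workday
    (individual days capped at 53), official hours 08:00-17:00 Mon-Fri with
    a minority of weekend workers and some evening point-of-care work.
    """

    n_providers: int = Field(13, ge=1)
    window_start: date = date(2019, 12, 2)
    window_end: date = date(2020, 3, 2)

    # Per-provider probability of working a given weekday. Drawn once per
    # provider from this range unless explicit probabilities are given.
    work_prob_range: tuple[float, float] = (0.05, 0.7)
    work_probs: Optional[dict[str, float]] = None

    # Patients per workday: 1 + NegBinomial(shape, p), truncated at the cap.
    patients_per_day_mean: float = Field(14.5, gt=1.0)
    patients_per_day_shape: float = Field(1.6, gt=0)
    patients_per_day_max: int = Field(53, ge=1)
    revisit_probability: float = Field(0.15, ge=0, le=1)

    # Entry-mode mixture and session shapes (minutes).
    point_of_care_fraction: float = Field(0.8, ge=0, le=1)
    live_duration_minutes: tuple[float, float] = (5.0, 30.0)
    retro_duration_minutes: tuple[float, float] = (0.5, 2.0)
    retro_gap_minutes: tuple[float, float] = (0.2, 1.0)
    evening_work_fraction: float = Field(0.05, ge=0, le=1)
    weekend_work_providers: Optional[set[str]] = None  # default: first 5
    weekend_prob_factor: float = Field(0.3, ge=0, le=1)

    # Noise knobs.
    incomplete_form_rate: float = Field(0.05, ge=0, le=1)
    duplicate_rate: float = Field(0.02, ge=0, le=1)
    clock_skew_minutes: dict[str, float] = Field(default_factory=lambda: {"DEV_05": -180.0})
    n_test_users: int = Field(2, ge=0)
    out_of_window_rate: float = Field(0.01, ge=0, le=1)

    # Transport model: server receipt lags the event by U(a, b) seconds.
    transmission_delay_seconds: tuple[float, float] = (10.0, 180.0)
    geo_fix_probability: float = Field(0.7, ge=0, le=1)

    rng_seed: int = 0

    @field_validator("live_duration_minutes", "retro_duration_minutes",
                     "retro_gap_minutes", "transmission_delay_seconds", "work_prob_range")
    @classmethod
    def _positive_interval(cls, v):
        lo, hi = v
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid interval {v}")
        return v

    @model_validator(mode="after")
    def _window_order(self):
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        if not (1 <= self.patients_per_day_mean <= self.patients_per_day_max):
            raise ValueError("patients_per_day_mean outside [1, patients_per_day_max]")
        return self

    def provider_ids(self) -> list[str]:
        return [f"USER_{i + 1:02d}" for i in range(self.n_providers)]

    def device_of(self, provider_id: str) -> str:
        return provider_id.replace("USER_", "DEV_")


@dataclass(frozen=True, slots=True)
class TrueEncounter:
    """Ground truth for one form session as entered in the app."""

    provider_id: str
    patient_id: str
    record_id: str
    start: datetime
    end: datetime
    complete: bool
    retrospective: bool
    device_id: str

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class CohortGroundTruth:
    """What the generator actually did — the oracle for recovery tests."""

    encounters: list[TrueEncounter] = field(default_factory=list)
    workdays: dict[str, set[date]] = field(default_factory=dict)
    patients_per_day: dict[tuple[str, date], int] = field(default_factory=dict)
    test_user_ids: set[str] = field(default_factory=set)
    test_log_count: int = 0
    duplicate_count: int = 0
    out_of_window_count: int = 0
    skew: dict[str, timedelta] = field(default_factory=dict)

    @property
    def n_complete(self) -> int:
        return sum(1 for e in self.encounters if e.complete)

    @property
    def retrospective_rate(self) -> float:
        if not self.encounters:
            return 0.0
        return sum(1 for e in self.encounters if e.retrospective) / len(self.encounters)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_UI_PAGE = {
    "login": "page_login",
    "logout": "page_login",
    "view_client_list": "page_client_list",
    "view_patient_summary": "page_patient_summary",
    "open_registration_form": "page_registration_form",
    "open_encounter_form": "page_encounter_form",
    "save_draft_form": "page_encounter_form",
    "save_complete_encounter_form": "page_encounter_form",
    "sync": "page_sync",
    "search_client": "page_client_list",
    "view_form_list": "page_form_list",
    "app_background": "page_none",
}


class _Emitter:
    """Accumulates logs with sequential uids and the configured transport lag."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.logs: list[EventLog] = []
        self._uid = 0
        self._facility: dict[str, tuple[float, float]] = {}

    def _facility_of(self, provider_id: str) -> tuple[float, float]:
        if provider_id not in self._facility:
            # western-Kenya-ish coordinates, one fixed site per provider
            self._facility[provider_id] = (
                0.3 + float(self.rng.uniform(-0.8, 0.8)),
                34.8 + float(self.rng.uniform(-0.6, 0.6)),
            )
        return self._facility[provider_id]

    def emit(
        self,
        event_type: str,
        user_id: str,
        device_id: str,
        when: datetime,
        patient_id: str | None = None,
        record_id: str | None = None,
    ) -> EventLog:
        self._uid += 1
        lo, hi = self.config.transmission_delay_seconds
        delay = timedelta(seconds=float(self.rng.uniform(lo, hi)))
        geo = None
        if self.rng.random() < self.config.geo_fix_probability:
            lat, lon = self._facility_of(user_id)
            geo = GeoPoint(lat=round(lat, 5), lon=round(lon, 5), ts=when)
        log = EventLog(
            log_uid=f"LOG_{self._uid:08d}",
            event_type=event_type,
            ui_page_id=_UI_PAGE.get(event_type, "page_none"),
            device_id=device_id,
            user_id=user_id,
            device_timestamp=when,
            event_timestamp=when,
            server_timestamp=when + delay,
            geo=geo,
            patient_id=patient_id,
            record_id=record_id,
        )
        self.logs.append(log)
        return log


def _sample_patients(config: SimulationConfig, rng: np.random.Generator) -> int:
    shape = config.patients_per_day_shape
    mean_excess = config.patients_per_day_mean - 1.0
    p = shape / (shape + mean_excess)
    k = 1 + int(rng.negative_binomial(shape, p))
    return min(k, config.patients_per_day_max)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[EventLog], list[EmrSubmission], CohortGroundTruth]:
    """Generate event logs, EMR submissions and ground truth for one cohort.

    Deterministic given ``config`` (including ``rng_seed``): identical
    configs yield byte-identical serialized outputs.  Every complete true
    encounter yields exactly one EMR submission; incomplete forms exist in
    the logs only.  Noise (duplicates, test users, out-of-window records,
    clock skew) is injected at the configured rates via :func:`inject_noise`
    and tallied in the returned :class:`CohortGroundTruth`.
    """
    rng = np.random.default_rng(config.rng_seed)
    emitter = _Emitter(config, rng)
    truth = CohortGroundTruth()
    emr: list[EmrSubmission] = []

    providers = config.provider_ids()
    lo, hi = config.work_prob_range
    if config.work_probs is not None:
        work_probs = {p: config.work_probs[p] for p in providers}
    else:
        work_probs = {p: float(rng.uniform(lo, hi)) for p in providers}
    weekend_set = config.weekend_work_providers
    if weekend_set is None:
        weekend_set = set(providers[: min(5, len(providers))])

    n_days = (config.window_end - config.window_start).days + 1
    all_dates = [config.window_start + timedelta(days=i) for i in range(n_days)]

    rec_counter = 0
    pat_counter = 0

    for provider in providers:
        device = config.device_of(provider)
        truth.workdays[provider] = set()
        seen_patients: list[str] = []

        for day in all_dates:
            p_work = work_probs[provider]
            if day.weekday() >= 5:  # Sat/Sun
                if provider not in weekend_set:
                    continue
                p_work *= config.weekend_prob_factor
            if rng.random() >= p_work:
                continue

            k = _sample_patients(config, rng)
            day_start = datetime.combine(day, time(0, 0), tzinfo=LOCAL_TZ)

            # choose entry mode per patient
            live_flags = rng.random(k) < config.point_of_care_fraction
            patients: list[str] = []
            new_flags: list[bool] = []
            for _ in range(k):
                if seen_patients and rng.random() < config.revisit_probability:
                    pid = seen_patients[int(rng.integers(len(seen_patients)))]
                    new = False
                else:
                    pat_counter += 1
                    pid = f"PAT_{pat_counter:06d}"
                    seen_patients.append(pid)
                    new = True
                patients.append(pid)
                new_flags.append(new)

            day_events: list[tuple] = []  # (start, end, pid, new, live)
            d_lo, d_hi = config.live_duration_minutes
            for pid, new, live in zip(patients, new_flags, live_flags):
                if not live:
                    continue
                if rng.random() < config.evening_work_fraction:
                    start_min = float(rng.uniform(17 * 60, 20 * 60))
                else:
                    start_min = float(rng.uniform(8 * 60, 16 * 60))
                dur = float(rng.uniform(d_lo, d_hi))
                start = day_start + timedelta(minutes=start_min)
                day_events.append((start, start + timedelta(minutes=dur), pid, new))

            # retrospective batch: the provider saw these patients on paper
            # during the day and types them in as a rapid evening run
            r_lo, r_hi = config.retro_duration_minutes
            g_lo, g_hi = config.retro_gap_minutes
            cursor = day_start + timedelta(minutes=float(rng.uniform(18 * 60, 19 * 60)))
            retro_events: list[tuple] = []
            for pid, new, live in zip(patients, new_flags, live_flags):
                if live:
                    continue
                dur = float(rng.uniform(r_lo, r_hi))
                retro_events.append((cursor, cursor + timedelta(minutes=dur), pid, new))
                cursor += timedelta(minutes=dur + float(rng.uniform(g_lo, g_hi)))

            if not day_events and not retro_events:
                continue
            truth.workdays[provider].add(day)
            truth.patients_per_day[(provider, day)] = len(set(patients))

            all_sessions = sorted(
                [(s, e, pid, new, True) for s, e, pid, new in day_events]
                + [(s, e, pid, new, False) for s, e, pid, new in retro_events],
                key=lambda t: t[0],
            )
            first_ts = all_sessions[0][0]
            last_ts = all_sessions[-1][1]

            # ambient navigation (not encounter-related; cleaned out later)
            emitter.emit("login", provider, device, first_ts - timedelta(minutes=float(rng.uniform(1, 10))))
            emitter.emit("view_client_list", provider, device, first_ts - timedelta(minutes=float(rng.uniform(0.2, 1))))

            for start, end, pid, new, live in all_sessions:
                rec_counter += 1
                rid = f"REC_{rec_counter:06d}"
                complete = rng.random() >= config.incomplete_form_rate
                open_type = "open_registration_form" if new else "open_encounter_form"
                emitter.emit(open_type, provider, device, start, patient_id=pid, record_id=rid)
                if live and (end - start) > timedelta(minutes=3):
                    mid = start + (end - start) * 0.4
                    emitter.emit("view_patient_summary", provider, device, mid,
                                 patient_id=pid, record_id=rid)
                save_type = "save_complete_encounter_form" if complete else "save_draft_form"
                save_log = emitter.emit(save_type, provider, device, end,
                                        patient_id=pid, record_id=rid)
                truth.encounters.append(
                    TrueEncounter(
                        provider_id=provider, patient_id=pid, record_id=rid,
                        start=start, end=end, complete=complete,
                        retrospective=not live, device_id=device,
                    )
                )
                if complete:
                    emr.append(
                        EmrSubmission(
                            provider_id=provider, patient_id=pid, form_uid=rid,
                            encounter_datetime=end,
                            submission_datetime=save_log.server_timestamp,
                        )
                    )

            emitter.emit("logout", provider, device, last_ts + timedelta(minutes=float(rng.uniform(1, 10))))

    logs = inject_noise(emitter.logs, config, rng=rng, truth=truth, emitter=emitter)
    logs.sort(key=lambda l: (l.server_timestamp, l.log_uid))
    return logs, emr, truth


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def inject_noise(
    logs: list[EventLog],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: CohortGroundTruth | None = None,
    emitter: _Emitter | None = None,
) -> list[EventLog]:
    """Inject test users, out-of-window records, duplicates and clock skew.

    Duplicates are exact field-for-field copies of existing records (a
    re-transmission to the server).  Clock skew shifts the device and event
    timestamps of every log of a flagged device by the configured offset;
    server and GPS timestamps are untouched, since only the device clock is
    wrong.  Everything injected is tallied in ``truth`` when given.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if emitter is None:
        emitter = _Emitter(config, rng)
        emitter.logs = list(logs)
        emitter._uid = len(logs)
    out = emitter.logs
    n_base = len(out)
    n_days = (config.window_end - config.window_start).days + 1

    # test users: engineers poking at the app inside the study window
    for t in range(config.n_test_users):
        uid = f"TEST_USER_{t + 1:02d}"
        dev = f"TEST_DEV_{t + 1:02d}"
        if truth is not None:
            truth.test_user_ids.add(uid)
        n_events = int(rng.integers(10, 40))
        for _ in range(n_events):
            day = config.window_start + timedelta(days=int(rng.integers(n_days)))
            when = datetime.combine(day, time(0, 0), tzinfo=LOCAL_TZ) + timedelta(
                minutes=float(rng.uniform(8 * 60, 20 * 60))
            )
            etype = ["login", "view_client_list", "open_encounter_form", "sync"][int(rng.integers(4))]
            emitter.emit(etype, uid, dev, when,
                         patient_id="PAT_TEST" if etype == "open_encounter_form" else None,
                         record_id=f"REC_TEST_{emitter._uid + 1}" if etype == "open_encounter_form" else None)
            if truth is not None:
                truth.test_log_count += 1

    # out-of-window stragglers from real providers (before/after the study)
    n_oow = int(round(config.out_of_window_rate * n_base))
    providers = config.provider_ids()
    for i in range(n_oow):
        provider = providers[int(rng.integers(len(providers)))]
        if rng.random() < 0.5:
            day = config.window_start - timedelta(days=int(rng.integers(1, 30)))
        else:
            day = config.window_end + timedelta(days=int(rng.integers(1, 30)))
        when = datetime.combine(day, time(0, 0), tzinfo=LOCAL_TZ) + timedelta(
            minutes=float(rng.uniform(8 * 60, 18 * 60))
        )
        emitter.emit("open_encounter_form", provider, config.device_of(provider), when,
                     patient_id=f"PAT_OOW_{i:04d}", record_id=f"REC_OOW_{i:04d}")
        if truth is not None:
            truth.out_of_window_count += 1

    # duplicates: exact copies (same uid — the server re-received the
    # record); only provider logs re-transmit, so removal tallies stay
    # attributable to one cleaning step each
    test_ids = {f"TEST_USER_{t + 1:02d}" for t in range(config.n_test_users)}
    candidates = [i for i, l in enumerate(out) if l.user_id not in test_ids]
    n_dup = int(round(config.duplicate_rate * len(candidates)))
    if n_dup:
        idx = rng.choice(len(candidates), size=n_dup, replace=False)
        for i in sorted(candidates[int(j)] for j in idx):
            out.append(copy.copy(out[i]))
        if truth is not None:
            truth.duplicate_count += n_dup

    # clock skew: device clock off by a fixed signed offset
    for dev, minutes in config.clock_skew_minutes.items():
        offset = timedelta(minutes=minutes)
        if truth is not None:
            truth.skew[dev] = offset
        for log in out:
            if log.device_id == dev:
                log.event_timestamp += offset
                log.device_timestamp += offset

    return out
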