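"""Shared fixtures: small simulated cohorts and hand-built log records."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from paradata import (
    DEFAULT_CATALOG,
    EventLog,
    SimulationConfig,
    generate_cohort,
)
from paradata.log_io import LOCAL_TZ


def make_log(
    uid: str = "LOG_1",
    event_type: str = "open_encounter_form",
    user: str = "USER_01",
    device: str = "DEV_01",
    when: datetime | None = None,
    delay_s: float = 60.0,
    patient: str | None = "PAT_1",
    record: str | None = "REC_1",
    geo=None,
) -> EventLog:
    """A hand-built event log with sensible defaults for unit tests."""
    when = when or datetime(2019, 12, 10, 10, 0, tzinfo=LOCAL_TZ)
    return EventLog(
        log_uid=uid,
        event_type=event_type,
        ui_page_id="page_x",
        device_id=device,
        user_id=user,
        device_timestamp=when,
        event_timestamp=when,
        server_timestamp=when + timedelta(seconds=delay_s),
        geo=geo,
        patient_id=patient,
        record_id=record,
    )


def ts(day: int, hour: int, minute: int = 0, month: int = 12, year: int = 2019) -> datetime:
    return datetime(year, month, day, hour, minute, tzinfo=LOCAL_TZ)


# A small, fast cohort: 4 providers over 3 weeks. Unit tests that need a
# simulated cohort use this scale; the acceptance tests run the full design.
SMALL = dict(
    n_providers=4,
    window_start=date(2019, 12, 2),
    window_end=date(2019, 12, 22),
    patients_per_day_mean=8.0,
)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimulationConfig(
        **SMALL,
        incomplete_form_rate=0.0,
        duplicate_rate=0.0,
        clock_skew_minutes={},
        n_test_users=0,
        out_of_window_rate=0.0,
        rng_seed=7,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = SimulationConfig(
        **SMALL,
        incomplete_form_rate=0.08,
        duplicate_rate=0.1,
        clock_skew_minutes={"DEV_02": 180.0},
        n_test_users=2,
        out_of_window_rate=0.02,
        rng_seed=11,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture
def catalog():
    return DEFAULT_CATALOG
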