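"""Performance metrics: workdays, patients/day, hours, after-hours, retro."""

from datetime import date, time, timedelta

import pytest

from paradata import (
    CleaningConfig,
    EncounterRecord,
    WorkSchedule,
    after_hours,
    build_encounters,
    clean,
    day_of_week_distribution,
    days_worked,
    flag_retrospective,
    patients_per_day,
    percentage,
    summarize,
    work_hours,
)
from paradata.log_io import LOCAL_TZ

from conftest import ts


def rec(provider="USER_01", patient="PAT_1", rid="R1", start=None, end=None,
        complete=True, device="DEV_01"):
    start = start or ts(10, 10)
    end = end or start + timedelta(minutes=15)
    return EncounterRecord(
        provider_id=provider, patient_id=patient, record_id=rid,
        start_ts=start, end_ts=end,
        duration_minutes=(end - start).total_seconds() / 60.0,
        complete=complete, work_date=end.astimezone(LOCAL_TZ).date(),
        device_id=device, n_events=2,
    )


# -- days worked & weekday distribution ---------------------------------------

def test_days_worked_counts_unique_dates_including_incomplete():
    records = [
        rec(rid="R1", start=ts(9, 10)),
        rec(rid="R2", start=ts(9, 14), complete=False),
        rec(rid="R3", start=ts(10, 10)),
        rec(rid="R4", start=ts(12, 10), complete=False),  # incomplete-only day
    ]
    assert days_worked(records) == {"USER_01": {date(2019, 12, 9), date(2019, 12, 10), date(2019, 12, 12)}}


def test_no_records_no_workdays():
    assert days_worked([]) == {}


def test_weekday_distribution_masses():
    mondays = {"USER_01": {date(2019, 12, 2), date(2019, 12, 9)}, "USER_02": {date(2019, 12, 16)}}
    dist = day_of_week_distribution(mondays)
    assert dist["Monday"] == 3
    assert sum(dist.values()) == 3


# -- patients per day ----------------------------------------------------------

def test_same_patient_twice_in_a_day_counts_once():
    records = [rec(rid="R1"), rec(rid="R2", start=ts(10, 14))]
    (summary,) = patients_per_day(records)
    assert summary.patients_seen == 1 and summary.encounters == 2


def test_two_patients_one_day_counts_two():
    records = [rec(rid="R1"), rec(rid="R2", patient="PAT_2", start=ts(10, 14))]
    (summary,) = patients_per_day(records)
    assert summary.patients_seen == 2


def test_per_day_counts_match_ground_truth(noise_free_cohort):
    cfg, logs, _, truth = noise_free_cohort
    cleaned, _ = clean(logs, CleaningConfig(study_window=(cfg.window_start, cfg.window_end)))
    summaries = patients_per_day(build_encounters(cleaned))
    observed = {(s.provider_id, s.work_date): s.patients_seen for s in summaries}
    assert observed == truth.patients_per_day


# -- work hours ----------------------------------------------------------------

def test_work_hours_wall_clock_vs_active():
    records = [
        rec(rid="R1", start=ts(10, 9, 0), end=ts(10, 9, 30)),
        rec(rid="R2", start=ts(10, 16, 0), end=ts(10, 16, 20)),
    ]
    (s,) = work_hours(records)
    assert s.wall_clock_span_hours == pytest.approx(7 + 20 / 60)
    assert s.active_minutes == pytest.approx(50.0)
    assert s.first_activity == ts(10, 9) and s.last_activity == ts(10, 16, 20)


def test_single_encounter_active_span():
    (s,) = work_hours([rec(start=ts(10, 9), end=ts(10, 9, 20))])
    assert s.active_minutes == pytest.approx(20.0)


# -- after hours ----------------------------------------------------------------

@pytest.mark.parametrize(
    ("end", "expected"),
    [
        (ts(10, 19, 30), True),   # Tuesday evening
        (ts(11, 10, 0), False),   # Wednesday morning
        (ts(14, 10, 0), True),    # Saturday morning: weekend rule
        (ts(10, 8, 0), False),    # at opening: regular
        (ts(10, 17, 0), True),    # at closing: half-open interval
        (ts(10, 7, 59), True),    # just before opening
    ],
)
def test_after_hours_boundaries(end, expected):
    _, count, _ = after_hours([rec(start=end - timedelta(minutes=5), end=end)])
    assert bool(count) is expected


def test_after_hours_fraction_order_invariant_and_monotone():
    records = [rec(rid=f"R{h}", start=ts(10, h), end=ts(10, h, 30)) for h in range(9, 20)]
    _, base, _ = after_hours(records)
    _, rev, _ = after_hours(records[::-1])
    assert base == rev
    # moving the end of the workday earlier can only flag more records
    _, earlier, _ = after_hours(records, WorkSchedule(workday_end=time(14, 0)))
    assert earlier >= base


# -- retrospective flagging ------------------------------------------------------

def _run(n, start, dur_min=1.0, gap_min=0.5, provider="USER_01"):
    out = []
    cursor = start
    for i in range(n):
        end = cursor + timedelta(minutes=dur_min)
        out.append(rec(provider=provider, patient=f"PAT_{i}", rid=f"B{i}", start=cursor, end=end))
        cursor = end + timedelta(minutes=gap_min)
    return out


def test_rapid_run_of_short_records_all_flagged():
    records = _run(5, ts(10, 19))
    assert len(flag_retrospective(records)) == 5


def test_isolated_long_encounter_not_flagged():
    assert flag_retrospective([rec(start=ts(10, 10), end=ts(10, 10, 20))]) == set()


def test_run_shorter_than_minimum_not_flagged():
    assert flag_retrospective(_run(2, ts(10, 19))) == set()


def test_long_record_breaks_the_run():
    records = _run(2, ts(10, 19))
    tail = records[-1].end_ts + timedelta(minutes=0.5)
    records.append(rec(rid="LONG", start=tail, end=tail + timedelta(minutes=20)))
    records += _run(2, records[-1].end_ts + timedelta(minutes=0.5), provider="USER_01")
    assert flag_retrospective(records) == set()


def test_flag_rate_tracks_generator_truth():
    from paradata import SimulationConfig, generate_cohort
    from conftest import SMALL

    cfg = SimulationConfig(**SMALL, point_of_care_fraction=0.5,
                           duplicate_rate=0.0, clock_skew_minutes={},
                           n_test_users=0, out_of_window_rate=0.0, rng_seed=21)
    logs, _, truth = generate_cohort(cfg)
    cleaned, _ = clean(logs, CleaningConfig(study_window=(cfg.window_start, cfg.window_end)))
    records = build_encounters(cleaned)
    flagged = flag_retrospective(records)
    rate = len(flagged) / len(records)
    assert rate == pytest.approx(truth.retrospective_rate, abs=0.10)


# -- cohort report ----------------------------------------------------------------

def test_percentage_rounding():
    assert percentage(9, 40) == 22.5
    assert percentage(0, 0) == 0.0


def test_empty_input_gives_zero_report():
    report = summarize([])
    assert report.total_encounters == 0
    assert report.after_hours_count == 0 and report.after_hours_pct == 0.0
    assert report.days_worked_per_provider == {}


def test_report_reconciles(noise_free_cohort):
    cfg, logs, _, truth = noise_free_cohort
    cleaned, _ = clean(logs, CleaningConfig(study_window=(cfg.window_start, cfg.window_end)))
    records = build_encounters(cleaned)
    report = summarize(records, cleaned)

    assert report.total_encounters == len(truth.encounters)
    assert sum(report.day_of_week_totals.values()) == sum(report.days_worked_per_provider.values())
    # provider totals reconcile with per-day distinct patients (conservation)
    assert sum(report.patients_per_provider.values()) == sum(truth.patients_per_day.values())
    assert report.days_worked_per_provider == {p: len(d) for p, d in truth.workdays.items() if d}
    tables = report.to_tables()
    assert set(tables) >= {"days_worked_per_provider", "workdays_by_weekday",
                           "patients_per_provider", "cohort_summary"}


def test_plot_export_writes_pngs(tmp_path, noise_free_cohort):
    cfg, logs, _, _ = noise_free_cohort
    cleaned, _ = clean(logs, CleaningConfig(study_window=(cfg.window_start, cfg.window_end)))
    records = build_encounters(cleaned)
    from paradata.metrics import save_plots

    written = save_plots(summarize(records, cleaned), tmp_path, records)
    assert {p.name for p in written} == {
        "days_worked.png", "workdays_by_weekday.png", "durations_and_gaps.png"
    }
    assert all(p.stat().st_size > 0 for p in written)
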