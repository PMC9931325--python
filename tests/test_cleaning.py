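"""Cleaning pipeline: each step's contract plus composition properties."""

import copy
from datetime import date, timedelta

import pytest

from paradata import (
    CleaningConfig,
    clean,
    deduplicate,
    exclude_test_users,
    filter_relevant,
    filter_window,
    impute_timestamps,
)
from paradata.cleaning import CleaningReport, _estimate_offsets

from conftest import make_log, ts


# -- test users ---------------------------------------------------------------

def test_empty_test_set_is_identity():
    logs = [make_log(uid=f"L{i}") for i in range(3)]
    assert exclude_test_users(logs, CleaningConfig()) == logs


def test_all_users_listed_empties_output():
    logs = [make_log(uid=f"L{i}", user=f"U{i}") for i in range(3)]
    cfg = CleaningConfig(test_user_ids=frozenset({"U0", "U1", "U2"}))
    assert exclude_test_users(logs, cfg) == []


def test_generator_test_logs_all_removed(noisy_cohort):
    _, logs, _, truth = noisy_cohort
    cfg = CleaningConfig(test_user_ids=frozenset(truth.test_user_ids))
    kept = exclude_test_users(logs, cfg)
    assert len(logs) - len(kept) == truth.test_log_count
    assert not any(l.user_id in truth.test_user_ids for l in kept)


# -- deduplication ------------------------------------------------------------

def test_no_duplicates_is_identity():
    logs = [make_log(uid=f"L{i}", when=ts(10, 9 + i)) for i in range(4)]
    assert deduplicate(logs) == logs


def test_exact_copy_leaves_one_survivor():
    a = make_log()
    assert deduplicate([a, copy.copy(a)]) == [a]


def test_retransmitted_event_with_fresh_uid_is_still_a_duplicate():
    a = make_log(uid="L1")
    b = copy.copy(a)
    b.log_uid = "L2"  # server re-assigned the uid on re-transmission
    b.server_timestamp = a.server_timestamp + timedelta(minutes=5)
    assert deduplicate([a, b]) == [a]


def test_first_by_server_timestamp_kept():
    a = make_log(uid="L1")
    b = copy.copy(a)
    b.server_timestamp = a.server_timestamp - timedelta(minutes=1)
    assert deduplicate([a, b]) == [b]


# -- relevance ----------------------------------------------------------------

def test_all_known_rule_keeps_known_types(catalog):
    logs = [make_log(event_type="login", patient=None, record=None), make_log()]
    cfg = CleaningConfig(relevance="all_known")
    assert filter_relevant(logs, catalog, cfg) == logs


def test_default_rule_drops_navigation_events(catalog):
    login = make_log(event_type="login", patient=None, record=None)
    form = make_log(event_type="open_encounter_form")
    assert filter_relevant([login, form], catalog) == [form]


def test_unknown_types_dropped(catalog):
    assert filter_relevant([make_log(event_type="mystery")], catalog) == []


def test_relevant_count_matches_hand_count(catalog):
    mix = (
        [make_log(uid=f"A{i}", event_type="open_encounter_form") for i in range(3)]
        + [make_log(uid=f"B{i}", event_type="save_complete_encounter_form") for i in range(2)]
        + [make_log(uid=f"C{i}", event_type="sync", patient=None, record=None) for i in range(4)]
    )
    assert len(filter_relevant(mix, catalog)) == 5


# -- timestamp imputation -----------------------------------------------------

def test_zero_skew_device_unchanged():
    logs = [make_log(uid=f"L{i}", when=ts(10, 9 + i), delay_s=30 + i) for i in range(5)]
    assert impute_timestamps(logs, CleaningConfig()) == logs


def test_injected_skew_recovered_within_delay_spread():
    # device clock 3 h behind: recorded event times lag the truth by 3 h
    true_times = [ts(10, 9) + timedelta(minutes=5 * i) for i in range(40)]
    logs = []
    for i, t in enumerate(true_times):
        l = make_log(uid=f"L{i}", when=t - timedelta(hours=3), delay_s=0)
        l.server_timestamp = t + timedelta(seconds=30 + (i % 5) * 20)  # real transport lag
        logs.append(l)
    report = CleaningReport()
    fixed = impute_timestamps(logs, CleaningConfig(), report)
    assert "DEV_01" in report.corrected_devices
    spread = 110  # max simulated delay, seconds
    for l, t in zip(fixed, true_times):
        assert abs((l.event_timestamp - t).total_seconds()) <= spread
        assert l.event_timestamp <= l.server_timestamp


def test_epoch_reset_clock_corrected_into_study_window():
    # a device reporting 1970: offset is estimated from the server timestamps
    true_times = [ts(10, 9 + i) for i in range(5)]
    logs = []
    for i, t in enumerate(true_times):
        l = make_log(uid=f"L{i}", when=ts(1, 0, 0, month=1, year=1970))
        l.event_timestamp += timedelta(hours=i)
        l.device_timestamp = l.event_timestamp
        l.server_timestamp = true_times[i] + timedelta(seconds=60)
        logs.append(l)
    cfg = CleaningConfig()
    fixed = impute_timestamps(logs, cfg)
    from paradata.log_io import local_date

    start, end = cfg.study_window
    assert all(start <= local_date(l.event_timestamp) <= end for l in fixed)


def test_skewed_device_with_too_few_logs_flagged_uncorrectable():
    logs = [make_log(uid=f"L{i}", when=ts(10, 9) - timedelta(hours=3), delay_s=0) for i in range(2)]
    for l in logs:
        l.server_timestamp = ts(10, 9) + timedelta(seconds=30)
    report = CleaningReport()
    fixed = impute_timestamps(logs, CleaningConfig(), report)
    assert report.uncorrectable_devices == ["DEV_01"]
    assert fixed == logs  # kept unshifted


def test_geo_timestamp_preferred_over_server():
    from paradata import GeoPoint

    true_t = ts(10, 9)
    logs = []
    for i in range(5):
        l = make_log(uid=f"L{i}", when=true_t + timedelta(minutes=i) - timedelta(hours=3),
                     geo=GeoPoint(0.5, 34.9, true_t + timedelta(minutes=i)))
        l.server_timestamp = true_t + timedelta(minutes=i, seconds=90)
        logs.append(l)
    offsets, _ = _estimate_offsets(logs, CleaningConfig())
    assert offsets["DEV_01"] == timedelta(hours=3)  # exact: GPS time has no lag


# -- window filter ------------------------------------------------------------

def test_window_is_inclusive_of_both_endpoints():
    cfg = CleaningConfig(study_window=(date(2019, 12, 2), date(2020, 3, 2)))
    first_minute = make_log(uid="A", when=ts(2, 0, 1))
    last_day = make_log(uid="B", when=ts(2, 23, 59, month=3, year=2020))
    day_before = make_log(uid="C", when=ts(1, 12))
    day_after = make_log(uid="D", when=ts(3, 0, 1, month=3, year=2020))
    assert filter_window([first_minute, last_day, day_before, day_after], cfg) == [
        first_minute,
        last_day,
    ]


def test_window_filter_must_follow_imputation():
    """A record only belongs in-window after its clock is corrected.

    Regression guard on step order: a device 3 h behind pushes a morning
    event on the first study day to the evening before; filtering first
    would discard it.
    """
    cfg = CleaningConfig(study_window=(date(2019, 12, 2), date(2020, 3, 2)))
    true_times = [ts(2, 1) + timedelta(minutes=10 * i) for i in range(6)]  # early on Dec 2nd
    logs = []
    for i, t in enumerate(true_times):
        l = make_log(uid=f"L{i}", when=t - timedelta(hours=3), delay_s=0)
        l.server_timestamp = t + timedelta(seconds=45)
        logs.append(l)
    assert filter_window(logs, cfg) == []  # raw timestamps fall before the window
    cleaned, report = clean(logs, cfg)
    assert len(cleaned) == len(logs)
    assert report.removed_out_of_window == 0


# -- composed pipeline --------------------------------------------------------

def _clean_cfg(truth, cfg):
    return CleaningConfig(
        study_window=(cfg.window_start, cfg.window_end),
        test_user_ids=frozenset(truth.test_user_ids),
    )


def test_report_balances_and_is_idempotent(noisy_cohort):
    cfg, logs, _, truth = noisy_cohort
    ccfg = _clean_cfg(truth, cfg)
    cleaned, report = clean(logs, ccfg)
    assert report.balanced
    assert report.input_total == len(logs) and report.output_total == len(cleaned)
    again, report2 = clean(cleaned, ccfg)
    assert again == cleaned
    assert report2.removed_test_users == report2.removed_duplicates == 0
    assert report2.removed_irrelevant == report2.removed_out_of_window == 0


def test_noise_free_cohort_reports_all_zero(noise_free_cohort):
    cfg, logs, _, truth = noise_free_cohort
    cleaned, report = clean(logs, _clean_cfg(truth, cfg))
    assert report.removed_test_users == 0
    assert report.removed_duplicates == 0
    assert report.removed_out_of_window == 0
    assert report.corrected_devices == {}
    # only ambient navigation events (login/logout/...) are dropped
    assert report.removed_irrelevant == report.input_total - report.output_total


def test_full_noise_cohort_recovers_truth_counts(noisy_cohort):
    cfg, logs, _, truth = noisy_cohort
    cleaned, report = clean(logs, _clean_cfg(truth, cfg))
    assert report.removed_test_users == truth.test_log_count
    assert report.removed_duplicates == truth.duplicate_count
    assert report.removed_out_of_window == truth.out_of_window_count
    assert set(report.corrected_devices) == set(truth.skew)
    est = report.corrected_devices["DEV_02"]
    assert est == pytest.approx(-180.0, abs=3.5)  # minutes; lag-limited accuracy
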