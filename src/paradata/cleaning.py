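"""Log cleaning: test users, duplicates, relevance, clock skew, study window.

The steps run in a fixed order — exclude test users, drop duplicates, keep
only app-usage-relevant events, impute timestamps for devices with a wrongly
set clock, then filter to the study window.  Window filtering must come
after imputation: a record stamped months off by a bad device clock may
belong inside the window only once corrected.  Every step's removals are
tallied in an auditable :class:`CleaningReport` and the composed pipeline is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timedelta
from statistics import median
from typing import Callable

import pandas as pd

from .log_io import DEFAULT_CATALOG, EventCatalog, EventFlags, EventLog, local_date

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "exclude_test_users",
    "deduplicate",
    "filter_relevant",
    "impute_timestamps",
    "filter_window",
    "clean",
]

# Relevance rules selectable by name in a config file.
RELEVANCE_RULES: dict[str, Callable[[EventFlags], bool]] = {
    # the default: only events tied to a patient clinical encounter
    "encounter_related": lambda f: f.encounter_related,
    # keep everything the catalog knows about
    "all_known": lambda f: True,
}


@dataclass
class CleaningConfig:
    """Study window, test users and skew handling for one cleaning run."""

    study_window: tuple[date, date] = (date(2019, 12, 2), date(2020, 3, 2))
    test_user_ids: frozenset[str] = frozenset()
    skew_threshold_minutes: float = 30.0
    relevance: str | Callable[[EventFlags], bool] = "encounter_related"
    min_logs_for_offset: int = 3

    def __post_init__(self) -> None:
        start, end = self.study_window
        if start > end:
            raise ValueError("study window start must be <= end")
        if self.skew_threshold_minutes <= 0:
            raise ValueError("skew_threshold_minutes must be positive")
        self.test_user_ids = frozenset(self.test_user_ids)

    def relevance_fn(self) -> Callable[[EventFlags], bool]:
        if callable(self.relevance):
            return self.relevance
        return RELEVANCE_RULES[self.relevance]


@dataclass
class CleaningReport:
    """Counts removed per step plus the device clock corrections applied."""

    input_total: int = 0
    removed_test_users: int = 0
    removed_duplicates: int = 0
    removed_irrelevant: int = 0
    removed_out_of_window: int = 0
    corrected_devices: dict[str, float] = dc_field(default_factory=dict)  # minutes
    uncorrectable_devices: list[str] = dc_field(default_factory=list)
    output_total: int = 0

    @property
    def balanced(self) -> bool:
        removed = (
            self.removed_test_users
            + self.removed_duplicates
            + self.removed_irrelevant
            + self.removed_out_of_window
        )
        return self.input_total - removed == self.output_total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_total", self.input_total),
            ("removed_test_users", self.removed_test_users),
            ("removed_duplicates", self.removed_duplicates),
            ("removed_irrelevant", self.removed_irrelevant),
            ("removed_out_of_window", self.removed_out_of_window),
            ("devices_corrected", len(self.corrected_devices)),
            ("devices_uncorrectable", len(self.uncorrectable_devices)),
            ("output_total", self.output_total),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])

    def to_text(self) -> str:
        lines = [f"{row.step:>24}: {row.count}" for row in self.to_frame().itertuples()]
        for dev, minutes in sorted(self.corrected_devices.items()):
            lines.append(f"{'corrected ' + dev:>24}: {minutes:+.1f} min")
        for dev in self.uncorrectable_devices:
            lines.append(f"{'uncorrectable ' + dev:>24}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def exclude_test_users(logs: list[EventLog], config: CleaningConfig) -> list[EventLog]:
    """Drop every log whose user id is a known test account."""
    if not config.test_user_ids:
        return list(logs)
    return [l for l in logs if l.user_id not in config.test_user_ids]


def _dup_key(log: EventLog) -> tuple:
    # log_uid is deliberately excluded: the server may assign a fresh uid
    # when an identical event is re-transmitted.
    return (
        log.user_id,
        log.device_id,
        log.event_type,
        log.ui_page_id,
        log.event_timestamp,
        log.patient_id,
        log.record_id,
    )


def deduplicate(logs: list[EventLog]) -> list[EventLog]:
    """Keep one record per duplicate key, the first by (server ts, file order)."""
    order = sorted(range(len(logs)), key=lambda i: (logs[i].server_timestamp, i))
    seen: set[tuple] = set()
    keep = [False] * len(logs)
    for i in order:
        key = _dup_key(logs[i])
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return [l for l, k in zip(logs, keep) if k]


def filter_relevant(
    logs: list[EventLog],
    catalog: EventCatalog = DEFAULT_CATALOG,
    config: CleaningConfig | None = None,
) -> list[EventLog]:
    """Keep events whose catalog flags satisfy the relevance rule.

    Event types absent from the catalog are treated as not relevant and
    dropped (their semantics are unknown, so they cannot feed encounter
    reconstruction).
    """
    rule = (config or CleaningConfig()).relevance_fn()
    out = []
    for l in logs:
        if l.event_type in catalog and rule(catalog[l.event_type]):
            out.append(l)
    return out


def _estimate_offsets(
    logs: list[EventLog], config: CleaningConfig
) -> tuple[dict[str, timedelta], list[str]]:
    """Per-device clock offset: median of (reference ts − event ts).

    The reference is the GPS timestamp when a fix is attached (satellite
    time: no transmission delay, immune to the device clock) and the server
    receipt timestamp otherwise.  The median resists a handful of delayed
    transmissions.
    """
    by_device: dict[str, list[float]] = {}
    for l in logs:
        ref = l.geo.ts if l.geo is not None else l.server_timestamp
        by_device.setdefault(l.device_id, []).append(
            (ref - l.event_timestamp).total_seconds()
        )
    threshold = config.skew_threshold_minutes * 60.0
    offsets: dict[str, timedelta] = {}
    uncorrectable: list[str] = []
    for dev, deltas in by_device.items():
        off = median(deltas)
        if abs(off) > threshold:
            if len(deltas) < config.min_logs_for_offset:
                uncorrectable.append(dev)
            else:
                offsets[dev] = timedelta(seconds=off)
    return offsets, uncorrectable


def impute_timestamps(
    logs: list[EventLog],
    config: CleaningConfig,
    report: CleaningReport | None = None,
) -> list[EventLog]:
    """Correct event/device timestamps on devices with a wrongly set clock.

    Devices whose estimated offset exceeds the skew threshold have all their
    event and device timestamps shifted by the estimated offset; smaller
    disagreement is attributed to transmission latency and left alone.
    Devices with too few logs to estimate reliably are flagged and left
    unshifted.  Records are copied, never mutated in place.
    """
    offsets, uncorrectable = _estimate_offsets(logs, config)
    if report is not None:
        report.corrected_devices.update(
            {d: off.total_seconds() / 60.0 for d, off in offsets.items()}
        )
        report.uncorrectable_devices.extend(uncorrectable)
    if not offsets:
        return list(logs)
    out = []
    for l in logs:
        off = offsets.get(l.device_id)
        if off is None:
            out.append(l)
        else:
            # clamp to the server receipt time: transport cannot precede the
            # event, so a median offset overshooting a quickly-delivered log
            # is pulled back to the hard bound
            corrected = min(l.event_timestamp + off, l.server_timestamp)
            out.append(
                EventLog(
                    log_uid=l.log_uid,
                    event_type=l.event_type,
                    ui_page_id=l.ui_page_id,
                    device_id=l.device_id,
                    user_id=l.user_id,
                    device_timestamp=l.device_timestamp + off,
                    event_timestamp=corrected,
                    server_timestamp=l.server_timestamp,
                    geo=l.geo,
                    patient_id=l.patient_id,
                    record_id=l.record_id,
                )
            )
    return out


def filter_window(logs: list[EventLog], config: CleaningConfig) -> list[EventLog]:
    """Keep logs whose local event date is inside the study window (inclusive)."""
    start, end = config.study_window
    return [l for l in logs if start <= local_date(l.event_timestamp) <= end]


def clean(
    logs: list[EventLog],
    config: CleaningConfig | None = None,
    catalog: EventCatalog = DEFAULT_CATALOG,
) -> tuple[list[EventLog], CleaningReport]:
    """Run the full cleaning pipeline and return the surviving logs + report.

    The report balances exactly: input − Σ removed = output.  Applying
    ``clean`` to its own output changes nothing.
    """
    config = config or CleaningConfig()
    report = CleaningReport(input_total=len(logs))

    step = exclude_test_users(logs, config)
    report.removed_test_users = len(logs) - len(step)

    deduped = deduplicate(step)
    report.removed_duplicates = len(step) - len(deduped)

    relevant = filter_relevant(deduped, catalog, config)
    report.removed_irrelevant = len(deduped) - len(relevant)

    imputed = impute_timestamps(relevant, config, report)

    windowed = filter_window(imputed, config)
    report.removed_out_of_window = len(imputed) - len(windowed)

    report.output_total = len(windowed)
    return windowed, report
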