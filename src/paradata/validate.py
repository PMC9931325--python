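"""Concordance of log-derived workdays with EMR form submissions.

Usage logs are only worth analysing if they agree with an independent
record of the same work.  The check: per provider, count unique workdays as
seen by the logs and as seen by the EMR (dates of submitted forms), and
correlate the two count vectors with Pearson's r.  The log count can only
exceed the EMR count — forms opened but never completed exist in the logs
alone — so per-provider violations of that superset relation are also
reported as a data-integrity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .log_io import EmrSubmission, local_date

__all__ = ["ValidationResult", "workdays_from_emr", "pearson_workdays", "simulated_concordance"]


@dataclass
class ValidationResult:
    """Pearson concordance between log and EMR per-provider workday counts."""

    per_provider: list[tuple[str, int, int]]  # (provider, log days, emr days)
    r: float
    df: int
    p_value: float
    n: int
    excluded: list[str] = dc_field(default_factory=list)
    superset_violations: int = 0
    zero_variance: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_provider, columns=["provider_id", "log_workdays", "emr_workdays"]
        )

    def to_text(self) -> str:
        lines = [
            f"providers compared : {self.n}",
            f"Pearson r({self.df}) = {self.r:.2f}, two-sided p = {self.p_value:.2g}",
            f"superset violations: {self.superset_violations}",
        ]
        if self.excluded:
            lines.append(f"excluded (absent from one source): {', '.join(self.excluded)}")
        if self.zero_variance:
            lines.append("WARNING: zero variance in one source; r undefined")
        return "\n".join(lines)


def workdays_from_emr(emr: Iterable[EmrSubmission]) -> dict[str, set[date]]:
    """Unique local encounter dates per provider, from submitted forms."""
    out: dict[str, set[date]] = {}
    for sub in emr:
        out.setdefault(sub.provider_id, set()).add(local_date(sub.encounter_datetime))
    return out


def pearson_workdays(
    log_days: Mapping[str, set[date]],
    emr_days: Mapping[str, set[date]],
) -> ValidationResult:
    """Correlate per-provider workday counts from the two sources.

    Only providers present in both sources enter the correlation (a provider
    who never used the app contributes nothing to compare); the excluded
    ones are listed, not silently dropped.  p comes from the usual
    t-transform with n−2 degrees of freedom, two-sided.

    Raises ``ValueError`` with fewer than 3 paired providers.
    """
    shared = sorted(set(log_days) & set(emr_days))
    excluded = sorted((set(log_days) | set(emr_days)) - set(shared))
    if len(shared) < 3:
        raise ValueError(
            f"insufficient providers: need >= 3 present in both sources, got {len(shared)}"
        )
    pairs = [(p, len(log_days[p]), len(emr_days[p])) for p in shared]
    x = np.array([a for _, a, _ in pairs], dtype=float)
    y = np.array([b for _, _, b in pairs], dtype=float)

    violations = 0
    for p in set(log_days) | set(emr_days):
        n_log = len(log_days.get(p, ()))
        n_emr = len(emr_days.get(p, ()))
        if n_emr > n_log:
            violations += 1

    zero_var = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if zero_var:
        r, p_value = float("nan"), float("nan")
    else:
        res = stats.pearsonr(x, y)
        r, p_value = float(res.statistic), float(res.pvalue)

    return ValidationResult(
        per_provider=pairs,
        r=r,
        df=len(shared) - 2,
        p_value=p_value,
        n=len(shared),
        excluded=excluded,
        superset_violations=violations,
        zero_variance=zero_var,
    )


def simulated_concordance(
    n_replicates: int = 200,
    seed: int = 0,
    **config_overrides,
) -> list[float]:
    """Pearson r between log and EMR workday counts on simulated cohorts.

    Each replicate simulates the default cohort design (13 providers, 91-day
    window, heterogeneous daily work probabilities, 5% incomplete forms)
    with no duplicates, test users, clock skew or out-of-window noise,
    runs the full clean -> sessionize pipeline on the logs, and correlates
    per-provider workday counts against the EMR-derived ones.  Returns one r
    per replicate; replicates with fewer than 3 providers in both sources
    are skipped (rare: a provider must log nothing all window).
    """
    from .cleaning import CleaningConfig, clean
    from .metrics import days_worked
    from .sessionize import build_encounters
    from .synthetic import SimulationConfig, generate_cohort

    base = dict(
        incomplete_form_rate=0.05,
        duplicate_rate=0.0,
        clock_skew_minutes={},
        n_test_users=0,
        out_of_window_rate=0.0,
    )
    base.update(config_overrides)
    rs: list[float] = []
    for i in range(n_replicates):
        cfg = SimulationConfig(rng_seed=(seed * 1_000_003 + i) % 2**31, **base)
        logs, emr, _ = generate_cohort(cfg)
        cleaning_cfg = CleaningConfig(study_window=(cfg.window_start, cfg.window_end))
        cleaned, _ = clean(logs, cleaning_cfg)
        records = build_encounters(cleaned)
        try:
            result = pearson_workdays(days_worked(records), workdays_from_emr(emr))
        except ValueError:
            continue
        if not result.zero_variance:
            rs.append(result.r)
    return rs
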