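# Methods

This note documents the models, parameters and design choices behind the
pipeline, and what the synthetic cohort does and does not establish about
real data.

## Data model

An **event log** is one UI navigation/action event with three timestamps:

- `event_timestamp` — when the app recorded the event (stamped from the
  device clock, so wrong whenever the clock is wrong);
- `device_timestamp` — the raw device clock reading (normally equal to the
  event timestamp);
- `server_timestamp` — when the log server received the record (correct,
  but late by the transmission delay; logs may be retransmitted, creating
  duplicates with fresh uids).

An optional GPS fix adds a fourth timestamp from the satellite clock:
correct *and* delay-free, which makes it the best reference for clock-skew
estimation when present.

Event semantics are data, not code: an `EventCatalog` maps each event type
to flags (`encounter_related`, `opens_form`, `completes_form`,
`drafts_form`, `registers_patient`). The default catalog covers twelve
common types; a deployment logging a larger vocabulary supplies its own
catalog as YAML. Flag implications (`completes_form ⇒ encounter_related`,
`opens_form ⇒ encounter_related`) are validated at construction.

All analysis is single-timezone (UTC+03:00); "local date" and "local time"
mean that offset throughout.

## Cleaning

Steps run in a fixed order; each one's removals are tallied so that
`input − Σ removed = output` exactly.

1. **Test users** — drop all logs from configured test accounts.
2. **Duplicates** — duplicate key is
   (user, device, event type, UI page, event timestamp, patient, form id);
   the log uid is excluded because a re-transmission can be assigned a
   fresh uid for an identical event. The first record by (server
   timestamp, file order) survives.
3. **Relevance** — keep events whose flags satisfy the relevance rule
   (default: `encounter_related`); unknown event types are dropped since
   their semantics are unknown.
4. **Clock-skew imputation** — per device, the offset is the *median* of
   (reference − event) over that device's logs, where the reference is the
   GPS timestamp when present and the server timestamp otherwise. The
   median resists a few delayed transmissions; GPS references make the
   estimate exact. If |offset| exceeds the threshold (default 30 min —
   below that, disagreement is attributed to transmission latency, not a
   wrong clock), event and device timestamps are shifted by the offset.
   Corrected event timestamps are clamped to the server timestamp, since
   transport cannot precede the event. Devices with fewer than 3 logs and
   a large offset are flagged uncorrectable and left unshifted.
5. **Study window** — keep logs whose local event date lies inside the
   window, both endpoints inclusive (default 2019-12-02..2020-03-02).

Window filtering **must** follow imputation: a record from a device hours
off may belong in-window only once corrected. A regression test pins this
ordering. The composed pipeline is idempotent: a second pass removes
nothing and shifts nothing (post-correction residual offsets are below the
threshold by construction).

## Sessionization

One `EncounterRecord` per (provider, form-instance id): start at the first
form-open event, end at the form-save (else the last event touching the
instance), `complete` iff a save-complete event exists. Records are dated
by their **completion** time — evening batch entry is evening work. A form
re-opened after more than `resume_gap_max` (default 12 h) starts a new
active segment, and the duration is the sum of segment spans rather than
the wall-clock span, so multi-day drafts do not inflate encounter length.
When the client sent no form id, time-contiguous same-patient activity
(gaps ≤ 30 min) is grouped into one encounter. A form-save with no
preceding open becomes a zero-duration complete record by default
(configurable to drop). Encounter-related logs carrying neither a form id
nor a patient id cannot be attributed and are ignored; all others map to
exactly one record.

## Metrics

- **Days worked** — unique local dates with ≥1 encounter record, complete
  or not. Incomplete forms count: they are evidence of work even though
  they never reach the EMR.
- **Patients per day** — distinct patient ids per provider-date
  (registration-only contacts included); provider totals are sums of the
  daily counts, so per-day and per-provider tables reconcile exactly.
- **Work hours** — both the wall-clock span (first to last
  encounter-related activity) and active time (sum of encounter durations)
  are reported; active time is the headline since an 11-hour span may
  contain 40 minutes of recording.
- **After hours** — a record is after-hours iff its completion time falls
  outside [08:00, 17:00) local or on a weekend (default schedule
  Monday–Friday; all parameters configurable). The interval is half-open:
  completion at exactly 17:00 is after hours.
- **Retrospective entry** — a maximal same-provider same-day run of ≥3
  records, each ≤3 min long with inter-record gaps ≤2 min, is flagged.
  Genuine encounters take longer and do not chain at that pace; the
  thresholds are exposed as parameters because they encode a qualitative
  judgement, not a measured boundary.

## Validation against the EMR

Per provider, workday counts from logs and from EMR submission dates are
paired; Pearson's r is computed over providers present in both sources
(scipy's implementation; p two-sided from the t transform with n−2 df).
Providers absent from one source — e.g. recruited providers who never used
the app — are excluded and listed, not silently dropped. Fewer than 3
paired providers is an error; zero variance in either vector flags r as
undefined rather than crashing. Because incomplete forms are log-only,
per-provider log workdays must be a superset of EMR workdays; violations
are counted as a data-integrity signal and are zero on all simulations.

## The synthetic cohort

Defaults describe a 13-provider, 91-day chronic-disease program:

| parameter | default | rationale |
|---|---|---|
| daily work probability | U(0.05, 0.7) per provider | wide between-provider variability; a couple of heavy users dominate volume |
| patients per workday | 1 + NegBin(1.6, ·), mean 14.5, cap 53 | cohort mean ≈14.5, right-skewed, max ≈53 |
| point-of-care fraction | 0.8 | with evening live work 0.05, yields an after-hours share in the low-to-mid 20s%, matching the scale of observed evening entry |
| live encounter duration | U(5, 30) min | plausible range for a hypertension visit form |
| retro duration / gap | U(0.5, 2) / U(0.2, 1) min | rapid batch typing: short sessions, short gaps |
| incomplete-form rate | 0.05 | free parameter (not observable externally); kept small |
| duplicate rate / out-of-window rate | 0.02 / 0.01 | plausible transport noise levels |
| clock skew | one device +180 min | one misconfigured tablet per cohort |
| test users | 2 | pre-deployment accounts inside the window |
| weekend workers | first 5 providers | a minority works weekends, at 0.3× their weekday probability |
| transmission delay | U(10, 180) s | bounds the achievable skew-correction accuracy |
| GPS fix probability | 0.7 | rural coverage is good but not universal |

Retrospective batches are modelled as: the provider sees k patients on
paper during the day and types the forms in one evening run (18:00–20:00),
so retro records are short, tightly spaced, and dated the same day. Every
complete encounter emits exactly one EMR submission; incomplete forms emit
a draft-save and nothing in the EMR, which is what makes log workdays a
strict superset when the incomplete rate is positive. All randomness flows
from one seed; identical configs give byte-identical files.

What the simulator does **not** model: multi-day drafts, providers sharing
devices, patient transfers between providers, GPS drift, server outages,
and any fitting to the source program's empirical distributions (its raw
logs are not public). Tests passing on this cohort therefore show the
pipeline recovers *known structure of this kind*; they do not certify
behaviour on pathologies the generator omits.

## Numerical and scale choices

- Skew estimation uses the sample median (exact, no interpolation
  surprises at these n); offsets are exact when GPS references dominate and
  otherwise biased upward by the median transmission delay — hence the
  accuracy statement "within the transmission-delay spread", verified
  against ground truth.
- Negative inter-encounter gaps (overlapping records) are clipped to zero.
- `percentage()` rounds to one decimal, the precision used in all reports.
- The acceptance script uses 200 simulation replicates and the test suite
  uses cohorts of 4–13 providers over 3–13 weeks; both complete in about a
  minute on one CPU while keeping Monte-Carlo noise on the median r far
  below the margin being tested.

## Known limitations

- Encounter identity depends on the form-instance id when present; clients
  that reuse ids across patients would merge encounters (not observed in
  the modelled app, unguarded).
- The after-hours rule is a fixed schedule; programs with shift work need
  per-provider schedules, which the `WorkSchedule` type does not model.
- Retrospective flagging is a heuristic on durations and gaps; a fast
  typist doing live care in under 3 minutes per form would be
  false-positive if they chain ≥3 such forms.
- Workday concordance is a count correlation, not a date-by-date
  agreement measure; two sources could agree on counts while disagreeing
  on dates (the superset check partially guards this).
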