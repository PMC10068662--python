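# Methods

## Architecture

The package follows the classic top-down warehousing pattern: a normalized
row-oriented warehouse ("one row per record") loaded incrementally from
validated staging copies of the sources, with denormalized wide tables
derived from it on demand. Granularity is one second for operating-room
data and one day for hospital-stay data; all timestamps are UTC ISO-8601
and all intervals are half-open `[start, end)`. The warehouse is a single
SQLite file created by the package itself — no database server — with
dimension tables (signals, drugs, events), fact tables carrying a quality
flag and an anchor date, and operational tables (`load_log`, `dq_result`,
`quarantine`) for run bookkeeping.

## Synthetic sources

The generator is first-class code, not a fixture: it defines the study
conditions every downstream stage is tested under.

**Vitals model.** Each signal is a baseline plus AR(1) noise
(`x_t = 0.9 x_{t-1} + ε`, stationary sd per signal) on a fixed 30 s grid
inside each operating-room window, clipped to a clean physiological band:
MAP 85 ± (72–108) mmHg, SBP 120, DBP 65, HR 75 bpm, SpO2 98 %, EtCO2
35 mmHg, tidal volume 450 mL. The clean bands deliberately stay on the
safe side of the shipped example thresholds (MAP 65/50, SpO2 90, HR
45/100), so an un-injected series never crosses them and every crossing in
a generated bundle is attributable to the truth log. The signal list and
its distributional parameters are the package's own choice of a realistic
monitor export; nothing downstream depends on their exact values.

**Episode injection.** Requested excursions are placed as level shifts on
grid-aligned windows with a one-sample clean buffer on both sides
(episodes never merge, and detected boundaries equal logged boundaries).
All in-window samples are strictly beyond the threshold; the deepest
sample equals `threshold ∓ depth`. Expected episodes per intervention are
Poisson with the requested rate. An optional dropout rate removes
non-episode samples to exercise gap handling; it defaults to 0 so that
exact-recovery checks are meaningful.

**Corruptions.** `corrupt_bundle` applies six kinds at per-kind rates,
picking `round(rate · n_eligible)` rows, disjoint within a table, and logs
each row: nulled measurement identifiers, drug doses rescaled mg → g
(value ÷ 1000), measurement values shifted +10000 (beyond every
plausibility range), signal labels replaced by French-abbreviation
misspellings or monitor-brand variants, and hospital-stay dates shifted
+60 days so the patient's interventions fall outside every stay.

**What the generator does not emulate.** Pharmacokinetics, waveform-level
artefacts, inter-signal correlation (MAP and HR move independently),
center-to-center case-mix differences, and free-text fields. Passing tests
therefore demonstrate the pipeline's correctness contracts — exact episode
recovery, exact corruption accounting, window discipline — on data with
the stated cadence and noise structure, not performance on any real AIMS
export.

## ETL

**Linkage.** An intervention links to a stay iff the patient matches and
the room-entry date lies within `[admission, discharge]`. Where several
stays qualify, the one with the latest admission not after the
intervention wins (the most specific admission); residual ties go to the
smallest `stay_id`. Unlinked records are reported with a reason
(`missing_patient_id` / `no_candidate`), never dropped.

**Vocabulary.** Labels are normalized (case-fold, trim, collapse
whitespace, strip diacritics) and then synonym-mapped; unmapped normalized
labels become their own canonical form. The raw label is retained beside
the canonical code so concordance checks can count how many rows needed
cleaning.

**Quality flags.** One flag per measurement/drug row, assigned in the
order orphan → missing_value → bad_unit → out_of_range → ok (identity
problems before value problems; a null value cannot be range-checked).
Flags are computed on the staged values *before* unit standardization: the
flag documents whether the source expressed the value correctly, even when
the subsequent g → mg conversion repairs it. Only `ok` rows feed feature
extraction and the OMOP export.

**Load flows.** Every fact row carries an anchor date (stays: admission;
diagnoses/procedures/unit stays: their stay's admission; measurements,
events, biology: their own timestamp's date). Flow 1 loads low-volume
updatable facts over `[as_of − 365 d, as_of]`; flow 2 loads measurements
and events over `[as_of − 14 d, as_of]`. Both delete the warehouse rows in
the window and re-insert the staged in-window rows (sorted by natural key,
deduplicated), so a rerun on unchanged staging is a no-op and rows outside
the window are untouched. Patients are upserted as master data by flow 1.
A per-flow lock row rejects overlapping runs. Each run appends a
`load_log` entry with `rows_in = rows_loaded + rows_rejected`; rejected
rows are quarantined to a side table with reasons.

**Determinism contract.** Idempotence is asserted on a content checksum:
SHA-256 over every dimension and fact table's rows in canonical sorted
order. Operational tables are excluded (their run timestamps legitimately
differ), and SQLite page layout is not part of the contract.

## Episode features

The LOCF step model (sample *i* holds until the next sample, the gap cap,
or the period end — whichever comes first) was chosen over interpolation
because it is honest to sampled data (no invented crossing times), makes
time-below-threshold and area monotone in the threshold, and is trivially
checkable by brute force: on second-resolution data, rectangle sums equal
a per-second evaluation of the same step function exactly, and the test
suite asserts that equality on randomized gappy series.

Defaults: `max_gap` 300 s (a sample's influence stops after 5 min of
silence), `min_duration` 60 s (two samples; one-sample dips at 30 s
cadence are treated as artefacts), strict inequality for "beyond"
(MAP < 65 means strictly less). The shipped thresholds (MAP < 65 and < 50
mmHg, SpO2 < 90 %, HR > 100, HR < 45) are example configuration, not
clinical guidance, and every parameter is exposed per feature spec.
Summary features use standard definitions; the even-length median is the
midpoint of the two central order statistics (pandas default). A period
whose anchor events are missing or duplicated yields null features with a
reason code rather than an error.

## Datamarts and cohorts

Wide tables are rebuilt from scratch on demand (never patched); a
duplicate (key, feature) pair is an error, not a silent overwrite, and
non-null cell count equals input row count by construction. Cohort
predicates use three-valued logic: a comparison against a null cell
excludes the row — the conservative choice for inclusion criteria.
`cohort_summary` rounds half-up to one decimal using decimal arithmetic,
so 166/387 prints 42.9 rather than banker's-rounded 42.8.

## Data quality

Eleven built-in checks cover the four audit axes: completeness (required
identifiers and values present, all four anesthesia/surgery step events
per intervention), correctness (values within per-signal plausibility
ranges, units as configured), concordance (raw labels canonical,
operating-room date inside the linked stay, measurements inside the room
window), plausibility (discharge ≥ admission, death ≥ last discharge).
The same suite runs on transformed staging frames and on the loaded
warehouse; it never mutates either, and results persist to `dq_result`
keyed by run so indicator trends survive across loads. Failure-key samples
are capped at 50 per check. The shipped ranges and the required-event list
are illustrative defaults, configurable in the ETL config.

## OMOP export

CDM version is fixed at v5.4 column names. Conventions: one
VISIT_OCCURRENCE per hospital stay; one VISIT_DETAIL per operating-room
passage and per unit stay, child of the stay's visit; an unlinked
intervention is exported under a synthetic standalone visit and counted.
Vitals become MEASUREMENT rows (value + UCUM unit concept), drug boluses
become DRUG_EXPOSURE rows with start = end = administration time, step
events route to PROCEDURE_OCCURRENCE when their vocabulary entry has
domain `Procedure` and to OBSERVATION otherwise; PMSI procedure codes
always go to PROCEDURE_OCCURRENCE. The bundled mini-vocabulary
(`data/mini_vocab_synthetic.csv`) is a synthetic stand-in for the OMOP
vocabulary download; labels outside it receive deterministic fallback ids
in the reserved local range ≥ 2,000,000,000, allocated in sorted label
order so re-exports are byte-identical. Only `ok`-flagged rows are
exported; non-ok rows are the counted exclusions in the conservation
report.

## Federated logistic regression

At a shared β each center computes its exact score `Xᵀ(y − μ)`,
information `XᵀWX` (`μ = logistic(Xβ)`, `W = diag(μ(1−μ))`) and local
log-likelihood; all three are sums over rows, so aggregating them equals
computing them on the pooled data, and the federated Newton–Raphson path
is the pooled path to floating point. Numerics: start at β = 0, converge
when the aggregated gradient's max-norm ≤ 1e-8, cap at 25 iterations
(non-convergence is flagged, not raised). Confidence intervals are Wald at
95 % from the inverse aggregated information (half-width 1.959964 · SE).
No regularization: a singular information matrix raises an explicit
separation error, and so does convergence with essentially zero deviance
(total log-likelihood > −1e-6), which is the signature of complete
separation — mid-fit the certainty-fitted rows make the score vanish
without any matrix becoming singular. The privacy contract is structural:
the fitting loop only ever touches `CenterSummary` objects (aggregates
plus a sample size), never rows. The demonstration dataset
(`make_logistic_dataset`) is synthetic — intercept plus standard-normal
and Bernoulli covariates — and documented as such; it does not claim to
reproduce any clinical study's variables.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale, chosen so
the whole suite completes in well under a minute while still exercising
every contract: 12–40 patients per bundle over a 12-day span (so a single
two-week flow-2 window, or a handful of weekly ones, covers the stream),
≈ 50 interventions with ≈ 100 injected MAP < 65 episodes for recovery
checks, 200 randomized series for monotonicity, 100 randomized tables for
pivot round-trips, and n = 400 with 4 centers for the federated
equivalence check.

## Known limitations

Single-process SQLite (the run lock models, but does not enforce,
cross-process exclusion); no change-data-capture or scheduling — the
weekly cadence is the caller's responsibility; the OMOP export covers the
OR-centric tables, not the full CDM (no CONDITION_OCCURRENCE from
diagnoses, no cost/payer tables); episode definitions are configuration
with documented defaults, not validated clinical phenotypes; and the
federated module implements one model (binary logistic regression) without
secure aggregation — summaries are exchanged in the clear.
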