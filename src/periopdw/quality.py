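"""Four-axis data-quality checks and load-run monitoring.

Checks are grouped on the four axes used for clinical warehouse audits —
completeness (required fields and events present), correctness (values
within acceptable ranges, units as expected), concordance (agreement
between sources, e.g. the operating-room date falls within the linked
hospital stay), and plausibility (discharge after admission, death after
last discharge). The same suite runs against transformed staging frames
and against the loaded warehouse; running it never mutates either.

Results persist to a ``dq_result`` table keyed by run, so indicator
trends can be followed across loads.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .etl import ConfigError, EtlConfig, Warehouse

AXES = ("completeness", "correctness", "concordance", "plausibility")

MAX_FAILURE_KEYS = 50  # keep report samples readable


@dataclass(frozen=True)
class DqCheck:
    check_id: str
    axis: str
    scope: str  # table the check evaluates
    fn: Callable[[Mapping[str, pd.DataFrame]], tuple[int, list[str]]]

    def __post_init__(self):
        if self.axis not in AXES:
            raise ConfigError(f"check {self.check_id!r}: unknown axis {self.axis!r}")


@dataclass
class DqCheckResult:
    check_id: str
    axis: str
    scope: str
    n_evaluated: int
    n_failed: int
    failure_keys: list[str]

    @property
    def pass_rate(self) -> float:
        if self.n_evaluated == 0:
            return 1.0
        return 1.0 - self.n_failed / self.n_evaluated


@dataclass
class DqReport:
    run_id: str
    run_ts: datetime
    results: list[DqCheckResult] = field(default_factory=list)

    def all_pass(self) -> bool:
        return all(r.n_failed == 0 for r in self.results)

    def by_id(self, check_id: str) -> DqCheckResult:
        for r in self.results:
            if r.check_id == check_id:
                return r
        raise KeyError(check_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "check_id": r.check_id,
                    "axis": r.axis,
                    "scope": r.scope,
                    "n_evaluated": r.n_evaluated,
                    "n_failed": r.n_failed,
                    "pass_rate": r.pass_rate,
                }
                for r in self.results
            ]
        )


def _null_mask(s: pd.Series) -> pd.Series:
    return s.isna() | (s.astype(object) == None)  # noqa: E711  (covers None in object cols)


def builtin_suite(config: EtlConfig) -> list[DqCheck]:
    """The shipped check suite; acceptable ranges and the required-event
    list come from the ETL config and are illustrative defaults."""

    def measurement_id_present(t):
        m = t["measurement"]
        bad = m.index[_null_mask(m["intervention_id"])]
        return len(m), [f"measurement[{i}]" for i in bad]

    def measurement_value_present(t):
        m = t["measurement"]
        bad = m.index[_null_mask(m["value"])]
        return len(m), [f"measurement[{i}]" for i in bad]

    def required_events_present(t):
        iv = t["intervention"]
        ev = t["event_record"]
        have = set(zip(ev["intervention_id"], ev["event_label"]))
        failures = [
            f"{iv_id}:{label}"
            for iv_id in iv["intervention_id"]
            for label in config.required_events
            if (iv_id, label) not in have
        ]
        return len(iv) * len(config.required_events), failures

    def measurement_in_range(t):
        m = t["measurement"]
        if "quality_flag" in m.columns:
            bad = m.index[m["quality_flag"] == "out_of_range"]
        else:
            bad = []
        return len(m), [f"measurement[{i}]" for i in bad]

    def measurement_unit(t):
        m = t["measurement"]
        bad = m.index[m["quality_flag"] == "bad_unit"] if "quality_flag" in m.columns else []
        return len(m), [f"measurement[{i}]" for i in bad]

    def drug_unit(t):
        ev = t["event_record"]
        drugs = ev[ev["kind"] == "drug"]
        bad = drugs.index[drugs["quality_flag"] == "bad_unit"] if "quality_flag" in ev.columns else []
        return len(drugs), [f"event_record[{i}]" for i in bad]

    def vocabulary_canonical(t):
        m = t["measurement"]
        if "raw_label" not in m.columns:
            return len(m), []
        bad = m.index[m["raw_label"].astype(str) != m["signal_code"].astype(str)]
        return len(m), [f"measurement[{i}]" for i in bad]

    def intervention_in_stay(t):
        iv = t["intervention"]
        stays = t["hospital_stay"]
        evaluated = iv[~_null_mask(iv["patient_id"])]
        by_patient = {pid: g for pid, g in stays.groupby("patient_id")}
        failures = []
        for row in evaluated.itertuples(index=False):
            d = pd.Timestamp(row.room_entry_ts).normalize()
            cand = by_patient.get(row.patient_id)
            ok = cand is not None and (
                (cand["admission_date"] <= d) & (d <= cand["discharge_date"])
            ).any()
            if not ok:
                failures.append(row.intervention_id)
        return len(evaluated), failures

    def measurement_in_room_window(t):
        m = t["measurement"]
        iv = t["intervention"].set_index("intervention_id")
        linked = m[~_null_mask(m["intervention_id"])]
        entry = linked["intervention_id"].map(iv["room_entry_ts"])
        exit_ = linked["intervention_id"].map(iv["room_exit_ts"])
        ts = pd.to_datetime(linked["ts"])
        bad = linked.index[~((entry <= ts) & (ts <= exit_))]
        return len(linked), [f"measurement[{i}]" for i in bad]

    def stay_dates_ordered(t):
        st = t["hospital_stay"]
        bad = st.loc[st["discharge_date"] < st["admission_date"], "stay_id"]
        return len(st), list(bad)

    def death_after_discharge(t):
        deaths = t["death"]
        st = t["hospital_stay"]
        last_discharge = st.groupby("patient_id")["discharge_date"].max()
        evaluated = deaths[deaths["patient_id"].isin(last_discharge.index)]
        bad = evaluated[
            pd.to_datetime(evaluated["death_date"])
            < evaluated["patient_id"].map(last_discharge)
        ]
        return len(evaluated), list(bad["patient_id"])

    return [
        DqCheck("measurement_id_present", "completeness", "measurement", measurement_id_present),
        DqCheck("measurement_value_present", "completeness", "measurement", measurement_value_present),
        DqCheck("required_events_present", "completeness", "event_record", required_events_present),
        DqCheck("measurement_in_range", "correctness", "measurement", measurement_in_range),
        DqCheck("measurement_unit", "correctness", "measurement", measurement_unit),
        DqCheck("drug_unit", "correctness", "event_record", drug_unit),
        DqCheck("vocabulary_canonical", "concordance", "measurement", vocabulary_canonical),
        DqCheck("intervention_in_stay", "concordance", "intervention", intervention_in_stay),
        DqCheck("measurement_in_room_window", "concordance", "measurement", measurement_in_room_window),
        DqCheck("stay_dates_ordered", "plausibility", "hospital_stay", stay_dates_ordered),
        DqCheck("death_after_discharge", "plausibility", "death", death_after_discharge),
    ]


def run_dq(
    tables: Warehouse | Mapping[str, pd.DataFrame],
    suite: Sequence[DqCheck],
) -> DqReport:
    """Evaluate a check suite against the warehouse or transformed frames.

    Read-only: the warehouse is never mutated (persist results separately
    with :func:`persist_dq`). Deterministic for fixed inputs.
    """
    if not suite:
        raise ConfigError("empty check suite")
    if isinstance(tables, Warehouse):
        names = set(tables.table_names())
        needed = {c.scope for c in suite}
        missing = needed - names
        if missing:
            raise ConfigError(f"check suite references missing table(s): {sorted(missing)}")
        frames = {name: tables.table(name) for name in
                  {"measurement", "event_record", "intervention", "hospital_stay", "death"} & names}
    else:
        frames = dict(tables)
        missing = {c.scope for c in suite} - set(frames)
        if missing:
            raise ConfigError(f"check suite references missing table(s): {sorted(missing)}")

    report = DqReport(run_id=uuid.uuid4().hex[:12], run_ts=datetime.now())
    for check in suite:
        n_evaluated, failures = check.fn(frames)
        report.results.append(
            DqCheckResult(
                check_id=check.check_id,
                axis=check.axis,
                scope=check.scope,
                n_evaluated=int(n_evaluated),
                n_failed=len(failures),
                failure_keys=[str(k) for k in failures[:MAX_FAILURE_KEYS]],
            )
        )
    return report


def persist_dq(wh: Warehouse, report: DqReport) -> None:
    """Append check results to the dq_result history table."""
    cur = wh.con.cursor()
    cur.executemany(
        "INSERT INTO dq_result VALUES (?,?,?,?,?,?,?,?,?)",
        [
            (
                report.run_id, report.run_ts.isoformat(), r.check_id, r.axis,
                r.scope, r.n_evaluated, r.n_failed, r.pass_rate,
                ";".join(r.failure_keys),
            )
            for r in report.results
        ],
    )
    wh.con.commit()


def monitor_loads(load_log: pd.DataFrame) -> dict:
    """Summarize load runs: per-flow last status and row-count trend,
    failed runs with messages, and conservation breaches
    (rows_in != rows_loaded + rows_rejected)."""
    report: dict = {"flows": {}, "failed_runs": [], "inconsistent_runs": []}
    if load_log.empty:
        return report
    for flow_id, grp in load_log.groupby("flow_id"):
        grp = grp.sort_values("started_ts")
        report["flows"][int(flow_id)] = {
            "n_runs": int(len(grp)),
            "last_status": str(grp["status"].iloc[-1]),
            "rows_loaded_trend": [int(x) for x in grp["rows_loaded"]],
        }
    failed = load_log[load_log["status"] != "success"]
    report["failed_runs"] = [
        {"run_id": r.run_id, "flow_id": int(r.flow_id), "messages": r.messages}
        for r in failed.itertuples(index=False)
    ]
    bad = load_log[
        load_log["rows_in"] != load_log["rows_loaded"] + load_log["rows_rejected"]
    ]
    report["inconsistent_runs"] = [str(r) for r in bad["run_id"]]
    return report
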