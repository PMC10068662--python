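"""Extract–transform–load into a normalized single-file warehouse.

The pipeline mirrors source extracts into a staging area (never touching
the originals), transforms them — record linkage between anesthesia
records and hospital stays, vocabulary cleaning, unit standardization,
quality flagging, procedure-code grouping — and loads a SQLite warehouse
through two incremental sliding-window flows:

* flow 1: low-volume, updatable facts (patients, interventions, stays,
  diagnoses, procedures, biology, deaths) over a one-year window;
* flow 2: high-volume, append-style facts (measurements, drug
  administrations and step events) over a two-week window.

Both flows overwrite their window (delete-then-insert on the anchor
date), so re-running on unchanged staging is idempotent and rows outside
the window are never touched. Every run is logged to ``load_log``.

Quality flags are computed on the staged values *before* unit
standardization, so the flag documents whether the source expressed the
value with a correct unit even when the conversion step can repair it.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import sqlite3
import unicodedata
import uuid
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    ANALYTES,
    BUNDLE_TABLES,
    BRAND_VARIANTS,
    DATE_COLUMNS,
    DRUGS,
    ECC_CODES,
    FLOAT_COLUMNS,
    MISSPELLED_VARIANTS,
    SIGNALS,
    STEP_EVENTS,
    TS_COLUMNS,
    SourceBundle,
)


class ConfigError(ValueError):
    """Invalid ETL configuration (conflicting synonyms, bad unit rules...)."""


class LoadError(RuntimeError):
    """Source file violates the expected schema; names file, row, column."""


class RunRejectedError(RuntimeError):
    """A load flow is already running against this warehouse."""


def validate_unit_rules(unit_rules: list[tuple[str, str, float]]) -> None:
    seen: dict[tuple[str, str], float] = {}
    graph: dict[str, str] = {}
    for frm, to, factor in unit_rules:
        if factor <= 0:
            raise ConfigError(f"unit rule {frm}->{to}: factor must be > 0")
        key = (frm, to)
        if key in seen and seen[key] != factor:
            raise ConfigError(f"duplicate unit rule {frm}->{to} with different factors")
        seen[key] = factor
        graph[frm] = to
    for start in graph:
        node, seen_nodes = start, {start}
        while node in graph:
            node = graph[node]
            if node in seen_nodes:
                raise ConfigError(f"unit rule cycle involving {start!r}")
            seen_nodes.add(node)


QUALITY_FLAGS = ("ok", "bad_unit", "out_of_range", "missing_value", "orphan")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class EtlConfig:
    """Ranges, unit rules, synonyms and code groupings driving the transform.

    signal_ranges: canonical signal -> (lo, hi, allowed unit)
    drug_units:    canonical drug -> allowed dose unit
    unit_rules:    (from_unit, to_unit, factor) conversions to standard units
    synonyms:      raw label variant -> canonical label
    groupings:     feature name -> set of procedure codes
    required_events: step labels every intervention must carry
    """

    signal_ranges: dict[str, tuple[float, float, str]]
    drug_units: dict[str, str]
    unit_rules: list[tuple[str, str, float]]
    synonyms: dict[str, str]
    groupings: dict[str, set[str]]
    required_events: list[str]

    def validate(self) -> "EtlConfig":
        validate_unit_rules(self.unit_rules)
        norm_seen: dict[str, str] = {}
        for variant, canonical in self.synonyms.items():
            nv = normalize_label(variant)
            if nv in norm_seen and norm_seen[nv] != canonical:
                raise ConfigError(f"synonym conflict: {variant!r} maps to two canonicals")
            norm_seen[nv] = canonical
        for name, codes in self.groupings.items():
            if not codes:
                raise ConfigError(f"grouping {name!r} has an empty code set")
        return self

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "signal_ranges": {k: list(v) for k, v in self.signal_ranges.items()},
            "drug_units": self.drug_units,
            "unit_rules": [list(r) for r in self.unit_rules],
            "synonyms": self.synonyms,
            "groupings": {k: sorted(v) for k, v in self.groupings.items()},
            "required_events": self.required_events,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EtlConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            signal_ranges={k: tuple(v) for k, v in payload["signal_ranges"].items()},
            drug_units=payload["drug_units"],
            unit_rules=[tuple(r) for r in payload["unit_rules"]],
            synonyms=payload["synonyms"],
            groupings={k: set(v) for k, v in payload["groupings"].items()},
            required_events=payload["required_events"],
        ).validate()


def default_config() -> EtlConfig:
    """Config matching the bundled synthetic vocabulary and signal set."""
    synonyms: dict[str, str] = {}
    for code, variant in MISSPELLED_VARIANTS.items():
        synonyms[variant] = code
    for code, variant in BRAND_VARIANTS.items():
        synonyms[variant] = code
        synonyms[f"{code}-GE"] = code
    return EtlConfig(
        signal_ranges={
            s.code: (s.range_lo, s.range_hi, s.unit) for s in SIGNALS.values()
        },
        drug_units={name: unit for name, (unit, _, _) in DRUGS.items()},
        unit_rules=[("g", "mg", 1000.0), ("mg", "ug", 1000.0)],
        synonyms=synonyms,
        groupings={"extracorporeal_circulation": set(ECC_CODES)},
        required_events=list(STEP_EVENTS),
    ).validate()


# ---------------------------------------------------------------------------
# Mirroring (step 1): validated copies of the source extracts
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_date"],
    "interventions": ["intervention_id", "patient_id", "room_entry_ts", "room_exit_ts", "unit_label"],
    "measurements": ["intervention_id", "signal_code", "ts", "value", "unit_label"],
    "events": ["intervention_id", "event_label", "ts", "kind", "dose", "dose_unit"],
    "stays": ["stay_id", "patient_id", "admission_date", "discharge_date", "discharge_status"],
    "unit_stays": ["unit_stay_id", "stay_id", "unit_label", "start_ts", "end_ts"],
    "diagnoses": ["stay_id", "code"],
    "procedures": ["stay_id", "code"],
    "biology": ["patient_id", "analyte", "ts", "value", "unit"],
    "deaths": ["patient_id", "death_date"],
}


def _validate_source_file(table: str, path: Path) -> None:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing column(s) {missing}")
    for col in TS_COLUMNS.get(table, []) + DATE_COLUMNS.get(table, []):
        parsed = pd.to_datetime(df[col].replace("", None), format="ISO8601", errors="coerce")
        bad = df.index[df[col].ne("") & parsed.isna()]
        if len(bad):
            row = int(bad[0])
            raise LoadError(
                f"{path.name}: row {row}, column {col!r}: "
                f"unparseable timestamp {df.at[row, col]!r}"
            )
    for col in FLOAT_COLUMNS.get(table, []):
        parsed = pd.to_numeric(df[col].replace("", None), errors="coerce")
        bad = df.index[df[col].ne("") & parsed.isna()]
        if len(bad):
            row = int(bad[0])
            raise LoadError(
                f"{path.name}: row {row}, column {col!r}: "
                f"non-numeric value {df.at[row, col]!r}"
            )


def mirror(source_dir: str | Path, staging_dir: str | Path) -> Path:
    """Copy validated source extracts into the staging area.

    Originals are never modified; the staging copy is content-identical.
    Re-mirroring overwrites staging with an identical snapshot.
    """
    source, staging = Path(source_dir), Path(staging_dir)
    for table in BUNDLE_TABLES:
        path = source / f"{table}.csv"
        if not path.exists():
            raise LoadError(f"{path.name}: missing source file")
        _validate_source_file(table, path)
    staging.mkdir(parents=True, exist_ok=True)
    for table in BUNDLE_TABLES:
        shutil.copyfile(source / f"{table}.csv", staging / f"{table}.csv")
    return staging


def read_staging(staging_dir: str | Path) -> SourceBundle:
    return SourceBundle.from_csv(staging_dir)


# ---------------------------------------------------------------------------
# Transform primitives (step 3)
# ---------------------------------------------------------------------------


def normalize_label(label: str) -> str:
    """Case-fold, trim, collapse whitespace, strip diacritics."""
    s = unicodedata.normalize("NFKD", str(label))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return " ".join(s.casefold().split())


def clean_vocabulary(
    labels: Iterable[str], synonym_table: Mapping[str, str]
) -> dict[str, str]:
    """Map raw labels to canonical forms.

    Normalization first, then the synonym table (itself matched on
    normalized variants); labels with no synonym entry become their own
    normalized canonical form.
    """
    norm_syn: dict[str, str] = {}
    for variant, canonical in synonym_table.items():
        nv = normalize_label(variant)
        if nv in norm_syn and norm_syn[nv] != canonical:
            raise ConfigError(f"synonym conflict on variant {variant!r}")
        norm_syn[nv] = canonical
    out: dict[str, str] = {}
    for raw in labels:
        norm = normalize_label(raw)
        out[raw] = norm_syn.get(norm, norm)
    return out


@dataclass
class LinkageMap:
    """Intervention → hospital-stay assignment with unlinked reasons."""

    links: pd.DataFrame      # intervention_id, stay_id
    unlinked: pd.DataFrame   # intervention_id, reason


def link_records(interventions: pd.DataFrame, stays: pd.DataFrame) -> LinkageMap:
    """Link each anesthesia record to the hospital stay containing it.

    An intervention links to a stay iff both share the patient_id and the
    room-entry date falls within [admission_date, discharge_date]. Among
    multiple candidates the stay with the latest admission not after the
    intervention wins; residual ties go to the smallest stay_id.
    """
    links, unlinked = [], []
    stays_by_patient: dict[str, pd.DataFrame] = {
        pid: grp for pid, grp in stays.groupby("patient_id")
    }
    for iv in interventions.itertuples(index=False):
        pid = iv.patient_id
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            unlinked.append((iv.intervention_id, "missing_patient_id"))
            continue
        cand = stays_by_patient.get(pid)
        iv_date = pd.Timestamp(iv.room_entry_ts).normalize()
        if cand is not None:
            mask = (cand["admission_date"] <= iv_date) & (iv_date <= cand["discharge_date"])
            cand = cand[mask]
        if cand is None or cand.empty:
            unlinked.append((iv.intervention_id, "no_candidate"))
            continue
        best = cand.sort_values(
            ["admission_date", "stay_id"], ascending=[False, True]
        ).iloc[0]
        links.append((iv.intervention_id, best["stay_id"]))
    return LinkageMap(
        links=pd.DataFrame(links, columns=["intervention_id", "stay_id"]),
        unlinked=pd.DataFrame(unlinked, columns=["intervention_id", "reason"]),
    )


def group_codes(
    procedures: pd.DataFrame, grouping_def: tuple[str, set[str]]
) -> pd.Series:
    """Per-stay boolean feature: stay has >=1 procedure code in the set."""
    name, codes = grouping_def
    if not codes:
        raise ConfigError(f"grouping {name!r} has an empty code set")
    flags = procedures.groupby("stay_id")["code"].apply(
        lambda s: bool(set(s) & codes)
    )
    flags.name = name
    return flags


def convert_units(
    rows: pd.DataFrame,
    unit_rules: list[tuple[str, str, float]],
    value_col: str = "dose",
    unit_col: str = "dose_unit",
) -> pd.DataFrame:
    """Standardize units: value x factor, unit relabeled; others unchanged."""
    validate_unit_rules(unit_rules)
    out = rows.copy()
    for frm, to, factor in unit_rules:
        mask = out[unit_col] == frm
        out.loc[mask, value_col] = out.loc[mask, value_col].astype(float) * factor
        out.loc[mask, unit_col] = to
    return out


def flag_quality(
    measurements: pd.DataFrame,
    range_table: Mapping[str, tuple[float, float, str]],
    signal_col: str = "signal_code",
    value_col: str = "value",
    unit_col: str = "unit_label",
    id_col: str = "intervention_id",
) -> pd.DataFrame:
    """Attach one quality flag per row (ok / bad_unit / out_of_range /
    missing_value / orphan).

    Identity problems take precedence over value problems: orphan, then
    missing_value, then bad_unit, then out_of_range. Only ok rows feed
    feature extraction downstream.
    """
    unknown = set(measurements[signal_col].dropna()) - set(range_table)
    if unknown:
        raise ConfigError(f"signal(s) absent from range table: {sorted(unknown)}")
    out = measurements.copy()
    flags = np.full(len(out), "ok", dtype=object)
    ids = out[id_col]
    vals = out[value_col]
    for i, (sig, v, unit, rid) in enumerate(
        zip(out[signal_col], vals, out[unit_col], ids)
    ):
        if rid is None or (isinstance(rid, float) and np.isnan(rid)):
            flags[i] = "orphan"
        elif v is None or (isinstance(v, float) and np.isnan(v)):
            flags[i] = "missing_value"
        else:
            lo, hi, allowed = range_table[sig]
            if unit != allowed:
                flags[i] = "bad_unit"
            elif not (lo <= float(v) <= hi):
                flags[i] = "out_of_range"
    out["quality_flag"] = flags
    return out


def _flag_events(events: pd.DataFrame, drug_units: Mapping[str, str]) -> pd.DataFrame:
    out = events.copy()
    flags = np.full(len(out), "ok", dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        rid = row.intervention_id
        if rid is None or (isinstance(rid, float) and np.isnan(rid)):
            flags[i] = "orphan"
        elif row.kind == "drug":
            dose = row.dose
            if dose is None or (isinstance(dose, float) and np.isnan(dose)):
                flags[i] = "missing_value"
            elif drug_units.get(row.event_label) not in (None, row.dose_unit):
                flags[i] = "bad_unit"
    out["quality_flag"] = flags
    return out


# ---------------------------------------------------------------------------
# Full transform: staging bundle -> warehouse-ready frames
# ---------------------------------------------------------------------------


@dataclass
class TransformResult:
    frames: dict[str, pd.DataFrame]
    quarantine: pd.DataFrame  # table, reason, anchor_date, row (JSON)
    linkage: LinkageMap


def transform(bundle: SourceBundle, config: EtlConfig) -> TransformResult:
    """Apply linkage, vocabulary cleaning, flagging, unit conversion and
    code grouping; attach an anchor date to every fact row."""
    config.validate()
    quarantined: list[tuple[str, str, object, str]] = []

    # vocabulary cleaning on measurement signal labels
    meas = bundle.measurements.copy()
    vocab = clean_vocabulary(meas["signal_code"].dropna().unique(), config.synonyms)
    # canonical signal codes are the configured uppercase codes; labels that
    # normalize to a configured code (case-insensitively) resolve to it
    canon_by_norm = {normalize_label(c): c for c in config.signal_ranges}
    resolved = {
        raw: canon_by_norm.get(normalize_label(canon), canon)
        for raw, canon in vocab.items()
    }
    meas["raw_label"] = meas["signal_code"]
    meas["signal_code"] = meas["signal_code"].map(resolved)

    known = meas["signal_code"].isin(config.signal_ranges)
    for row in meas[~known].itertuples():
        quarantined.append(
            ("measurement", "unknown_signal", pd.Timestamp(row.ts).normalize(),
             json.dumps({"raw_label": row.raw_label, "ts": pd.Timestamp(row.ts).isoformat()}))
        )
    meas = meas[known].copy()

    meas = flag_quality(meas, config.signal_ranges)
    meas["anchor_date"] = pd.to_datetime(meas["ts"]).dt.normalize()

    events = _flag_events(bundle.events, config.drug_units)
    events = convert_units(events, config.unit_rules)
    events["anchor_date"] = pd.to_datetime(events["ts"]).dt.normalize()

    linkage = link_records(bundle.interventions, bundle.stays)
    iv = bundle.interventions.merge(linkage.links, on="intervention_id", how="left")
    iv = iv.merge(linkage.unlinked, on="intervention_id", how="left").rename(
        columns={"reason": "link_reason"}
    )
    iv["anchor_date"] = pd.to_datetime(iv["room_entry_ts"]).dt.normalize()

    stays = bundle.stays.copy()
    for name, codes in config.groupings.items():
        flags = group_codes(bundle.procedures, (name, codes))
        stays[name] = stays["stay_id"].map(flags).fillna(False).astype(int)
    stays["anchor_date"] = stays["admission_date"]

    stay_anchor = stays.set_index("stay_id")["admission_date"]
    diagnoses = bundle.diagnoses.copy()
    diagnoses["anchor_date"] = diagnoses["stay_id"].map(stay_anchor)
    procedures = bundle.procedures.copy()
    procedures["anchor_date"] = procedures["stay_id"].map(stay_anchor)
    unit_stays = bundle.unit_stays.copy()
    unit_stays["anchor_date"] = unit_stays["stay_id"].map(stay_anchor)
    biology = bundle.biology.copy()
    biology["anchor_date"] = pd.to_datetime(biology["ts"]).dt.normalize()
    deaths = bundle.deaths.copy()
    deaths["anchor_date"] = deaths["death_date"]

    frames = {
        "patient": bundle.patients.copy(),
        "intervention": iv,
        "measurement": meas,
        "event_record": events.rename(columns={}),
        "hospital_stay": stays,
        "unit_stay": unit_stays,
        "diagnosis": diagnoses,
        "procedure": procedures,
        "biology": biology,
        "death": deaths,
    }
    quarantine = pd.DataFrame(
        quarantined, columns=["table", "reason", "anchor_date", "row"]
    )
    return TransformResult(frames=frames, quarantine=quarantine, linkage=linkage)


# ---------------------------------------------------------------------------
# Warehouse (SQLite, single file)
# ---------------------------------------------------------------------------

FACT_NATURAL_KEYS: dict[str, list[str]] = {
    "intervention": ["intervention_id"],
    "measurement": ["intervention_id", "signal_code", "ts"],
    "event_record": ["intervention_id", "event_label", "ts"],
    "hospital_stay": ["stay_id"],
    "unit_stay": ["unit_stay_id"],
    "diagnosis": ["stay_id", "code"],
    "procedure": ["stay_id", "code"],
    "biology": ["patient_id", "analyte", "ts"],
    "death": ["patient_id"],
}

FLOW1_TABLES = [
    "intervention",
    "hospital_stay",
    "unit_stay",
    "diagnosis",
    "procedure",
    "biology",
    "death",
]
FLOW2_TABLES = ["measurement", "event_record"]

_OPS_TABLES = ("load_log", "dq_result", "load_lock", "quarantine")

_DT_SUFFIXES = ("_ts", "_date", "ts")


def _to_sql_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    return out


def _from_sql_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if col.endswith(_DT_SUFFIXES) or col in ("anchor_date", "window_start", "window_end"):
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


class Warehouse:
    """Row-oriented warehouse in a single SQLite file.

    Dimension tables describe the configured vocabularies; fact tables
    hold one row per source record with its quality flag and anchor date.
    Operational tables (load_log, dq_result, quarantine) are excluded
    from the content checksum so that run bookkeeping never breaks
    idempotence comparisons.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.con = sqlite3.connect(self.path)

    def close(self) -> None:
        self.con.close()

    # -- schema --------------------------------------------------------
    def init_schema(self, config: EtlConfig) -> None:
        cur = self.con.cursor()
        fact_cols = {
            "patient": REQUIRED_COLUMNS["patients"],
            "intervention": REQUIRED_COLUMNS["interventions"] + ["stay_id", "link_reason", "anchor_date"],
            "measurement": REQUIRED_COLUMNS["measurements"] + ["raw_label", "quality_flag", "anchor_date"],
            "event_record": REQUIRED_COLUMNS["events"] + ["quality_flag", "anchor_date"],
            "hospital_stay": REQUIRED_COLUMNS["stays"] + sorted(config.groupings) + ["anchor_date"],
            "unit_stay": REQUIRED_COLUMNS["unit_stays"] + ["anchor_date"],
            "diagnosis": REQUIRED_COLUMNS["diagnoses"] + ["anchor_date"],
            "procedure": REQUIRED_COLUMNS["procedures"] + ["anchor_date"],
            "biology": REQUIRED_COLUMNS["biology"] + ["anchor_date"],
            "death": REQUIRED_COLUMNS["deaths"] + ["anchor_date"],
        }
        for table, cols in fact_cols.items():
            cur.execute(f"CREATE TABLE IF NOT EXISTS {table} ({', '.join(cols)})")
        cur.execute(
            "CREATE TABLE IF NOT EXISTS dim_signal (signal_code, unit, range_lo, range_hi)"
        )
        cur.execute("CREATE TABLE IF NOT EXISTS dim_drug (drug_label, dose_unit)")
        cur.execute("CREATE TABLE IF NOT EXISTS dim_event (event_label)")
        cur.execute(
            "CREATE TABLE IF NOT EXISTS load_log (run_id, flow_id, started_ts, finished_ts,"
            " rows_in, rows_loaded, rows_rejected, window_start, window_end, status, messages)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS dq_result (run_id, run_ts, check_id, axis, scope,"
            " n_evaluated, n_failed, pass_rate, failure_keys)"
        )
        cur.execute("CREATE TABLE IF NOT EXISTS quarantine (run_id, tbl, reason, anchor_date, row)")
        cur.execute("CREATE TABLE IF NOT EXISTS load_lock (flow_id, acquired_ts)")
        if not cur.execute("SELECT COUNT(*) FROM dim_signal").fetchone()[0]:
            cur.executemany(
                "INSERT INTO dim_signal VALUES (?,?,?,?)",
                [(c, u, lo, hi) for c, (lo, hi, u) in sorted(config.signal_ranges.items())],
            )
            cur.executemany(
                "INSERT INTO dim_drug VALUES (?,?)", sorted(config.drug_units.items())
            )
            cur.executemany(
                "INSERT INTO dim_event VALUES (?)", [(e,) for e in config.required_events]
            )
        self.con.commit()

    # -- access --------------------------------------------------------
    def table(self, name: str) -> pd.DataFrame:
        df = pd.read_sql_query(f"SELECT * FROM {name}", self.con)
        return _from_sql_frame(df)

    def table_names(self) -> list[str]:
        rows = self.con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ).fetchall()
        return [r[0] for r in rows]

    def checksum(self, include_ops: bool = False) -> str:
        """sha256 over every table's rows in canonical sorted order.

        Content-level digest: two warehouses with identical logical state
        produce identical checksums regardless of SQLite page layout.
        """
        h = hashlib.sha256()
        for name in self.table_names():
            if not include_ops and name in _OPS_TABLES:
                continue
            df = pd.read_sql_query(f"SELECT * FROM {name}", self.con)
            df = df.astype(str).sort_values(list(df.columns), kind="mergesort")
            h.update(name.encode())
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


@dataclass
class LoadLog:
    run_id: str
    flow_id: int
    started_ts: datetime
    finished_ts: datetime
    rows_in: int
    rows_loaded: int
    rows_rejected: int
    window_start: date
    window_end: date
    status: str
    messages: str = ""


def _windowed_load(
    wh: Warehouse,
    tables: list[str],
    result: TransformResult,
    win_start: pd.Timestamp,
    win_end: pd.Timestamp,
) -> tuple[int, int, int]:
    """Delete-then-insert each table's rows whose anchor date lies in the
    closed window; returns (rows_in, rows_loaded, rows_rejected)."""
    cur = wh.con.cursor()
    rows_in = rows_loaded = 0
    for table in tables:
        staged = result.frames[table]
        anchor = pd.to_datetime(staged["anchor_date"])
        in_window = staged[(anchor >= win_start) & (anchor <= win_end)]
        keys = FACT_NATURAL_KEYS[table]
        in_window = in_window.sort_values(keys, kind="mergesort").drop_duplicates(keys)
        cur.execute(
            f"DELETE FROM {table} WHERE anchor_date >= ? AND anchor_date <= ?",
            (win_start.strftime("%Y-%m-%dT%H:%M:%S"), win_end.strftime("%Y-%m-%dT%H:%M:%S")),
        )
        cols = [r[1] for r in cur.execute(f"PRAGMA table_info({table})")]
        payload = _to_sql_frame(in_window.reindex(columns=cols))
        payload = payload.where(pd.notna(payload), None)
        cur.executemany(
            f"INSERT INTO {table} VALUES ({','.join('?' * len(cols))})",
            payload.itertuples(index=False, name=None),
        )
        rows_in += len(in_window)
        rows_loaded += len(in_window)
    q = result.quarantine
    rejected = q[
        q["table"].isin(tables)
        & (pd.to_datetime(q["anchor_date"]) >= win_start)
        & (pd.to_datetime(q["anchor_date"]) <= win_end)
    ] if len(q) else q
    return rows_in + len(rejected), rows_loaded, len(rejected)


def _run_flow(
    wh: Warehouse,
    flow_id: int,
    tables: list[str],
    result: TransformResult,
    as_of_date: date,
    window_days: int,
    upsert_patients: bool,
) -> LoadLog:
    cur = wh.con.cursor()
    if cur.execute("SELECT COUNT(*) FROM load_lock WHERE flow_id=?", (flow_id,)).fetchone()[0]:
        raise RunRejectedError(f"flow {flow_id} already running against this warehouse")
    started = datetime.now()
    cur.execute("INSERT INTO load_lock VALUES (?,?)", (flow_id, started.isoformat()))
    wh.con.commit()
    try:
        win_end = pd.Timestamp(as_of_date)
        win_start = win_end - pd.Timedelta(days=window_days)
        if upsert_patients:
            pats = result.frames["patient"].sort_values("patient_id", kind="mergesort")
            cur.executemany(
                "DELETE FROM patient WHERE patient_id=?",
                [(p,) for p in pats["patient_id"]],
            )
            cur.executemany(
                "INSERT INTO patient VALUES (?,?,?)",
                _to_sql_frame(pats[REQUIRED_COLUMNS["patients"]]).itertuples(index=False, name=None),
            )
        rows_in, rows_loaded, rows_rejected = _windowed_load(
            wh, tables, result, win_start, win_end
        )
        run_id = uuid.uuid4().hex[:12]
        if rows_rejected:
            q = result.quarantine
            payload = q.copy()
            payload["anchor_date"] = pd.to_datetime(payload["anchor_date"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
            cur.executemany(
                "INSERT INTO quarantine VALUES (?,?,?,?,?)",
                [(run_id, r.table, r.reason, r.anchor_date, r.row) for r in payload.itertuples(index=False)],
            )
        log = LoadLog(
            run_id=run_id,
            flow_id=flow_id,
            started_ts=started,
            finished_ts=datetime.now(),
            rows_in=rows_in,
            rows_loaded=rows_loaded,
            rows_rejected=rows_rejected,
            window_start=win_start.date(),
            window_end=win_end.date(),
            status="success",
            messages="",
        )
        cur.execute(
            "INSERT INTO load_log VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (
                log.run_id, log.flow_id, log.started_ts.isoformat(),
                log.finished_ts.isoformat(), log.rows_in, log.rows_loaded,
                log.rows_rejected, log.window_start.isoformat(),
                log.window_end.isoformat(), log.status, log.messages,
            ),
        )
        wh.con.commit()
        return log
    finally:
        cur.execute("DELETE FROM load_lock WHERE flow_id=?", (flow_id,))
        wh.con.commit()


def load_flow1(result: TransformResult, wh: Warehouse, as_of_date: date) -> LoadLog:
    """Weekly flow for low-volume updatable facts; one-year window."""
    return _run_flow(wh, 1, FLOW1_TABLES, result, as_of_date, 365, upsert_patients=True)


def load_flow2(result: TransformResult, wh: Warehouse, as_of_date: date) -> LoadLog:
    """Weekly flow for high-volume monitor facts; two-sliding-week window."""
    return _run_flow(wh, 2, FLOW2_TABLES, result, as_of_date, 14, upsert_patients=False)


def run_etl(
    source_dir: str | Path,
    staging_dir: str | Path,
    warehouse_path: str | Path,
    as_of_date: date | None = None,
    config: EtlConfig | None = None,
) -> tuple[Warehouse, list[LoadLog]]:
    """Convenience pipeline: mirror -> transform -> flow 1 -> flow 2.

    With an explicit ``as_of_date`` each flow runs once at that date.
    Without one, the weekly production cadence is emulated: flow 1 runs
    at the latest staged anchor date, and flow 2 runs at successive
    weekly dates so its two-week windows tile the staged measurement
    span with overlap (the overwrite semantics make overlap harmless).
    """
    config = config or default_config()
    mirror(source_dir, staging_dir)
    bundle = read_staging(staging_dir)
    result = transform(bundle, config)
    wh = Warehouse(warehouse_path)
    wh.init_schema(config)
    logs: list[LoadLog] = []
    if as_of_date is not None:
        logs.append(load_flow1(result, wh, as_of_date))
        logs.append(load_flow2(result, wh, as_of_date))
        return wh, logs

    anchors = pd.concat(
        [pd.to_datetime(result.frames[t]["anchor_date"]) for t in FLOW1_TABLES + FLOW2_TABLES
         if len(result.frames[t])]
    )
    first, last = anchors.min().date(), anchors.max().date()
    as_of = first + timedelta(days=365)
    while True:
        logs.append(load_flow1(result, wh, min(as_of, last)))
        if as_of >= last:
            break
        as_of += timedelta(days=365)
    as_of = first + timedelta(days=7)
    while True:
        logs.append(load_flow2(result, wh, min(as_of, last)))
        if as_of >= last:
            break
        as_of += timedelta(days=7)
    return wh, logs
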