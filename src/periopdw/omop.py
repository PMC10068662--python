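"""OMOP CDM v5.4-shaped export of the warehouse.

The anesthesia conventions: each hospital stay becomes a
VISIT_OCCURRENCE; the passage through the operating room becomes a
VISIT_DETAIL child of that visit, exactly like an ICU unit stay; every
OR-derived row (vital-sign measurement, drug administration,
anesthesia/surgery step) carries the visit_detail_id of its passage.

Routing of step events: an event label whose vocabulary entry has domain
``Procedure`` goes to PROCEDURE_OCCURRENCE; free-text milestones go to
OBSERVATION. PMSI procedure codes always go to PROCEDURE_OCCURRENCE and
diagnoses are out of scope here (they live warehouse-side).

Concept mappings come from a bundled mini-vocabulary
(``data/mini_vocab_synthetic.csv``) — a synthetic stand-in for the OMOP
vocabulary download, kept tiny so the artifact needs no network. Labels
absent from it fall back to deterministic local concept ids in the
reserved range >= 2,000,000,000 and are counted in the export report.

Only ok-flagged rows are exported; per-category counts in the report let
callers verify conservation (ok rows = exported rows + counted
exclusions). Re-exporting an unchanged warehouse is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .etl import Warehouse

FALLBACK_CONCEPT_BASE = 2_000_000_000

CDM_TABLES = (
    "PERSON",
    "VISIT_OCCURRENCE",
    "VISIT_DETAIL",
    "MEASUREMENT",
    "DRUG_EXPOSURE",
    "PROCEDURE_OCCURRENCE",
    "OBSERVATION",
)

# standard visit concepts: 9201 inpatient visit, 32037 intensive care,
# 4021813 operating-room "anesthesia procedure" detail (synthetic choice)
VISIT_CONCEPTS = {"inpatient": 9201, "or_passage": 4021813, "icu": 32037}
GENDER_CONCEPTS = {"M": 8507, "F": 8532}
EHR_TYPE_CONCEPT = 32817  # record sourced from an EHR


def load_vocab(path: str | Path | None = None) -> pd.DataFrame:
    """Load the concept mapping table (default: bundled mini-vocabulary)."""
    if path is None:
        ref = resources.files("periopdw").joinpath("data/mini_vocab_synthetic.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


class ConceptMap:
    """Local label -> (concept_id, vocabulary, domain), with deterministic
    fallback allocation for unmapped labels."""

    def __init__(self, vocab: pd.DataFrame):
        dup = vocab["local_label"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate vocabulary entries: {sorted(vocab.loc[dup, 'local_label'])}"
            )
        self._map = {
            r.local_label: (int(r.concept_id), r.vocabulary, r.domain)
            for r in vocab.itertuples(index=False)
        }
        self._fallback: dict[str, int] = {}
        self.unmapped_counts: dict[str, int] = {}

    def register_fallbacks(self, labels) -> None:
        """Allocate reserved-range ids for unmapped labels, sorted so the
        assignment is stable across exports."""
        unmapped = sorted({str(l) for l in labels if l is not None and str(l) not in self._map})
        for i, label in enumerate(unmapped):
            if label not in self._fallback:
                self._fallback[label] = FALLBACK_CONCEPT_BASE + len(self._fallback)

    def concept_id(self, label) -> int:
        label = str(label)
        if label in self._map:
            return self._map[label][0]
        if label not in self._fallback:
            self._fallback[label] = FALLBACK_CONCEPT_BASE + len(self._fallback)
        self.unmapped_counts[label] = self.unmapped_counts.get(label, 0) + 1
        return self._fallback[label]

    def domain(self, label) -> str | None:
        entry = self._map.get(str(label))
        return entry[2] if entry else None

    @property
    def n_unmapped_rows(self) -> int:
        return sum(self.unmapped_counts.values())


@dataclass
class CdmBundle:
    tables: dict[str, pd.DataFrame]
    report: dict = field(default_factory=dict)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in CDM_TABLES:
            self.tables[name].to_csv(out / f"{name}.csv", index=False)


def _iso(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.strftime("%Y-%m-%dT%H:%M:%S")


def _iso_date(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.strftime("%Y-%m-%d")


def map_visits(wh: Warehouse) -> dict:
    """PERSON + VISIT_OCCURRENCE + VISIT_DETAIL from stays, interventions
    and ICU/ward unit stays.

    Linked interventions become children of their stay's visit; an
    unlinked intervention is exported under a synthetic standalone visit
    and counted in the report.
    """
    patients = wh.table("patient").sort_values("patient_id")
    stays = wh.table("hospital_stay").sort_values("stay_id")
    interventions = wh.table("intervention").sort_values("intervention_id")
    unit_stays = wh.table("unit_stay").sort_values("unit_stay_id")

    person_ids = {pid: i + 1 for i, pid in enumerate(patients["patient_id"])}
    person = pd.DataFrame(
        {
            "person_id": [person_ids[p] for p in patients["patient_id"]],
            "gender_concept_id": patients["sex"].map(GENDER_CONCEPTS).fillna(0).astype(int),
            "year_of_birth": pd.to_datetime(patients["birth_date"]).dt.year,
            "month_of_birth": pd.to_datetime(patients["birth_date"]).dt.month,
            "day_of_birth": pd.to_datetime(patients["birth_date"]).dt.day,
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
            "person_source_value": patients["patient_id"],
            "gender_source_value": patients["sex"],
        }
    )

    visit_ids = {sid: i + 1 for i, sid in enumerate(stays["stay_id"])}
    vo_rows = [
        {
            "visit_occurrence_id": visit_ids[s.stay_id],
            "person_id": person_ids.get(s.patient_id, 0),
            "visit_concept_id": VISIT_CONCEPTS["inpatient"],
            "visit_start_date": pd.Timestamp(s.admission_date).strftime("%Y-%m-%d"),
            "visit_end_date": pd.Timestamp(s.discharge_date).strftime("%Y-%m-%d"),
            "visit_type_concept_id": EHR_TYPE_CONCEPT,
            "visit_source_value": s.stay_id,
        }
        for s in stays.itertuples(index=False)
    ]

    # synthetic standalone visits for unlinked interventions
    next_vo = len(visit_ids) + 1
    iv_visit: dict[str, int] = {}
    n_standalone = 0
    for iv in interventions.itertuples(index=False):
        sid = iv.stay_id
        if sid is not None and not (isinstance(sid, float) and np.isnan(sid)) and sid in visit_ids:
            iv_visit[iv.intervention_id] = visit_ids[sid]
        else:
            vo_rows.append(
                {
                    "visit_occurrence_id": next_vo,
                    "person_id": person_ids.get(iv.patient_id, 0),
                    "visit_concept_id": VISIT_CONCEPTS["inpatient"],
                    "visit_start_date": pd.Timestamp(iv.room_entry_ts).strftime("%Y-%m-%d"),
                    "visit_end_date": pd.Timestamp(iv.room_exit_ts).strftime("%Y-%m-%d"),
                    "visit_type_concept_id": EHR_TYPE_CONCEPT,
                    "visit_source_value": f"standalone:{iv.intervention_id}",
                }
            )
            iv_visit[iv.intervention_id] = next_vo
            next_vo += 1
            n_standalone += 1
    visit_occurrence = pd.DataFrame(vo_rows)

    vd_rows = []
    vd_id = 1
    iv_detail: dict[str, int] = {}
    for iv in interventions.itertuples(index=False):
        vd_rows.append(
            {
                "visit_detail_id": vd_id,
                "person_id": person_ids.get(iv.patient_id, 0),
                "visit_detail_concept_id": VISIT_CONCEPTS["or_passage"],
                "visit_detail_start_datetime": pd.Timestamp(iv.room_entry_ts).strftime("%Y-%m-%dT%H:%M:%S"),
                "visit_detail_end_datetime": pd.Timestamp(iv.room_exit_ts).strftime("%Y-%m-%dT%H:%M:%S"),
                "visit_detail_type_concept_id": EHR_TYPE_CONCEPT,
                "visit_detail_source_value": iv.intervention_id,
                "visit_occurrence_id": iv_visit[iv.intervention_id],
            }
        )
        iv_detail[iv.intervention_id] = vd_id
        vd_id += 1
    stay_patient = dict(stays[["stay_id", "patient_id"]].itertuples(index=False))
    for us in unit_stays.itertuples(index=False):
        if us.stay_id not in visit_ids:
            continue
        concept = VISIT_CONCEPTS["icu"] if "REA" in str(us.unit_label) else VISIT_CONCEPTS["inpatient"]
        vd_rows.append(
            {
                "visit_detail_id": vd_id,
                "person_id": person_ids.get(stay_patient.get(us.stay_id), 0),
                "visit_detail_concept_id": concept,
                "visit_detail_start_datetime": pd.Timestamp(us.start_ts).strftime("%Y-%m-%dT%H:%M:%S"),
                "visit_detail_end_datetime": pd.Timestamp(us.end_ts).strftime("%Y-%m-%dT%H:%M:%S"),
                "visit_detail_type_concept_id": EHR_TYPE_CONCEPT,
                "visit_detail_source_value": us.unit_stay_id,
                "visit_occurrence_id": visit_ids[us.stay_id],
            }
        )
        vd_id += 1
    visit_detail = pd.DataFrame(vd_rows)

    return {
        "PERSON": person,
        "VISIT_OCCURRENCE": visit_occurrence,
        "VISIT_DETAIL": visit_detail,
        "person_ids": person_ids,
        "visit_ids": visit_ids,
        "iv_visit": iv_visit,
        "iv_detail": iv_detail,
        "n_standalone_visits": n_standalone,
    }


def map_records(wh: Warehouse, concept_map: ConceptMap, visits: dict) -> dict:
    """MEASUREMENT, DRUG_EXPOSURE, PROCEDURE_OCCURRENCE, OBSERVATION rows
    for ok-flagged warehouse facts, keyed to their VISIT_DETAIL."""
    iv = wh.table("intervention").set_index("intervention_id")
    iv_patient = iv["patient_id"].to_dict()
    person_ids = visits["person_ids"]
    iv_visit, iv_detail = visits["iv_visit"], visits["iv_detail"]

    meas = wh.table("measurement")
    meas_ok = meas[meas["quality_flag"] == "ok"].sort_values(
        ["intervention_id", "signal_code", "ts"], kind="mergesort"
    )
    concept_map.register_fallbacks(meas_ok["signal_code"].unique())
    concept_map.register_fallbacks(meas_ok["unit_label"].unique())
    measurement = pd.DataFrame(
        {
            "measurement_id": range(1, len(meas_ok) + 1),
            "person_id": [
                person_ids.get(iv_patient.get(i), 0) for i in meas_ok["intervention_id"]
            ],
            "measurement_concept_id": [concept_map.concept_id(c) for c in meas_ok["signal_code"]],
            "measurement_datetime": _iso(meas_ok["ts"]),
            "measurement_type_concept_id": EHR_TYPE_CONCEPT,
            "value_as_number": meas_ok["value"].astype(float),
            "unit_concept_id": [concept_map.concept_id(u) for u in meas_ok["unit_label"]],
            "visit_occurrence_id": [iv_visit.get(i) for i in meas_ok["intervention_id"]],
            "visit_detail_id": [iv_detail.get(i) for i in meas_ok["intervention_id"]],
            "measurement_source_value": meas_ok["signal_code"],
        }
    )

    ev = wh.table("event_record")
    ev_ok = ev[ev["quality_flag"] == "ok"]
    drugs = ev_ok[ev_ok["kind"] == "drug"].sort_values(
        ["intervention_id", "event_label", "ts"], kind="mergesort"
    )
    concept_map.register_fallbacks(drugs["event_label"].unique())
    drug_exposure = pd.DataFrame(
        {
            "drug_exposure_id": range(1, len(drugs) + 1),
            "person_id": [person_ids.get(iv_patient.get(i), 0) for i in drugs["intervention_id"]],
            "drug_concept_id": [concept_map.concept_id(d) for d in drugs["event_label"]],
            # bolus convention: start = end = administration time
            "drug_exposure_start_datetime": _iso(drugs["ts"]),
            "drug_exposure_end_datetime": _iso(drugs["ts"]),
            "drug_type_concept_id": EHR_TYPE_CONCEPT,
            "quantity": drugs["dose"].astype(float),
            "dose_unit_source_value": drugs["dose_unit"],
            "visit_occurrence_id": [iv_visit.get(i) for i in drugs["intervention_id"]],
            "visit_detail_id": [iv_detail.get(i) for i in drugs["intervention_id"]],
            "drug_source_value": drugs["event_label"],
        }
    )

    steps = ev_ok[ev_ok["kind"] == "step"].sort_values(
        ["intervention_id", "event_label", "ts"], kind="mergesort"
    )
    concept_map.register_fallbacks(steps["event_label"].unique())
    step_is_proc = steps["event_label"].map(lambda l: concept_map.domain(l) == "Procedure")
    obs_steps = steps[~step_is_proc]
    proc_steps = steps[step_is_proc]

    observation = pd.DataFrame(
        {
            "observation_id": range(1, len(obs_steps) + 1),
            "person_id": [person_ids.get(iv_patient.get(i), 0) for i in obs_steps["intervention_id"]],
            "observation_concept_id": [concept_map.concept_id(l) for l in obs_steps["event_label"]],
            "observation_datetime": _iso(obs_steps["ts"]),
            "observation_type_concept_id": EHR_TYPE_CONCEPT,
            "visit_occurrence_id": [iv_visit.get(i) for i in obs_steps["intervention_id"]],
            "visit_detail_id": [iv_detail.get(i) for i in obs_steps["intervention_id"]],
            "observation_source_value": obs_steps["event_label"],
        }
    )

    procs = wh.table("procedure").sort_values(["stay_id", "code"], kind="mergesort")
    stays = wh.table("hospital_stay").set_index("stay_id")
    visit_ids = visits["visit_ids"]
    concept_map.register_fallbacks(procs["code"].unique())
    po_rows = []
    po_id = 1
    for p in procs.itertuples(index=False):
        po_rows.append(
            {
                "procedure_occurrence_id": po_id,
                "person_id": person_ids.get(stays.at[p.stay_id, "patient_id"], 0)
                if p.stay_id in stays.index
                else 0,
                "procedure_concept_id": concept_map.concept_id(p.code),
                "procedure_date": pd.Timestamp(stays.at[p.stay_id, "admission_date"]).strftime("%Y-%m-%d")
                if p.stay_id in stays.index
                else "",
                "procedure_type_concept_id": EHR_TYPE_CONCEPT,
                "visit_occurrence_id": visit_ids.get(p.stay_id),
                "visit_detail_id": None,
                "procedure_source_value": p.code,
            }
        )
        po_id += 1
    for s in proc_steps.itertuples(index=False):
        po_rows.append(
            {
                "procedure_occurrence_id": po_id,
                "person_id": person_ids.get(iv_patient.get(s.intervention_id), 0),
                "procedure_concept_id": concept_map.concept_id(s.event_label),
                "procedure_date": pd.Timestamp(s.ts).strftime("%Y-%m-%d"),
                "procedure_type_concept_id": EHR_TYPE_CONCEPT,
                "visit_occurrence_id": iv_visit.get(s.intervention_id),
                "visit_detail_id": iv_detail.get(s.intervention_id),
                "procedure_source_value": s.event_label,
            }
        )
        po_id += 1
    procedure_occurrence = pd.DataFrame(
        po_rows,
        columns=[
            "procedure_occurrence_id", "person_id", "procedure_concept_id",
            "procedure_date", "procedure_type_concept_id",
            "visit_occurrence_id", "visit_detail_id", "procedure_source_value",
        ],
    )

    report = {
        "source_ok_rows": {
            "measurement": int(len(meas_ok)),
            "drug": int(len(drugs)),
            "step": int(len(steps)),
            "procedure": int(len(procs)),
        },
        "exported_rows": {
            "MEASUREMENT": int(len(measurement)),
            "DRUG_EXPOSURE": int(len(drug_exposure)),
            "OBSERVATION": int(len(observation)),
            "PROCEDURE_OCCURRENCE": int(len(procedure_occurrence)),
        },
        "excluded_rows": {
            "measurement_not_ok": int((meas["quality_flag"] != "ok").sum()),
            "event_not_ok": int((ev["quality_flag"] != "ok").sum()),
        },
        "unmapped_concept_rows": concept_map.n_unmapped_rows,
        "unmapped_labels": sorted(concept_map.unmapped_counts),
    }
    return {
        "MEASUREMENT": measurement,
        "DRUG_EXPOSURE": drug_exposure,
        "PROCEDURE_OCCURRENCE": procedure_occurrence,
        "OBSERVATION": observation,
        "report": report,
    }


def export_cdm(
    wh: Warehouse, vocab: pd.DataFrame | None = None, out_dir: str | Path | None = None
) -> CdmBundle:
    """Full export: visits first, then the record tables; optionally write
    one CSV per CDM table."""
    concept_map = ConceptMap(vocab if vocab is not None else load_vocab())
    visits = map_visits(wh)
    records = map_records(wh, concept_map, visits)
    tables = {name: visits[name] for name in ("PERSON", "VISIT_OCCURRENCE", "VISIT_DETAIL")}
    tables.update({name: records[name] for name in
                   ("MEASUREMENT", "DRUG_EXPOSURE", "PROCEDURE_OCCURRENCE", "OBSERVATION")})
    report = dict(records["report"])
    report["n_standalone_visits"] = visits["n_standalone_visits"]
    bundle = CdmBundle(tables=tables, report=report)
    if out_dir is not None:
        bundle.to_csv(out_dir)
    return bundle


def check_cdm(bundle: CdmBundle) -> dict:
    """Referential-integrity report: foreign-key closure, row counts,
    unmapped-concept counts. Report-only, raises nothing."""
    t = bundle.tables
    persons = set(t["PERSON"]["person_id"])
    visits = set(t["VISIT_OCCURRENCE"]["visit_occurrence_id"])
    details = set(t["VISIT_DETAIL"]["visit_detail_id"])
    violations: list[str] = []

    def _check_fk(table: str, col: str, valid: set, allow_null: bool = True):
        series = t[table][col]
        for idx, v in series.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                if not allow_null:
                    violations.append(f"{table}[{idx}].{col} is null")
                continue
            if int(v) not in valid:
                violations.append(f"{table}[{idx}].{col}={int(v)} unresolved")

    for table in ("VISIT_OCCURRENCE", "VISIT_DETAIL", "MEASUREMENT",
                  "DRUG_EXPOSURE", "PROCEDURE_OCCURRENCE", "OBSERVATION"):
        _check_fk(table, "person_id", persons, allow_null=False)
    _check_fk("VISIT_DETAIL", "visit_occurrence_id", visits, allow_null=False)
    for table in ("MEASUREMENT", "DRUG_EXPOSURE", "OBSERVATION"):
        _check_fk(table, "visit_detail_id", details, allow_null=False)
        _check_fk(table, "visit_occurrence_id", visits)
    _check_fk("PROCEDURE_OCCURRENCE", "visit_detail_id", details)
    _check_fk("PROCEDURE_OCCURRENCE", "visit_occurrence_id", visits)

    return {
        "n_violations": len(violations),
        "violations": violations[:50],
        "row_counts": {name: int(len(t[name])) for name in CDM_TABLES},
        "unmapped_concept_rows": bundle.report.get("unmapped_concept_rows", 0),
    }
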