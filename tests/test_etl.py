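"""ETL contracts: mirroring, linkage, vocabulary, units, flags, load flows."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

import periopdw as pw
from periopdw.etl import (
    ConfigError,
    LoadError,
    RunRejectedError,
    Warehouse,
    load_flow1,
    load_flow2,
    normalize_label,
)


# -- mirror ----------------------------------------------------------------


def test_mirror_copies_every_table_and_is_idempotent(clean_bundle, tmp_path):
    bundle, _ = clean_bundle
    bundle.to_csv(tmp_path / "src")
    pw.mirror(tmp_path / "src", tmp_path / "stage")
    first = {p.name: p.read_bytes() for p in (tmp_path / "stage").iterdir()}
    staged = pw.read_staging(tmp_path / "stage")
    for name, df in bundle.tables().items():
        assert len(staged.tables()[name]) == len(df)
    pw.mirror(tmp_path / "src", tmp_path / "stage")
    second = {p.name: p.read_bytes() for p in (tmp_path / "stage").iterdir()}
    assert first == second


def test_mirror_rejects_malformed_timestamp_naming_the_row(clean_bundle, tmp_path):
    bundle, _ = clean_bundle
    bundle.to_csv(tmp_path / "src")
    path = tmp_path / "src" / "interventions.csv"
    lines = path.read_text().splitlines()
    lines[3] = lines[3].replace("2023", "not-a-date")
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(LoadError, match=r"interventions\.csv: row 2"):
        pw.mirror(tmp_path / "src", tmp_path / "stage")


# -- linkage ---------------------------------------------------------------


def _mk_interventions(rows):
    return pd.DataFrame(
        rows, columns=["intervention_id", "patient_id", "room_entry_ts", "room_exit_ts", "unit_label"]
    )


def _mk_stays(rows):
    return pd.DataFrame(
        rows, columns=["stay_id", "patient_id", "admission_date", "discharge_date", "discharge_status"]
    )


def test_intervention_links_to_containing_stay():
    iv = _mk_interventions(
        [("I1", "P1", pd.Timestamp("2023-01-05 09:00"), pd.Timestamp("2023-01-05 11:00"), "OR")]
    )
    stays = _mk_stays(
        [("S1", "P1", pd.Timestamp("2023-01-01"), pd.Timestamp("2023-01-10"), "home")]
    )
    lm = pw.link_records(iv, stays)
    assert lm.links.iloc[0].tolist() == ["I1", "S1"]
    assert lm.unlinked.empty


def test_tie_break_prefers_latest_admission_before_intervention():
    """Two candidate stays admitted day 1 and day 4; intervention on day 5
    links to the day-4 stay (smallest admission-to-intervention gap)."""
    iv = _mk_interventions(
        [("I1", "P1", pd.Timestamp("2023-01-05 09:00"), pd.Timestamp("2023-01-05 11:00"), "OR")]
    )
    stays = _mk_stays(
        [
            ("S1", "P1", pd.Timestamp("2023-01-01"), pd.Timestamp("2023-01-10"), "home"),
            ("S2", "P1", pd.Timestamp("2023-01-04"), pd.Timestamp("2023-01-08"), "home"),
        ]
    )
    lm = pw.link_records(iv, stays)
    assert lm.links.iloc[0]["stay_id"] == "S2"
    # oracle: enumerate candidates and minimize the admission gap
    d = pd.Timestamp("2023-01-05")
    best = min(
        (r for r in stays.itertuples() if r.admission_date <= d <= r.discharge_date),
        key=lambda r: (d - r.admission_date, r.stay_id),
    )
    assert lm.links.iloc[0]["stay_id"] == best.stay_id


def test_unlinkable_rows_reported_with_reason():
    iv = _mk_interventions(
        [
            ("I1", None, pd.Timestamp("2023-01-05 09:00"), pd.Timestamp("2023-01-05 10:00"), "OR"),
            ("I2", "P9", pd.Timestamp("2023-06-05 09:00"), pd.Timestamp("2023-06-05 10:00"), "OR"),
        ]
    )
    stays = _mk_stays(
        [("S1", "P9", pd.Timestamp("2023-01-01"), pd.Timestamp("2023-01-10"), "home")]
    )
    lm = pw.link_records(iv, stays)
    reasons = dict(lm.unlinked.itertuples(index=False))
    assert reasons == {"I1": "missing_patient_id", "I2": "no_candidate"}


# -- vocabulary ------------------------------------------------------------


def test_normalization_merges_case_space_and_diacritic_variants():
    out = pw.clean_vocabulary(["Heart  Rate ", "heart rate", "Fréquence"], {})
    assert out["Heart  Rate "] == out["heart rate"] == "heart rate"
    assert out["Fréquence"] == "frequence"


def test_brand_synonyms_collapse_to_one_canonical():
    table = {"HR-GE": "heart rate", "HR-Mindray": "heart rate"}
    out = pw.clean_vocabulary(["HR-GE", "HR-Mindray"], table)
    assert set(out.values()) == {"heart rate"}


def test_conflicting_synonyms_rejected():
    with pytest.raises(ConfigError, match="conflict"):
        pw.clean_vocabulary(["x"], {"HR ": "heart rate", "hr": "pulse"})


def test_unmapped_label_becomes_its_own_canonical():
    assert pw.clean_vocabulary(["SpO2"], {}) == {"SpO2": "spo2"}


# -- code grouping ---------------------------------------------------------


def test_group_codes_flags_exactly_the_stays_with_in_set_codes():
    rows = [(f"S{i}", "AAAA001") for i in range(10)]
    for i in (2, 5, 7):
        rows.append((f"S{i}", f"ECC00{i}"))
    procedures = pd.DataFrame(rows, columns=["stay_id", "code"])
    ecc = {"ECC002", "ECC005", "ECC007"}
    flags = pw.group_codes(procedures, ("ecc", ecc))
    # oracle: set-membership scan
    expected = {sid: bool(set(g["code"]) & ecc) for sid, g in procedures.groupby("stay_id")}
    assert flags.to_dict() == expected
    assert sum(flags) == 3
    with pytest.raises(ConfigError, match="empty"):
        pw.group_codes(procedures, ("ecc", set()))


# -- unit conversion -------------------------------------------------------


def test_convert_units_examples():
    rows = pd.DataFrame(
        {"dose": [1.0, 250.0, 5.0], "dose_unit": ["g", "mg", "furlongs"]}
    )
    out = pw.convert_units(rows, [("g", "mg", 1000.0)])
    assert out.iloc[0].tolist() == [1000.0, "mg"]
    assert out.iloc[1].tolist() == [250.0, "mg"]
    assert out.iloc[2].tolist() == [5.0, "furlongs"]  # unknown unit untouched


def test_bad_unit_rules_rejected():
    with pytest.raises(ConfigError, match="different factors"):
        pw.convert_units(pd.DataFrame({"dose": [], "dose_unit": []}),
                         [("g", "mg", 1000.0), ("g", "mg", 100.0)])
    with pytest.raises(ConfigError, match="cycle"):
        pw.convert_units(pd.DataFrame({"dose": [], "dose_unit": []}),
                         [("g", "mg", 1000.0), ("mg", "g", 0.001)])
    with pytest.raises(ConfigError, match="factor"):
        pw.convert_units(pd.DataFrame({"dose": [], "dose_unit": []}), [("g", "mg", -1.0)])


# -- quality flags ---------------------------------------------------------


def _meas(rows):
    return pd.DataFrame(
        rows, columns=["intervention_id", "signal_code", "ts", "value", "unit_label"]
    )


RANGES = {"HR": (20.0, 250.0, "bpm"), "MAP": (30.0, 200.0, "mmHg")}


def test_flag_precedence_and_values():
    t = pd.Timestamp("2023-01-01 10:00")
    rows = _meas(
        [
            ("I1", "HR", t, 400.0, "bpm"),      # out of range
            ("I1", "MAP", t, 80.0, "mmHg"),     # ok
            ("I1", "MAP", t, 80.0, "kPa"),      # bad unit
            ("I1", "HR", t, None, "bpm"),       # missing value
            (None, "HR", t, 70.0, "bpm"),       # orphan
        ]
    )
    out = pw.flag_quality(rows, RANGES)
    assert out["quality_flag"].tolist() == [
        "out_of_range", "ok", "bad_unit", "missing_value", "orphan",
    ]


def test_unknown_signal_is_config_error():
    rows = _meas([("I1", "XYZ", pd.Timestamp("2023-01-01"), 1.0, "u")])
    with pytest.raises(ConfigError, match="XYZ"):
        pw.flag_quality(rows, RANGES)


def test_injected_out_of_range_rows_flagged_exactly(transformed_corrupted, corrupted_bundle):
    _, log = corrupted_bundle
    meas = transformed_corrupted.frames["measurement"]
    k = log.corruption_counts()["out_of_range"]
    assert (meas["quality_flag"] == "out_of_range").sum() == k


# -- load flows ------------------------------------------------------------


@pytest.fixture()
def loaded(clean_bundle, tmp_path):
    bundle, _ = clean_bundle
    config = pw.default_config()
    result = pw.transform(bundle, config)
    wh = Warehouse(tmp_path / "wh.sqlite")
    wh.init_schema(config)
    yield wh, result, bundle
    wh.close()


def test_flow_logs_conserve_rows(loaded):
    wh, result, bundle = loaded
    as_of = bundle.measurements["ts"].max().date()
    for log in (load_flow1(result, wh, as_of), load_flow2(result, wh, as_of)):
        assert log.rows_in == log.rows_loaded + log.rows_rejected
        assert log.status == "success"


def test_reload_is_idempotent_and_out_of_window_rows_untouched(loaded):
    wh, result, bundle = loaded
    last = bundle.measurements["ts"].max().date()
    mid = last - timedelta(days=5)
    load_flow1(result, wh, last)
    load_flow2(result, wh, mid)   # covers [mid-14, mid]
    before_meas = wh.table("measurement")
    outside_before = before_meas[pd.to_datetime(before_meas["anchor_date"]) > pd.Timestamp(mid)]
    ck = wh.checksum()
    load_flow1(result, wh, last)
    load_flow2(result, wh, mid)
    assert wh.checksum() == ck
    after_meas = wh.table("measurement")
    outside_after = after_meas[pd.to_datetime(after_meas["anchor_date"]) > pd.Timestamp(mid)]
    pd.testing.assert_frame_equal(
        outside_before.reset_index(drop=True), outside_after.reset_index(drop=True)
    )


def test_flow2_excludes_measurements_older_than_its_window(loaded):
    wh, result, bundle = loaded
    as_of = bundle.measurements["ts"].max().date() + timedelta(days=25)
    log = load_flow2(result, wh, as_of)  # every sample now > 14 days old... or in window?
    cutoff = pd.Timestamp(as_of - timedelta(days=14))
    staged = result.frames["measurement"]
    expected = (pd.to_datetime(staged["anchor_date"]) >= cutoff).sum()
    assert len(wh.table("measurement")) == expected
    assert log.rows_loaded <= len(staged)


def test_flow1_overwrite_reflects_updated_discharge_date(loaded):
    wh, result, bundle = loaded
    as_of = bundle.measurements["ts"].max().date()
    load_flow1(result, wh, as_of)
    sid = result.frames["hospital_stay"]["stay_id"].iloc[0]
    updated = pw.transform(bundle, pw.default_config())
    stays = updated.frames["hospital_stay"]
    new_date = stays.loc[stays["stay_id"] == sid, "discharge_date"].iloc[0] + timedelta(days=3)
    stays.loc[stays["stay_id"] == sid, "discharge_date"] = new_date
    load_flow1(updated, wh, as_of)
    stored = wh.table("hospital_stay").set_index("stay_id")
    assert stored.at[sid, "discharge_date"] == new_date


def test_consecutive_weekly_runs_cover_stream_without_dupes_or_gaps(loaded):
    wh, result, bundle = loaded
    staged = result.frames["measurement"]
    first = pd.to_datetime(staged["anchor_date"]).min().date()
    last = pd.to_datetime(staged["anchor_date"]).max().date()
    as_of = first + timedelta(days=7)
    while True:
        load_flow2(result, wh, min(as_of, last))
        if as_of >= last:
            break
        as_of += timedelta(days=7)
    loaded_meas = wh.table("measurement")
    key = ["intervention_id", "signal_code", "ts"]
    assert not loaded_meas.duplicated(key).any()
    # oracle: set comparison with staging
    assert (
        set(map(tuple, loaded_meas[key].astype(str).itertuples(index=False)))
        == set(map(tuple, staged[key].astype(str).itertuples(index=False)))
    )


def test_concurrent_run_rejected(loaded):
    wh, result, bundle = loaded
    wh.con.execute("INSERT INTO load_lock VALUES (1, '2023-01-01T00:00:00')")
    with pytest.raises(RunRejectedError):
        load_flow1(result, wh, date(2023, 6, 1))
    wh.con.execute("DELETE FROM load_lock")


def test_referential_integrity_of_ok_rows_after_load(warehouse):
    wh, _ = warehouse
    iv_ids = set(wh.table("intervention")["intervention_id"])
    meas = wh.table("measurement")
    ok = meas[meas["quality_flag"] == "ok"]
    assert ok["intervention_id"].isin(iv_ids).all()
    pat_ids = set(wh.table("patient")["patient_id"])
    assert wh.table("hospital_stay")["patient_id"].isin(pat_ids).all()
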