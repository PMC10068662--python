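"""Generator contracts: determinism, episode realizability, corruption logging."""

import numpy as np
import pandas as pd
import pytest

import periopdw as pw
from periopdw.synthetic import CORRUPTION_KINDS, SIGNALS


def test_no_injection_stays_in_baseline_band():
    bundle, truth = pw.generate_bundle(1, interventions_per_patient=1.0, seed=7)
    assert truth.injected_episodes == []
    for code, grp in bundle.measurements.groupby("signal_code"):
        sig = SIGNALS[code]
        assert grp["value"].between(sig.clean_lo, sig.clean_hi).all()


def test_seed_determinism_table_by_table():
    spec = [pw.EpisodeSpec("MAP", 65.0, "below", 1.0, (5.0, 15.0), (120, 300))]
    b1, t1 = pw.generate_bundle(5, seed=7, episode_spec=spec)
    b2, t2 = pw.generate_bundle(5, seed=7, episode_spec=spec)
    for name, df in b1.tables().items():
        pd.testing.assert_frame_equal(df, b2.tables()[name])
    assert t1.injected_episodes == t2.injected_episodes


def test_five_minute_episode_emits_ten_samples_below_threshold():
    """A logged 5-min MAP<65 episode is exactly 10 consecutive 30 s samples
    strictly below 65, recoverable by a direct scan of the table."""
    spec = [pw.EpisodeSpec("MAP", 65.0, "below", 1.0, (10.0, 10.0), (300, 300))]
    bundle, truth = pw.generate_bundle(3, seed=13, episode_spec=spec)
    assert truth.injected_episodes, "expected at least one injected episode"
    meas = bundle.measurements
    for ep in truth.injected_episodes:
        s = meas[
            (meas["intervention_id"] == ep.intervention_id)
            & (meas["signal_code"] == "MAP")
        ].sort_values("ts")
        in_window = s[(s["ts"] >= ep.start_ts) & (s["ts"] < ep.end_ts)]
        assert len(in_window) == 10
        assert (in_window["value"] < 65.0).all()
        # samples adjacent to the window are on the clean side
        before = s[s["ts"] < ep.start_ts].tail(1)
        after = s[s["ts"] >= ep.end_ts].head(1)
        for neighbour in (before, after):
            if len(neighbour):
                assert (neighbour["value"] >= 65.0).all()


def test_every_logged_episode_recoverable_by_direct_scan(clean_bundle):
    bundle, truth = clean_bundle
    meas = bundle.measurements
    assert len(truth.injected_episodes) > 10
    for ep in truth.injected_episodes:
        s = meas[
            (meas["intervention_id"] == ep.intervention_id)
            & (meas["signal_code"] == ep.signal_code)
        ]
        in_window = s[(s["ts"] >= ep.start_ts) & (s["ts"] < ep.end_ts)]
        assert len(in_window) == ep.duration_s / 30
        assert (in_window["value"] < ep.threshold).all()


def test_episodes_lie_within_intervention_windows(clean_bundle):
    bundle, truth = clean_bundle
    iv = bundle.interventions.set_index("intervention_id")
    for ep in truth.injected_episodes:
        assert iv.at[ep.intervention_id, "room_entry_ts"] <= pd.Timestamp(ep.start_ts)
        assert pd.Timestamp(ep.end_ts) <= iv.at[ep.intervention_id, "room_exit_ts"]


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"n_patients": 3, "interventions_per_patient": 0},
        {"n_patients": 3, "episode_spec": [pw.EpisodeSpec("MAP", 65, "below", 1, (5, 10), (15, 300))]},
        {"n_patients": 3, "episode_spec": [pw.EpisodeSpec("MAP", 65, "sideways", 1, (5, 10), (120, 300))]},
        {"n_patients": 3, "episode_spec": [pw.EpisodeSpec("XYZ", 65, "below", 1, (5, 10), (120, 300))]},
    ],
)
def test_invalid_generation_arguments_rejected(kwargs):
    with pytest.raises(ValueError):
        pw.generate_bundle(seed=1, **kwargs)


# -- corruption ------------------------------------------------------------


def test_zero_rates_leave_bundle_identical(clean_bundle):
    bundle, _ = clean_bundle
    out, log = pw.corrupt_bundle(bundle, {k: 0.0 for k in CORRUPTION_KINDS}, seed=5)
    for name, df in bundle.tables().items():
        pd.testing.assert_frame_equal(df, out.tables()[name])
    assert log.injected_corruptions == []


def test_wrong_unit_rows_are_logged_and_value_consistent(clean_bundle):
    bundle, _ = clean_bundle
    out, log = pw.corrupt_bundle(bundle, {"wrong_unit": 0.2}, seed=5)
    entries = [c for c in log.injected_corruptions if c.corruption_kind == "wrong_unit"]
    assert entries
    n_mg = ((bundle.events["kind"] == "drug") & (bundle.events["dose_unit"] == "mg")).sum()
    assert len(entries) == round(0.2 * n_mg)
    for c in entries:
        row = out.events.iloc[c.row_key]
        assert row["dose_unit"] == "g"
        assert row["dose"] * 1000 == pytest.approx(c.original["dose"])


def test_missing_id_nulls_the_row_and_logs_it(clean_bundle):
    bundle, _ = clean_bundle
    out, log = pw.corrupt_bundle(bundle, {"missing_id": 0.005}, seed=5)
    entries = [c for c in log.injected_corruptions if c.corruption_kind == "missing_id"]
    assert entries
    for c in entries:
        assert pd.isna(out.measurements.iloc[c.row_key]["intervention_id"])


def test_corruption_conservation_per_table(corrupted_bundle, clean_bundle):
    """clean rows + logged corrupted rows = total rows, per table."""
    clean, _ = clean_bundle
    corrupted, log = corrupted_bundle
    by_table: dict[str, set[int]] = {}
    for c in log.injected_corruptions:
        by_table.setdefault(c.table, set()).add(c.row_key)
    for name, df in corrupted.tables().items():
        touched = by_table.get(name, set())
        assert len(df) == len(clean.tables()[name])
        untouched_idx = [i for i in range(len(df)) if i not in touched]
        pd.testing.assert_frame_equal(
            df.iloc[untouched_idx].reset_index(drop=True),
            clean.tables()[name].iloc[untouched_idx].reset_index(drop=True),
        )


def test_unknown_corruption_kind_rejected(clean_bundle):
    bundle, _ = clean_bundle
    with pytest.raises(ValueError, match="unknown corruption kind"):
        pw.corrupt_bundle(bundle, {"gremlins": 0.1}, seed=1)
    with pytest.raises(ValueError, match="rate"):
        pw.corrupt_bundle(bundle, {"missing_id": 1.5}, seed=1)


def test_csv_round_trip_preserves_tables(clean_bundle, tmp_path):
    bundle, _ = clean_bundle
    bundle.to_csv(tmp_path / "out")
    back = pw.SourceBundle.from_csv(tmp_path / "out")
    for name, df in bundle.tables().items():
        pd.testing.assert_frame_equal(df.reset_index(drop=True), back.tables()[name])
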