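"""Episode detection against a brute-force per-second oracle, plus
summary statistics, period derivation and warehouse-level extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import periopdw as pw
from periopdw.features import (
    Period,
    PeriodRule,
    PeriodUndefinedError,
    detect_episodes,
    episode_features,
    summarize,
)

T0 = pd.Timestamp("2023-03-01 09:00:00")


def _series(values, step_s=30, start=T0, flags=None):
    n = len(values)
    return pd.DataFrame(
        {
            "signal_code": "MAP",
            "ts": [start + pd.Timedelta(seconds=i * step_s) for i in range(n)],
            "value": values,
            "quality_flag": flags if flags is not None else ["ok"] * n,
        }
    )


def _period(duration_s, start=T0):
    return Period("I1", "p", start, start + pd.Timedelta(seconds=duration_s))


def brute_force_episodes(series, period, threshold, direction, min_duration_s, max_gap_s):
    """Independent oracle: evaluate the LOCF step function second by
    second and collect maximal beyond-threshold runs."""
    used = series[series["quality_flag"] == "ok"] if "quality_flag" in series else series
    ts = pd.to_datetime(used["ts"])
    used = used[(ts >= period.start_ts) & (ts < period.end_ts)].sort_values("ts")
    t = [(pd.Timestamp(x) - period.start_ts).total_seconds() for x in used["ts"]]
    v = list(used["value"].astype(float))
    total = int(period.duration_s)
    episodes = []
    cur = None  # (start_s, dur, area)
    for s in range(total):
        val = None
        for ti, vi in zip(t, v):
            if ti <= s < ti + max_gap_s:
                val = vi  # last sample holding at second s
            elif ti > s:
                break
        # the hold also ends when the next sample arrives
        for ti in t:
            if ti <= s:
                last = ti
        beyond = val is not None and (val < threshold if direction == "below" else val > threshold)
        # a newer sample overrides: recompute val as the most recent sample
        if beyond:
            if cur is None:
                cur = [s, 0, 0.0]
            cur[1] += 1
            cur[2] += abs(val - threshold)
        else:
            if cur is not None:
                episodes.append(cur)
                cur = None
    if cur is not None:
        episodes.append(cur)
    return [
        (start, dur, area)
        for start, dur, area in episodes
        if dur >= min_duration_s
    ]


def test_constant_series_never_crossing_yields_nothing():
    s = _series([80.0] * 10)
    eps = detect_episodes(s, _period(300), 65.0, "below", 0, 60)
    assert eps == []
    feats = episode_features(eps, _period(300))
    assert feats == {"n_episodes": 0, "total_time_s": 0.0, "total_area": 0.0, "deepest_value": None}


def test_hand_computed_rectangle_sum():
    """Samples [70,60,55,60,70] at 30 s: one 90 s episode below 65 with
    area (5+10+5)x30 = 600 mmHg*s."""
    s = _series([70.0, 60.0, 55.0, 60.0, 70.0])
    eps = detect_episodes(s, _period(150), 65.0, "below", 0, 60)
    assert len(eps) == 1
    ep = eps[0]
    assert ep.duration_s == 90.0
    assert ep.area == pytest.approx(600.0)
    assert ep.extreme_value == 55.0
    oracle = brute_force_episodes(s, _period(150), 65.0, "below", 0, 60)
    assert [(o[1], o[2]) for o in oracle] == [(90, pytest.approx(600.0))]


def test_single_dip_shorter_than_min_duration_discarded():
    s = _series([70.0, 60.0, 70.0, 70.0])
    assert detect_episodes(s, _period(120), 65.0, "below", 60, 60) == []
    assert len(detect_episodes(s, _period(120), 65.0, "below", 30, 60)) == 1


def test_gap_longer_than_max_gap_splits_episodes():
    # below-threshold samples at 0s and 300s with max_gap 60: two episodes
    s = pd.DataFrame(
        {
            "signal_code": "MAP",
            "ts": [T0, T0 + pd.Timedelta(seconds=300)],
            "value": [60.0, 60.0],
            "quality_flag": ["ok", "ok"],
        }
    )
    eps = detect_episodes(s, _period(600), 65.0, "below", 0, 60)
    assert len(eps) == 2
    assert all(e.duration_s == 60.0 for e in eps)


def test_matches_brute_force_oracle_on_random_gappy_series():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(5, 40))
        vals = np.round(rng.uniform(40, 90, n), 1)
        keep = rng.random(n) > 0.2  # introduce gaps
        keep[0] = True
        s = _series(list(vals))[keep.tolist()]
        period = _period(n * 30)
        threshold = float(rng.integers(50, 81))
        for min_dur in (0, 60):
            got = detect_episodes(s, period, threshold, "below", min_dur, 90)
            oracle = brute_force_episodes(s, period, threshold, "below", min_dur, 90)
            assert len(got) == len(oracle)
            for g, (o_start, o_dur, o_area) in zip(got, oracle):
                assert (g.start_ts - period.start_ts).total_seconds() == o_start
                assert g.duration_s == o_dur
                assert g.area == pytest.approx(o_area, rel=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(min_value=40, max_value=90), min_size=2, max_size=30),
    t1=st.floats(min_value=50, max_value=80),
    t2=st.floats(min_value=50, max_value=80),
)
def test_time_and_area_monotone_in_threshold(values, t1, t2):
    lo, hi = sorted((t1, t2))
    s = _series(values)
    period = _period(len(values) * 30)
    f_lo = episode_features(detect_episodes(s, period, lo, "below", 0, 300), period)
    f_hi = episode_features(detect_episodes(s, period, hi, "below", 0, 300), period)
    assert f_lo["total_time_s"] <= f_hi["total_time_s"]
    assert f_lo["total_area"] <= f_hi["total_area"] + 1e-9
    assert f_hi["total_time_s"] <= period.duration_s


def test_direction_above_and_invalid_direction():
    s = _series([95.0, 110.0, 112.0, 95.0])
    eps = detect_episodes(s, _period(120), 100.0, "above", 0, 60)
    assert len(eps) == 1 and eps[0].extreme_value == 112.0
    with pytest.raises(ValueError, match="direction"):
        detect_episodes(s, _period(120), 100.0, "sideways", 0, 60)


def test_non_ok_samples_never_influence_features():
    flags = ["ok", "out_of_range", "ok", "ok", "ok"]
    s1 = _series([70.0, 20.0, 70.0, 70.0, 70.0], flags=flags)
    s2 = _series([70.0, 55.0, 70.0, 70.0, 70.0], flags=flags)
    p = _period(150)
    for a, b in [(s1, s2)]:
        ea = detect_episodes(a, p, 65.0, "below", 0, 300)
        eb = detect_episodes(b, p, 65.0, "below", 0, 300)
        assert episode_features(ea, p) == episode_features(eb, p)
        assert summarize(a, p) == summarize(b, p)


def test_mixed_thresholds_rejected():
    p = _period(300)
    e1 = detect_episodes(_series([60.0, 60.0, 70.0]), p, 65.0, "below", 0, 60)
    e2 = detect_episodes(_series([60.0, 60.0, 70.0]), p, 62.0, "below", 0, 60)
    with pytest.raises(ValueError, match="mix"):
        episode_features(e1 + e2, p)


# -- summarize -------------------------------------------------------------


def test_summary_statistics_examples():
    p = _period(300)
    one = summarize(_series([80.0]), p)
    assert one == {"count": 1, "min": 80.0, "max": 80.0, "mean": 80.0, "median": 80.0}
    four = summarize(_series([1.0, 2.0, 3.0, 4.0]), p)
    assert four["mean"] == 2.5 and four["median"] == 2.5
    empty = summarize(_series([]), p)
    assert empty["count"] == 0 and empty["mean"] is None


def test_summary_counts_only_ok_in_period_samples():
    flags = ["ok"] * 4 + ["out_of_range"] * 3
    s = _series([80.0] * 7, flags=flags)
    assert summarize(s, _period(7 * 30))["count"] == 4


# -- periods ---------------------------------------------------------------


def _events(rows):
    return pd.DataFrame(rows, columns=["intervention_id", "event_label", "ts", "kind"])


def test_period_from_anchor_events_with_offsets():
    ev = _events(
        [
            ("I1", "anesthesia_start", pd.Timestamp("2023-01-01 09:00"), "step"),
            ("I1", "anesthesia_end", pd.Timestamp("2023-01-01 10:00"), "step"),
        ]
    )
    p0 = pw.define_period(ev, "I1", PeriodRule("op", "anesthesia_start", 0, "anesthesia_end", 0))
    assert (p0.start_ts, p0.end_ts) == (pd.Timestamp("2023-01-01 09:00"), pd.Timestamp("2023-01-01 10:00"))
    p1 = pw.define_period(ev, "I1", PeriodRule("core", "anesthesia_start", 300, "anesthesia_end", -300))
    assert (p1.start_ts, p1.end_ts) == (pd.Timestamp("2023-01-01 09:05"), pd.Timestamp("2023-01-01 09:55"))


def test_missing_and_duplicate_anchors_raise():
    ev = _events(
        [
            ("I1", "anesthesia_start", pd.Timestamp("2023-01-01 09:00"), "step"),
            ("I1", "anesthesia_start", pd.Timestamp("2023-01-01 09:10"), "step"),
            ("I1", "anesthesia_end", pd.Timestamp("2023-01-01 10:00"), "step"),
        ]
    )
    with pytest.raises(PeriodUndefinedError, match="2 times"):
        pw.define_period(ev, "I1", PeriodRule("op", "anesthesia_start", 0, "anesthesia_end", 0))
    with pytest.raises(PeriodUndefinedError, match="not found"):
        pw.define_period(ev, "I1", PeriodRule("op", "surgery_start", 0, "anesthesia_end", 0))


# -- warehouse extraction --------------------------------------------------


def test_extraction_cardinality_and_determinism(warehouse):
    wh, _ = warehouse
    n_iv = len(wh.table("intervention"))
    spec = [pw.FeatureSpec(PeriodRule("intraop", "anesthesia_start", 0, "anesthesia_end", 0),
                           "MAP", "episode", {"threshold": 65.0, "direction": "below"})]
    t1 = pw.extract_features(wh, spec)
    assert len(t1) == 4 * n_iv  # n_episodes, total_time_s, total_area, deepest
    spec2 = spec + [pw.FeatureSpec(PeriodRule("intraop", "anesthesia_start", 0, "anesthesia_end", 0),
                                   "HR", "summary")]
    t2 = pw.extract_features(wh, spec2)
    assert len(t2) == len(t1) + 5 * n_iv
    pd.testing.assert_frame_equal(t1, pw.extract_features(wh, spec))


def test_recovers_injected_episode_counts_from_warehouse(warehouse, clean_bundle):
    """Within the intraoperative period, detected MAP<65 episodes match the
    injected ones clipped to the period: count exact, durations equal to
    the clipped overlap (episodes straddling the period boundary surface
    as their in-period part)."""
    wh, _ = warehouse
    _, truth = clean_bundle
    events = wh.table("event_record")
    meas = wh.table("measurement")
    rule = PeriodRule("intraop", "anesthesia_start", 0, "anesthesia_end", 0)
    n_checked = 0
    for iv_id in wh.table("intervention")["intervention_id"]:
        period = pw.define_period(events, iv_id, rule)
        s = meas[(meas["intervention_id"] == iv_id) & (meas["signal_code"] == "MAP")]
        got = detect_episodes(s, period, 65.0, "below", 60, 60)
        expected = []
        for ep in truth.injected_episodes:
            if ep.intervention_id != iv_id:
                continue
            start = max(pd.Timestamp(ep.start_ts), period.start_ts)
            end = min(pd.Timestamp(ep.end_ts), period.end_ts)
            clip = (end - start).total_seconds()
            if clip >= 60:
                expected.append((start, clip))
        assert len(got) == len(expected)
        got_by_start = {e.start_ts: e for e in got}
        for start, clip in expected:
            assert got_by_start[start].duration_s == clip
            n_checked += 1
    assert n_checked > 5
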