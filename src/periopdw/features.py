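"""Per-intervention, per-period features from ok-flagged measurements.

Intraoperative vital-sign series are irregularly sampled (nominally every
30 s, with gaps); the episode model treats each sample as holding until
the next one arrives, up to a configurable ``max_gap_s`` — a
last-observation-carried-forward (LOCF) step function. A threshold
episode is a maximal stretch of held time during which the value is
strictly beyond the threshold; its burden is the rectangle sum
``sum(|value - threshold| * held_duration)``. Episodes shorter than
``min_duration_s`` are discarded as one-sample artifacts.

This rectangle model has three properties worth the restriction: it is
honest to sampled data (no interpolation invents a crossing time), it is
monotone in the threshold, and it agrees exactly with a brute-force
per-second evaluation of the same step function, which the test suite
uses as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .etl import Warehouse

DEFAULT_MIN_DURATION_S = 60.0   # two samples at the 30 s cadence
DEFAULT_MAX_GAP_S = 300.0       # a sample's influence stops after 5 min

#: Shipped example thresholds — illustrative configuration, not clinical
#: guidance: hypotension MAP < 65 and < 50 mmHg, desaturation SpO2 < 90 %,
#: tachycardia HR > 100 bpm, bradycardia HR < 45 bpm.
EXAMPLE_THRESHOLDS: list[tuple[str, str, float, str]] = [
    ("hypotension_map65", "MAP", 65.0, "below"),
    ("severe_hypotension_map50", "MAP", 50.0, "below"),
    ("desaturation_spo2_90", "SPO2", 90.0, "below"),
    ("tachycardia_hr100", "HR", 100.0, "above"),
    ("bradycardia_hr45", "HR", 45.0, "below"),
]


class PeriodUndefinedError(ValueError):
    """An anchor event is missing or ambiguous; recorded, not fatal."""


class InvalidPeriodError(ValueError):
    """Derived period is empty or inverted."""


@dataclass(frozen=True)
class Period:
    """Half-open time window [start_ts, end_ts) attached to an intervention."""

    intervention_id: str
    name: str
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp

    def __post_init__(self):
        if self.start_ts >= self.end_ts:
            raise InvalidPeriodError(
                f"period {self.name!r} of {self.intervention_id}: "
                f"start {self.start_ts} not before end {self.end_ts}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end_ts - self.start_ts).total_seconds()


@dataclass(frozen=True)
class PeriodRule:
    """Anchor events ± offsets defining a period, e.g. the intraoperative
    window [anesthesia_start + 0 s, anesthesia_end + 0 s)."""

    name: str
    start_event: str
    start_offset_s: float = 0.0
    end_event: str = ""
    end_offset_s: float = 0.0


@dataclass(frozen=True)
class Episode:
    signal_code: str
    threshold: float
    direction: str  # "below" | "above"
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp
    duration_s: float
    area: float          # unit·s beyond the threshold
    extreme_value: float  # deepest sample (min for below, max for above)


def define_period(
    events: pd.DataFrame, intervention_id: str, rule: PeriodRule
) -> Period:
    """Derive a period from this intervention's step events.

    Each anchor must occur exactly once; a missing anchor raises
    PeriodUndefinedError and a duplicated one lists the timestamps.
    """
    ev = events[events["intervention_id"] == intervention_id]
    anchors = {}
    for which, label in (("start", rule.start_event), ("end", rule.end_event)):
        hits = ev[ev["event_label"] == label]
        if len(hits) == 0:
            raise PeriodUndefinedError(
                f"{intervention_id}: anchor event {label!r} not found"
            )
        if len(hits) > 1:
            ts_list = sorted(pd.Timestamp(t).isoformat() for t in hits["ts"])
            raise PeriodUndefinedError(
                f"{intervention_id}: anchor event {label!r} occurs "
                f"{len(hits)} times at {ts_list}"
            )
        anchors[which] = pd.Timestamp(hits["ts"].iloc[0])
    return Period(
        intervention_id=intervention_id,
        name=rule.name,
        start_ts=anchors["start"] + pd.Timedelta(seconds=rule.start_offset_s),
        end_ts=anchors["end"] + pd.Timedelta(seconds=rule.end_offset_s),
    )


def _ok_in_period(series: pd.DataFrame, period: Period) -> pd.DataFrame:
    """Ok-flagged samples with ts in [start, end), sorted by time."""
    df = series
    if "quality_flag" in df.columns:
        df = df[df["quality_flag"] == "ok"]
    ts = pd.to_datetime(df["ts"])
    df = df[(ts >= period.start_ts) & (ts < period.end_ts)]
    return df.sort_values("ts", kind="mergesort")


def summarize(series: pd.DataFrame, period: Period) -> dict[str, float | None]:
    """count / min / max / mean / median over ok samples in the period.

    Zero usable samples yield count 0 and null statistics, not an error.
    """
    used = _ok_in_period(series, period)
    values = used["value"].astype(float)
    if len(values) == 0:
        return {"count": 0, "min": None, "max": None, "mean": None, "median": None}
    return {
        "count": int(len(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "median": float(values.median()),
    }


def detect_episodes(
    series: pd.DataFrame,
    period: Period,
    threshold: float,
    direction: str,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> list[Episode]:
    """Maximal threshold excursions of the LOCF step function.

    Sample i holds over [t_i, min(t_{i+1}, t_i + max_gap_s, period.end)).
    Contiguous held stretches where the value is strictly beyond the
    threshold form candidate episodes; those shorter than
    ``min_duration_s`` are dropped. Per-episode area is the rectangle sum
    of |value - threshold| x held duration.
    """
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")

    used = _ok_in_period(series, period)
    if len(used) == 0:
        return []
    t = pd.to_datetime(used["ts"]).to_numpy()
    v = used["value"].astype(float).to_numpy()
    end = np.datetime64(period.end_ts)
    next_t = np.append(t[1:], end)
    hold_end = np.minimum(
        np.minimum(next_t, t + np.timedelta64(int(max_gap_s * 1e9), "ns")), end
    )
    held = (hold_end - t) / np.timedelta64(1, "s")
    beyond = v < threshold if direction == "below" else v > threshold

    episodes: list[Episode] = []
    i, n = 0, len(v)
    while i < n:
        if not beyond[i]:
            i += 1
            continue
        j = i
        # extend while the next sample is beyond AND contiguous in held time
        while j + 1 < n and beyond[j + 1] and hold_end[j] == t[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        duration = float(held[seg].sum())
        if duration >= min_duration_s and duration > 0:
            area = float(np.sum(np.abs(v[seg] - threshold) * held[seg]))
            extreme = float(v[seg].min() if direction == "below" else v[seg].max())
            episodes.append(
                Episode(
                    signal_code=str(used["signal_code"].iloc[0])
                    if "signal_code" in used.columns
                    else "",
                    threshold=threshold,
                    direction=direction,
                    start_ts=pd.Timestamp(t[i]),
                    end_ts=pd.Timestamp(hold_end[j]),
                    duration_s=duration,
                    area=area,
                    extreme_value=extreme,
                )
            )
        i = j + 1
    return episodes


def episode_features(
    episodes: Sequence[Episode], period: Period
) -> dict[str, float | None]:
    """n_episodes, total time, total area and deepest value over episodes
    that share one (signal, threshold, direction)."""
    if episodes:
        keys = {(e.threshold, e.direction) for e in episodes}
        if len(keys) > 1:
            raise ValueError(f"episodes mix thresholds/directions: {sorted(keys)}")
    if not episodes:
        return {"n_episodes": 0, "total_time_s": 0.0, "total_area": 0.0, "deepest_value": None}
    direction = episodes[0].direction
    extremes = [e.extreme_value for e in episodes]
    return {
        "n_episodes": len(episodes),
        "total_time_s": float(sum(e.duration_s for e in episodes)),
        "total_area": float(sum(e.area for e in episodes)),
        "deepest_value": float(min(extremes) if direction == "below" else max(extremes)),
    }


# ---------------------------------------------------------------------------
# Warehouse-level extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """One feature request: a period rule, a signal, and a kind.

    kind "summary" yields count/min/max/mean/median; kind "episode"
    yields n_episodes/total_time_s/total_area/deepest_value and requires
    params threshold + direction (min_duration_s, max_gap_s optional).
    """

    period_rule: PeriodRule
    signal_code: str
    kind: str  # "summary" | "episode"
    params: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        if self.kind == "episode":
            d = "lt" if self.params["direction"] == "below" else "gt"
            return f"{self.signal_code.lower()}_{d}{self.params['threshold']:g}"
        return f"{self.signal_code.lower()}"


def default_feature_spec() -> list[FeatureSpec]:
    intraop = PeriodRule("intraop", "anesthesia_start", 0, "anesthesia_end", 0)
    specs = [FeatureSpec(intraop, "MAP", "summary"), FeatureSpec(intraop, "HR", "summary")]
    for _, signal, threshold, direction in EXAMPLE_THRESHOLDS:
        specs.append(
            FeatureSpec(
                intraop, signal, "episode",
                {"threshold": threshold, "direction": direction},
            )
        )
    return specs


FEATURE_COLUMNS = [
    "intervention_id", "period", "feature", "value", "unit", "n_samples_used", "reason",
]


def extract_features(
    warehouse: Warehouse, feature_spec: Sequence[FeatureSpec]
) -> pd.DataFrame:
    """Long-form feature table: one row per (intervention, period, feature).

    Interventions whose period cannot be derived get null features with a
    reason code instead of being dropped. Deterministic for a fixed
    warehouse state: rows ordered by intervention, period, feature.
    """
    signals = set(warehouse.table("dim_signal")["signal_code"])
    for spec in feature_spec:
        if spec.kind not in ("summary", "episode"):
            raise ValueError(f"unknown feature kind {spec.kind!r}")
        if spec.signal_code not in signals:
            raise ValueError(f"unknown signal {spec.signal_code!r} in feature spec")

    interventions = warehouse.table("intervention").sort_values("intervention_id")
    events = warehouse.table("event_record")
    measurements = warehouse.table("measurement")
    units = dict(
        warehouse.table("dim_signal")[["signal_code", "unit"]].itertuples(index=False)
    )

    rows: list[tuple] = []
    for iv_id in interventions["intervention_id"]:
        for spec in feature_spec:
            try:
                period = define_period(events, iv_id, spec.period_rule)
            except (PeriodUndefinedError, InvalidPeriodError) as exc:
                reason = "period_undefined" if isinstance(exc, PeriodUndefinedError) else "invalid_period"
                names = (
                    ["count", "min", "max", "mean", "median"]
                    if spec.kind == "summary"
                    else ["n_episodes", "total_time_s", "total_area", "deepest_value"]
                )
                for nm in names:
                    rows.append(
                        (iv_id, spec.period_rule.name, f"{spec.label}_{nm}",
                         None, units.get(spec.signal_code), 0, reason)
                    )
                continue
            series = measurements[
                (measurements["intervention_id"] == iv_id)
                & (measurements["signal_code"] == spec.signal_code)
            ]
            n_used = len(_ok_in_period(series, period))
            if spec.kind == "summary":
                stats = summarize(series, period)
                for nm, val in stats.items():
                    rows.append(
                        (iv_id, period.name, f"{spec.label}_{nm}", val,
                         units.get(spec.signal_code), n_used, None)
                    )
            else:
                eps = detect_episodes(
                    series, period,
                    threshold=spec.params["threshold"],
                    direction=spec.params["direction"],
                    min_duration_s=spec.params.get("min_duration_s", DEFAULT_MIN_DURATION_S),
                    max_gap_s=spec.params.get("max_gap_s", DEFAULT_MAX_GAP_S),
                )
                feats = episode_features(eps, period)
                for nm, val in feats.items():
                    rows.append(
                        (iv_id, period.name, f"{spec.label}_{nm}", val,
                         units.get(spec.signal_code), n_used, None)
                    )
    out = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return out.sort_values(
        ["intervention_id", "period", "feature"], kind="mergesort"
    ).reset_index(drop=True)
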