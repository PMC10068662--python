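"""Synthetic AIMS / PMSI / biology / mortality source extracts with ground truth.

Every downstream stage of the warehouse (ETL, feature extraction, data
quality, OMOP export) is exercised against bundles produced here, so the
generator records exactly what it injected: hypotension-style vital-sign
excursions in a :class:`TruthLog`, and — via :func:`corrupt_bundle` —
deliberate data-entry corruptions of the kinds an anesthesia information
system accumulates over years of manual input and monitor changes.

The vitals model is a per-signal baseline plus AR(1) noise sampled on a
fixed 30-second grid, clipped to a clean physiological band that stays on
the safe side of the shipped alert thresholds; threshold excursions are
injected explicitly as level shifts so that each one is recoverable from
the emitted table by a direct scan.
"""

from __future__ import annotations

import dataclasses
import json
import unicodedata
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLING_STEP_S = 30  # monitor export cadence: one value every 30 s

# ---------------------------------------------------------------------------
# Signal and vocabulary catalogues
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalDef:
    """One monitored vital sign.

    ``clean_lo``/``clean_hi`` bound the baseline+noise process; they are
    chosen so that an un-injected series never crosses the shipped example
    thresholds (MAP 65/50, SpO2 90, HR 45/100). ``range_lo``/``range_hi``
    are the plausibility range used for quality flagging.
    """

    code: str
    unit: str
    baseline: float
    noise_sd: float
    clean_lo: float
    clean_hi: float
    range_lo: float
    range_hi: float


SIGNALS: dict[str, SignalDef] = {
    s.code: s
    for s in [
        SignalDef("MAP", "mmHg", 85.0, 3.0, 72.0, 108.0, 30.0, 200.0),
        SignalDef("SBP", "mmHg", 120.0, 5.0, 98.0, 155.0, 50.0, 260.0),
        SignalDef("DBP", "mmHg", 65.0, 3.0, 54.0, 92.0, 20.0, 150.0),
        SignalDef("HR", "bpm", 75.0, 4.0, 52.0, 97.0, 20.0, 250.0),
        SignalDef("SPO2", "%", 98.0, 0.6, 93.0, 100.0, 50.0, 100.0),
        SignalDef("ETCO2", "mmHg", 35.0, 1.5, 28.0, 45.0, 10.0, 80.0),
        SignalDef("TV", "mL", 450.0, 20.0, 350.0, 560.0, 0.0, 1500.0),
    ]
}

# drug → canonical dose unit and plausible bolus range
DRUGS: dict[str, tuple[str, float, float]] = {
    "propofol": ("mg", 80.0, 200.0),
    "sufentanil": ("ug", 10.0, 50.0),
    "rocuronium": ("mg", 30.0, 60.0),
    "ephedrine": ("mg", 3.0, 9.0),
    "cefazolin": ("mg", 1000.0, 2000.0),
}

STEP_EVENTS = ["anesthesia_start", "surgery_start", "surgery_end", "anesthesia_end"]

CARE_UNITS = ["CHIR_A", "CHIR_B", "ORTHO", "CARDIO", "REA_CHIR", "SSPI"]

ANALYTES: dict[str, tuple[str, float, float]] = {
    "HSTNT": ("ng/L", 3.0, 40.0),
    "HB": ("g/dL", 9.0, 16.0),
    "CREAT": ("umol/L", 50.0, 130.0),
}

# Small bundled ICD-10-like code list (synthetic labels, plausible codes).
ICD10_CODES: list[tuple[str, str]] = [
    ("I10", "essential hypertension"),
    ("I20.9", "angina pectoris"),
    ("I25.1", "atherosclerotic heart disease"),
    ("I48", "atrial fibrillation"),
    ("I50.9", "heart failure"),
    ("E11.9", "type 2 diabetes"),
    ("E66.9", "obesity"),
    ("E78.5", "hyperlipidaemia"),
    ("J44.9", "COPD"),
    ("J45.9", "asthma"),
    ("N18.3", "chronic kidney disease stage 3"),
    ("N18.5", "chronic kidney disease stage 5"),
    ("K80.2", "cholelithiasis"),
    ("K35.8", "acute appendicitis"),
    ("C18.9", "malignant neoplasm of colon"),
    ("C34.9", "malignant neoplasm of lung"),
    ("C61", "malignant neoplasm of prostate"),
    ("M16.9", "coxarthrosis"),
    ("M17.9", "gonarthrosis"),
    ("S72.0", "fracture of neck of femur"),
    ("I71.4", "abdominal aortic aneurysm"),
    ("I65.2", "occlusion of carotid artery"),
    ("D64.9", "anaemia"),
    ("F32.9", "depressive episode"),
    ("Z95.1", "presence of aortocoronary bypass graft"),
]

# CCAM-like procedure codes; the third element marks the extracorporeal
# circulation (ECC) subset used by the code-grouping feature.
CCAM_CODES: list[tuple[str, str, bool]] = [
    ("HHFA016", "appendicectomy", False),
    ("HMFC004", "cholecystectomy", False),
    ("NEKA020", "total hip replacement", False),
    ("NFKA007", "total knee replacement", False),
    ("JVJF004", "nephrectomy", False),
    ("GFFA004", "lobectomy of lung", False),
    ("HFFA011", "colectomy", False),
    ("DZEA003", "aortic valve replacement", False),
    ("DDMA006", "coronary artery bypass graft", False),
    ("EBLA002", "carotid endarterectomy", False),
    ("DGAA004", "abdominal aortic aneurysm repair", False),
    ("JQGA002", "caesarean section", False),
    ("LMMA012", "laminectomy", False),
    ("QZFA036", "skin graft", False),
    ("FELF004", "splenectomy", False),
    ("EQQF001", "extracorporeal circulation setup", True),
    ("EQQF002", "extracorporeal circulation monitoring", True),
    ("EQLF001", "cardiopulmonary bypass perfusion", True),
    ("EQLF002", "extracorporeal circulatory assistance", True),
    ("EQQP004", "extracorporeal circulation weaning", True),
]

ECC_CODES: frozenset[str] = frozenset(c for c, _, ecc in CCAM_CODES if ecc)

# Misspelled / brand-duplicated vocabulary variants injected by
# corrupt_bundle; the ETL's bundled synonym table maps them back.
MISSPELLED_VARIANTS: dict[str, str] = {
    "MAP": "PAM",            # French abbreviation entered by hand
    "SBP": "PAS",
    "DBP": "PAD",
    "HR": "FC",
    "SPO2": "SAT O2",
    "ETCO2": "ET CO2",
    "TV": "VOL COURANT",
}
BRAND_VARIANTS: dict[str, str] = {code: f"{code}-Mindray" for code in SIGNALS}

CORRUPTION_KINDS = (
    "missing_id",
    "wrong_unit",
    "out_of_range",
    "misspelled_vocab",
    "duplicate_vocab",
    "date_discordance",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

BUNDLE_TABLES = (
    "patients",
    "interventions",
    "measurements",
    "events",
    "stays",
    "unit_stays",
    "diagnoses",
    "procedures",
    "biology",
    "deaths",
)


@dataclass
class SourceBundle:
    """One coherent set of source extracts, as pandas DataFrames.

    Timestamps are second-resolution UTC; stay dates are day-resolution.
    Intervals are half-open ``[start, end)``.
    """

    patients: pd.DataFrame
    interventions: pd.DataFrame
    measurements: pd.DataFrame
    events: pd.DataFrame
    stays: pd.DataFrame
    unit_stays: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    biology: pd.DataFrame
    deaths: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in BUNDLE_TABLES}

    def copy(self) -> "SourceBundle":
        return SourceBundle(**{k: v.copy() for k, v in self.tables().items()})

    def to_csv(self, out_dir: str | Path) -> None:
        """Write one UTF-8 delimited file per table (ISO-8601 timestamps)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, src_dir: str | Path) -> "SourceBundle":
        src = Path(src_dir)
        frames = {}
        for name in BUNDLE_TABLES:
            df = pd.read_csv(src / f"{name}.csv", dtype=str, keep_default_na=False)
            frames[name] = _restore_types(name, df)
        return cls(**frames)


# column typing used for CSV round-trips and staging validation
TS_COLUMNS: dict[str, list[str]] = {
    "interventions": ["room_entry_ts", "room_exit_ts"],
    "measurements": ["ts"],
    "events": ["ts"],
    "unit_stays": ["start_ts", "end_ts"],
    "biology": ["ts"],
}
DATE_COLUMNS: dict[str, list[str]] = {
    "patients": ["birth_date"],
    "stays": ["admission_date", "discharge_date"],
    "deaths": ["death_date"],
}
FLOAT_COLUMNS: dict[str, list[str]] = {
    "measurements": ["value"],
    "events": ["dose"],
    "biology": ["value"],
}


def _restore_types(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.replace({"": None})
    for col in TS_COLUMNS.get(name, []):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    for col in DATE_COLUMNS.get(name, []):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    for col in FLOAT_COLUMNS.get(name, []):
        df[col] = pd.to_numeric(df[col])
    return df


@dataclass
class InjectedEpisode:
    intervention_id: str
    signal_code: str
    threshold: float
    direction: str  # "below" | "above"
    start_ts: datetime
    end_ts: datetime  # half-open
    depth: float

    @property
    def duration_s(self) -> float:
        return (self.end_ts - self.start_ts).total_seconds()


@dataclass
class InjectedCorruption:
    table: str
    row_key: int  # positional row index in the bundle table
    corruption_kind: str
    original: dict = field(default_factory=dict)


@dataclass
class TruthLog:
    """Ground truth for a generated (and possibly corrupted) bundle."""

    injected_episodes: list[InjectedEpisode] = field(default_factory=list)
    injected_corruptions: list[InjectedCorruption] = field(default_factory=list)

    def corruption_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.injected_corruptions:
            counts[c.corruption_kind] = counts.get(c.corruption_kind, 0) + 1
        return counts

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, (datetime, pd.Timestamp)):
                return o.isoformat()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        payload = {
            "injected_episodes": [dataclasses.asdict(e) for e in self.injected_episodes],
            "injected_corruptions": [dataclasses.asdict(c) for c in self.injected_corruptions],
        }
        Path(path).write_text(json.dumps(payload, default=_default, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLog":
        payload = json.loads(Path(path).read_text())
        episodes = [
            InjectedEpisode(
                intervention_id=e["intervention_id"],
                signal_code=e["signal_code"],
                threshold=e["threshold"],
                direction=e["direction"],
                start_ts=datetime.fromisoformat(e["start_ts"]),
                end_ts=datetime.fromisoformat(e["end_ts"]),
                depth=e["depth"],
            )
            for e in payload["injected_episodes"]
        ]
        corruptions = [InjectedCorruption(**c) for c in payload["injected_corruptions"]]
        return cls(episodes, corruptions)


@dataclass(frozen=True)
class EpisodeSpec:
    """Request to inject threshold excursions for one signal.

    ``episode_rate`` is the expected number of episodes per intervention
    (Poisson); ``depth_range`` is the excursion depth beyond the threshold
    in signal units; ``duration_range`` is in seconds and must consist of
    multiples of the 30 s sampling step.
    """

    signal_code: str
    threshold: float
    direction: str  # "below" | "above"
    episode_rate: float
    depth_range: tuple[float, float]
    duration_range: tuple[int, int]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _validate_episode_spec(spec: Sequence[EpisodeSpec]) -> None:
    for es in spec:
        if es.signal_code not in SIGNALS:
            raise ValueError(f"unknown signal_code {es.signal_code!r}")
        if es.direction not in ("below", "above"):
            raise ValueError(f"direction must be 'below' or 'above', got {es.direction!r}")
        lo, hi = es.duration_range
        if lo < SAMPLING_STEP_S:
            raise ValueError(
                f"episode duration {lo}s shorter than one {SAMPLING_STEP_S}s sampling step"
            )
        if lo % SAMPLING_STEP_S or hi % SAMPLING_STEP_S:
            raise ValueError("duration_range values must be multiples of the 30 s step")
        if hi < lo:
            raise ValueError("duration_range must be (min, max) with min <= max")
        if es.depth_range[0] <= 0:
            raise ValueError("episode depth must be positive")
        if es.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")


def _ar1_series(rng: np.random.Generator, sig: SignalDef, n: int) -> np.ndarray:
    """Baseline + AR(1) noise, clipped to the clean band."""
    phi = 0.9
    innov_sd = sig.noise_sd * np.sqrt(1.0 - phi**2)
    noise = np.empty(n)
    x = rng.normal(0.0, sig.noise_sd)
    for i in range(n):
        x = phi * x + rng.normal(0.0, innov_sd)
        noise[i] = x
    return np.clip(sig.baseline + noise, sig.clean_lo, sig.clean_hi).round(1)


def _place_episodes(
    rng: np.random.Generator, n_samples: int, n_episodes: int, dur_steps: np.ndarray
) -> list[tuple[int, int]]:
    """Pick non-overlapping [start, start+k) sample-index windows.

    A one-sample clean buffer is kept on both sides of every episode so
    that injected excursions never merge with each other and detected
    boundaries match the log exactly.
    """
    placed: list[tuple[int, int]] = []
    occupied = np.zeros(n_samples, dtype=bool)
    for k in dur_steps:
        k = int(k)
        candidates = [
            s
            for s in range(1, n_samples - k - 1)
            if not occupied[s - 1 : s + k + 1].any()
        ]
        if not candidates:
            continue
        s = int(rng.choice(candidates))
        occupied[s - 1 : s + k + 1] = True
        placed.append((s, s + k))
    return placed


def generate_bundle(
    n_patients: int,
    interventions_per_patient: float = 1.2,
    seed: int = 0,
    episode_spec: Sequence[EpisodeSpec] = (),
    dropout_rate: float = 0.0,
    start_date: date = date(2023, 1, 2),
    study_days: int = 365,
) -> tuple[SourceBundle, TruthLog]:
    """Generate a coherent AIMS+PMSI+biology+mortality extract.

    Deterministic for a fixed argument set and seed. Measurements are
    sampled on a 30 s grid inside each intervention's room window;
    episodes requested in ``episode_spec`` are injected as level shifts
    strictly beyond the threshold and logged exactly in the TruthLog.
    ``dropout_rate`` removes that fraction of non-episode samples to
    emulate monitor gaps.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if interventions_per_patient <= 0:
        raise ValueError("interventions_per_patient must be positive")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    episode_spec = list(episode_spec)
    _validate_episode_spec(episode_spec)

    rng = np.random.default_rng(seed)
    truth = TruthLog()

    # --- patients -----------------------------------------------------
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n_patients + 1)],
            "sex": rng.choice(["M", "F"], size=n_patients),
            "birth_date": [
                datetime(int(y), int(m), int(d))
                for y, m, d in zip(
                    rng.integers(1935, 2003, n_patients),
                    rng.integers(1, 13, n_patients),
                    rng.integers(1, 29, n_patients),
                )
            ],
        }
    )

    # --- interventions ------------------------------------------------
    iv_rows = []
    base = datetime.combine(start_date, datetime.min.time())
    for pid in patients["patient_id"]:
        n_iv = int(rng.poisson(interventions_per_patient))
        if n_iv == 0 and rng.random() < 0.5:
            n_iv = 1  # keep most patients surgical
        day0 = int(rng.integers(0, max(1, study_days - 30)))
        for j in range(n_iv):
            entry = base + timedelta(
                days=day0 + j * int(rng.integers(2, 10)),
                hours=int(rng.integers(8, 15)),
                minutes=int(rng.integers(0, 60)),
            )
            dur_steps = int(rng.integers(120, 360))  # 1 h – 3 h on the 30 s grid
            exit_ = entry + timedelta(seconds=dur_steps * SAMPLING_STEP_S)
            iv_rows.append((pid, entry, exit_, str(rng.choice(CARE_UNITS[:4]))))
    interventions = pd.DataFrame(
        iv_rows, columns=["patient_id", "room_entry_ts", "room_exit_ts", "unit_label"]
    )
    interventions.insert(
        0, "intervention_id", [f"I{i:05d}" for i in range(1, len(interventions) + 1)]
    )

    # --- measurements (+ injected episodes) ---------------------------
    meas_parts: list[pd.DataFrame] = []
    for iv in interventions.itertuples(index=False):
        n = int((iv.room_exit_ts - iv.room_entry_ts).total_seconds() // SAMPLING_STEP_S)
        grid = pd.DatetimeIndex(
            [iv.room_entry_ts + timedelta(seconds=i * SAMPLING_STEP_S) for i in range(n)]
        )
        protected = {code: np.zeros(n, dtype=bool) for code in SIGNALS}
        values = {code: _ar1_series(rng, SIGNALS[code], n) for code in SIGNALS}

        for es in episode_spec:
            n_ep = int(rng.poisson(es.episode_rate))
            if n_ep == 0:
                continue
            k_lo = es.duration_range[0] // SAMPLING_STEP_S
            k_hi = es.duration_range[1] // SAMPLING_STEP_S
            dur_steps = rng.integers(k_lo, k_hi + 1, size=n_ep)
            for s, e in _place_episodes(rng, n, n_ep, dur_steps):
                depth = float(
                    np.round(rng.uniform(es.depth_range[0], es.depth_range[1]), 1)
                )
                k = e - s
                # all samples strictly beyond threshold; deepest = threshold -/+ depth
                excur = np.round(rng.uniform(0.5, depth, size=k), 1)
                excur[int(rng.integers(0, k))] = depth
                sign = -1.0 if es.direction == "below" else 1.0
                vals = es.threshold + sign * excur
                values[es.signal_code][s:e] = vals
                protected[es.signal_code][s - 1 : e + 1] = True
                # one-sample buffers stay on the clean side of the threshold
                sig = SIGNALS[es.signal_code]
                for b in (s - 1, e):
                    if es.direction == "below":
                        values[es.signal_code][b] = max(
                            values[es.signal_code][b], es.threshold + 2.0
                        )
                    else:
                        values[es.signal_code][b] = min(
                            values[es.signal_code][b], es.threshold - 2.0
                        )
                truth.injected_episodes.append(
                    InjectedEpisode(
                        intervention_id=iv.intervention_id,
                        signal_code=es.signal_code,
                        threshold=es.threshold,
                        direction=es.direction,
                        start_ts=grid[s].to_pydatetime(),
                        end_ts=(grid[s] + timedelta(seconds=k * SAMPLING_STEP_S)).to_pydatetime(),
                        depth=depth,
                    )
                )

        for code in SIGNALS:
            keep = np.ones(n, dtype=bool)
            if dropout_rate > 0:
                drop = rng.random(n) < dropout_rate
                keep = ~(drop & ~protected[code])
            meas_parts.append(
                pd.DataFrame(
                    {
                        "intervention_id": iv.intervention_id,
                        "signal_code": code,
                        "ts": grid[keep],
                        "value": values[code][keep],
                        "unit_label": SIGNALS[code].unit,
                    }
                )
            )
    measurements = (
        pd.concat(meas_parts, ignore_index=True)
        if meas_parts
        else pd.DataFrame(columns=["intervention_id", "signal_code", "ts", "value", "unit_label"])
    )

    # --- events: anesthesia/surgery steps + drug boluses ---------------
    ev_rows = []
    for iv in interventions.itertuples(index=False):
        span = (iv.room_exit_ts - iv.room_entry_ts).total_seconds()
        offsets = {
            "anesthesia_start": 300,
            "surgery_start": 1200,
            "surgery_end": span - 900,
            "anesthesia_end": span - 300,
        }
        for label in STEP_EVENTS:
            ev_rows.append(
                (
                    iv.intervention_id,
                    label,
                    iv.room_entry_ts + timedelta(seconds=offsets[label]),
                    "step",
                    None,
                    None,
                )
            )
        n_drugs = int(rng.integers(2, 5))
        for name in rng.choice(list(DRUGS), size=n_drugs, replace=False):
            unit, lo, hi = DRUGS[str(name)]
            ts = iv.room_entry_ts + timedelta(
                seconds=int(rng.integers(300, max(600, int(span) - 600)))
            )
            ev_rows.append(
                (iv.intervention_id, str(name), ts, "drug", round(float(rng.uniform(lo, hi)), 1), unit)
            )
    events = pd.DataFrame(
        ev_rows, columns=["intervention_id", "event_label", "ts", "kind", "dose", "dose_unit"]
    )

    # --- PMSI: one stay per patient covering their interventions --------
    stay_rows, ustay_rows, diag_rows, proc_rows = [], [], [], []
    deaths_rows, bio_rows = [], []
    for i, pid in enumerate(patients["patient_id"], start=1):
        ivs = interventions[interventions["patient_id"] == pid]
        if len(ivs):
            admission = (ivs["room_entry_ts"].min() - timedelta(days=1)).normalize()
            discharge = (ivs["room_exit_ts"].max() + timedelta(days=int(rng.integers(2, 8)))).normalize()
        else:
            admission = (base + timedelta(days=int(rng.integers(0, study_days)))).replace(
                hour=0, minute=0, second=0
            )
            admission = pd.Timestamp(admission).normalize()
            discharge = admission + timedelta(days=int(rng.integers(1, 10)))
        dead = rng.random() < 0.03
        status = "death" if dead else str(rng.choice(["home", "transfer"], p=[0.85, 0.15]))
        stay_id = f"S{i:04d}"
        stay_rows.append((stay_id, pid, admission, discharge, status))

        ward = str(rng.choice(CARE_UNITS[:4]))
        ustay_rows.append(
            (f"{stay_id}U1", stay_id, ward, admission + timedelta(hours=10), discharge)
        )
        if rng.random() < 0.2:  # some patients pass through the ICU
            icu_start = admission + timedelta(days=1, hours=18)
            ustay_rows.append(
                (
                    f"{stay_id}U2",
                    stay_id,
                    "REA_CHIR",
                    icu_start,
                    min(pd.Timestamp(icu_start + timedelta(days=2)), discharge),
                )
            )

        for code, _label in [ICD10_CODES[int(j)] for j in rng.choice(len(ICD10_CODES), size=int(rng.integers(1, 4)), replace=False)]:
            diag_rows.append((stay_id, code))
        n_proc = int(rng.integers(1, 3))
        use_ecc = rng.random() < 0.2
        pool = [c for c, _, ecc in CCAM_CODES if not ecc]
        chosen = [str(c) for c in rng.choice(pool, size=n_proc, replace=False)]
        if use_ecc:
            chosen[0] = str(rng.choice(sorted(ECC_CODES)))
        for code in chosen:
            proc_rows.append((stay_id, code))

        for _ in range(int(rng.integers(2, 6))):
            analyte = str(rng.choice(list(ANALYTES)))
            unit, lo, hi = ANALYTES[analyte]
            ts = admission + timedelta(
                hours=float(rng.uniform(6, max(12.0, (discharge - admission).total_seconds() / 3600 - 6)))
            )
            bio_rows.append((pid, analyte, ts.floor("s"), round(float(rng.uniform(lo, hi)), 1), unit))

        if dead:
            deaths_rows.append((pid, discharge + timedelta(days=int(rng.integers(0, 30)))))

    stays = pd.DataFrame(
        stay_rows, columns=["stay_id", "patient_id", "admission_date", "discharge_date", "discharge_status"]
    )
    unit_stays = pd.DataFrame(
        ustay_rows, columns=["unit_stay_id", "stay_id", "unit_label", "start_ts", "end_ts"]
    )
    diagnoses = pd.DataFrame(diag_rows, columns=["stay_id", "code"])
    procedures = pd.DataFrame(proc_rows, columns=["stay_id", "code"])
    biology = pd.DataFrame(bio_rows, columns=["patient_id", "analyte", "ts", "value", "unit"])
    deaths = pd.DataFrame(deaths_rows, columns=["patient_id", "death_date"])
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])  # typed even when empty

    bundle = SourceBundle(
        patients=patients,
        interventions=interventions,
        measurements=measurements,
        events=events,
        stays=stays,
        unit_stays=unit_stays,
        diagnoses=diagnoses,
        procedures=procedures,
        biology=biology,
        deaths=deaths,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------


def corrupt_bundle(
    bundle: SourceBundle,
    corruption_spec: dict[str, float],
    seed: int = 0,
    truth: TruthLog | None = None,
) -> tuple[SourceBundle, TruthLog]:
    """Apply per-kind corruption rates and log every corrupted row.

    The number of rows corrupted per kind is ``round(rate * n_eligible)``;
    row sets are disjoint within a table so per-kind counts stay exact.
    Returns a corrupted copy plus a TruthLog extending ``truth`` (episodes
    carried over) with the injected corruptions.
    """
    for kind, rate in corruption_spec.items():
        if kind not in CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind {kind!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"corruption rate for {kind!r} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    out = bundle.copy()
    log = TruthLog(
        injected_episodes=list(truth.injected_episodes) if truth else [],
        injected_corruptions=list(truth.injected_corruptions) if truth else [],
    )

    used_meas: set[int] = set()

    def _pick(n_eligible: int, eligible: np.ndarray, rate: float) -> np.ndarray:
        n_corrupt = int(round(rate * n_eligible))
        if n_corrupt == 0 or len(eligible) == 0:
            return np.array([], dtype=int)
        n_corrupt = min(n_corrupt, len(eligible))
        return rng.choice(eligible, size=n_corrupt, replace=False)

    meas = out.measurements

    def _meas_eligible() -> np.ndarray:
        return np.array([i for i in range(len(meas)) if i not in used_meas], dtype=int)

    for kind in ("missing_id", "out_of_range", "misspelled_vocab", "duplicate_vocab"):
        rate = corruption_spec.get(kind, 0.0)
        if rate == 0.0:
            continue
        idx = _pick(len(meas), _meas_eligible(), rate)
        for i in idx:
            i = int(i)
            used_meas.add(i)
            orig = {
                "intervention_id": meas.at[i, "intervention_id"],
                "signal_code": meas.at[i, "signal_code"],
                "ts": pd.Timestamp(meas.at[i, "ts"]).isoformat(),
                "value": float(meas.at[i, "value"]),
            }
            if kind == "missing_id":
                meas.at[i, "intervention_id"] = None
            elif kind == "out_of_range":
                # +10000 exceeds every signal's plausibility range
                meas.at[i, "value"] = float(meas.at[i, "value"]) + 10000.0
            elif kind == "misspelled_vocab":
                meas.at[i, "signal_code"] = MISSPELLED_VARIANTS[orig["signal_code"]]
            else:
                meas.at[i, "signal_code"] = BRAND_VARIANTS[orig["signal_code"]]
            log.injected_corruptions.append(
                InjectedCorruption("measurements", i, kind, orig)
            )

    rate = corruption_spec.get("wrong_unit", 0.0)
    if rate > 0.0:
        ev = out.events
        mg_rows = np.array(
            [i for i in range(len(ev)) if ev.at[i, "kind"] == "drug" and ev.at[i, "dose_unit"] == "mg"],
            dtype=int,
        )
        for i in _pick(len(mg_rows), mg_rows, rate):
            i = int(i)
            orig = {"dose": float(ev.at[i, "dose"]), "dose_unit": "mg",
                    "event_label": ev.at[i, "event_label"],
                    "intervention_id": ev.at[i, "intervention_id"]}
            ev.at[i, "dose"] = float(ev.at[i, "dose"]) / 1000.0
            ev.at[i, "dose_unit"] = "g"
            log.injected_corruptions.append(InjectedCorruption("events", i, "wrong_unit", orig))

    rate = corruption_spec.get("date_discordance", 0.0)
    if rate > 0.0:
        st = out.stays
        with_iv = set(out.interventions["patient_id"].dropna())
        eligible = np.array(
            [i for i in range(len(st)) if st.at[i, "patient_id"] in with_iv], dtype=int
        )
        for i in _pick(len(eligible), eligible, rate):
            i = int(i)
            orig = {
                "stay_id": st.at[i, "stay_id"],
                "patient_id": st.at[i, "patient_id"],
                "admission_date": pd.Timestamp(st.at[i, "admission_date"]).isoformat(),
                "discharge_date": pd.Timestamp(st.at[i, "discharge_date"]).isoformat(),
            }
            st.at[i, "admission_date"] = st.at[i, "admission_date"] + timedelta(days=60)
            st.at[i, "discharge_date"] = st.at[i, "discharge_date"] + timedelta(days=60)
            log.injected_corruptions.append(InjectedCorruption("stays", i, "date_discordance", orig))

    return out, log
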