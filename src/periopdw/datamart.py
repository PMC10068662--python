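"""Denormalized datamarts: wide tables and cohort extraction.

The warehouse stores one row per record; cohort work wants one row per
statistical unit (patient, stay or intervention) with one column per
feature. ``pivot`` performs that reshaping, ``build_cohort`` applies
inclusion predicates and variable selection, and ``cohort_summary``
produces the percentage-of-cohort figures reported in study summaries.

Null handling in predicates is three-valued: a comparison against a null
cell is neither true nor false, and the row is excluded — the safe
behaviour for inclusion criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class PivotError(ValueError):
    """Duplicate (key, feature) pairs make the pivot ambiguous."""


class SpecError(ValueError):
    """A cohort spec references a column the wide table does not have."""


class UndefinedRateError(ZeroDivisionError):
    """A percentage over an empty denominator is undefined."""


VALID_UNITS = ("patient", "stay", "intervention")
UNIT_KEYS = {"patient": "patient_id", "stay": "stay_id", "intervention": "intervention_id"}


@dataclass
class WideTable:
    """One row per statistical unit, one column per feature."""

    unit: str
    key: str
    data: pd.DataFrame  # indexed by key column
    source_features: list[str] = field(default_factory=list)
    built_ts: datetime = field(default_factory=datetime.now)


def pivot(long_rows: pd.DataFrame, unit: str, key_col: str | None = None) -> WideTable:
    """Pivot a long-form feature table into a wide one-row-per-unit table.

    Missing (unit, feature) combinations become nulls; every non-null
    cell traces back to exactly one long-form row.
    """
    if unit not in VALID_UNITS:
        raise ValueError(f"unit must be one of {VALID_UNITS}, got {unit!r}")
    key_col = key_col or UNIT_KEYS[unit]
    dup = long_rows.duplicated(subset=[key_col, "feature"], keep=False)
    if dup.any():
        offenders = (
            long_rows.loc[dup, [key_col, "feature"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise PivotError(f"duplicate (key, feature) pairs: {sorted(offenders)[:10]}")
    wide = long_rows.pivot(index=key_col, columns="feature", values="value")
    wide = wide.sort_index().sort_index(axis=1)
    wide.columns.name = None
    return WideTable(
        unit=unit,
        key=key_col,
        data=wide,
        source_features=sorted(long_rows["feature"].unique()),
    )


def unpivot(wide: WideTable) -> pd.DataFrame:
    """Inverse of pivot, dropping nulls: the long-form rows as a set."""
    long = (
        wide.data.reset_index()
        .melt(id_vars=wide.key, var_name="feature", value_name="value")
        .dropna(subset=["value"])
    )
    return long.sort_values([wide.key, "feature"], kind="mergesort").reset_index(drop=True)


#: predicate operators with three-valued null semantics: a null operand
#: compares as unknown, excluding the row.
_OPS: dict[str, Callable[[pd.Series, object], pd.Series]] = {
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s.notna() & (s != v),
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    "in": lambda s, v: s.isin(list(v)),
    "notnull": lambda s, v: s.notna(),
}


@dataclass(frozen=True)
class Predicate:
    column: str
    op: str
    value: object = None


@dataclass
class CohortSpec:
    """Inclusion predicates (conjunction) and variable selection."""

    unit: str
    predicates: Sequence[Predicate] = ()
    variables: Sequence[str] = ()  # empty = all columns


def build_cohort(wide: WideTable, spec: CohortSpec) -> pd.DataFrame:
    """Rows satisfying every predicate, restricted to selected variables.

    Row order is deterministic (sorted by key). An empty result is a
    valid table with its header, not an error.
    """
    df = wide.data
    for pred in spec.predicates:
        if pred.column not in df.columns:
            raise SpecError(f"predicate references missing column {pred.column!r}")
        if pred.op not in _OPS:
            raise SpecError(f"unknown predicate operator {pred.op!r}")
    for var in spec.variables:
        if var not in df.columns:
            raise SpecError(f"selected variable {var!r} not in wide table")

    mask = pd.Series(True, index=df.index)
    for pred in spec.predicates:
        hit = _OPS[pred.op](df[pred.column], pred.value)
        mask &= hit.fillna(False).astype(bool)
    out = df.loc[mask]
    if spec.variables:
        out = out[list(spec.variables)]
    return out.sort_index()


def cohort_summary(n_flagged: int, n_total: int) -> float:
    """Percentage of a cohort carrying a flag, to 1 decimal, half-up.

    E.g. 240 of 387 patients -> 62.0; 166 of 387 -> 42.9.
    """
    if n_total <= 0:
        raise UndefinedRateError("cohort_summary: n_total must be positive")
    if not 0 <= n_flagged <= n_total:
        raise ValueError("cohort_summary: need 0 <= n_flagged <= n_total")
    pct = Decimal(100 * n_flagged) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
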