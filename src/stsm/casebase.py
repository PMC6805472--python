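"""Typed case-base data model, CSV readers/writers, validation and rare-value pooling.

A case base is a collection of clinical cases, each carrying a unique ID, an
overall-survival outcome (time + event/censoring status), optionally a
randomized therapy arm, and any number of nominal or numeric descriptive
attributes.  The on-disk representation is a plain RFC-4180 CSV with a header
row; the column roles are declared by a schema of :class:`AttributeSpec`.

Missing values are represented by the empty string or a configurable token
(default ``"NA"``) on disk, and by ``None`` (nominal) / ``NaN`` (numeric) in
memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AttributeSpec",
    "CaseRecord",
    "CaseBase",
    "ValidationReport",
    "read_case_base",
    "write_case_base",
    "validate",
    "pool_rare_values",
    "schema_from_yaml",
    "schema_to_yaml",
    "DEFAULT_STATUS_MAP",
    "DEFAULT_MISSING_TOKEN",
    "RARE_LABEL",
]

KINDS = ("nominal", "numeric", "id", "survival_time", "survival_status", "arm")

#: on-disk tokens accepted for the survival status (case-insensitive)
DEFAULT_STATUS_MAP: dict[str, int] = {
    "1": 1, "dead": 1, "deceased": 1, "event": 1, "true": 1,
    "0": 0, "alive": 0, "censored": 0, "false": 0,
}

DEFAULT_MISSING_TOKEN = "NA"

#: reserved label that rare nominal values are pooled into
RARE_LABEL = "__rare__"


@dataclass(frozen=True)
class AttributeSpec:
    """Declares one column of a case base: its name and role.

    ``positive_label`` marks, for a nominal attribute, which value counts as
    "biomarker present" when scoring against ground truth.
    """

    name: str
    kind: str
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if not self.name:
            raise ValueError("attribute name must be non-empty")


def _check_schema(schema: Sequence[AttributeSpec]) -> None:
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        raise ValueError("attribute names must be unique")
    for role in ("id", "survival_time", "survival_status"):
        n = sum(s.kind == role for s in schema)
        if n != 1:
            raise ValueError(f"schema must contain exactly one {role} column, found {n}")
    if sum(s.kind == "arm" for s in schema) > 1:
        raise ValueError("schema may contain at most one arm column")


@dataclass(frozen=True)
class CaseRecord:
    """One case: an ID, the attribute-value assignment and the survival outcome."""

    id: str
    values: Mapping[str, object]  # descriptive attributes; missing -> None
    survival_time: float
    survival_status: int  # 1 = deceased (event), 0 = alive (censored)
    arm: str | None = None

    def value(self, attribute: str) -> object:
        v = self.values.get(attribute)
        if isinstance(v, float) and math.isnan(v):
            return None
        return v


class CaseBase:
    """Schema plus an ordered collection of case records.

    Internally backed by a :class:`pandas.DataFrame` with one column per
    schema entry (id as string, survival time as float, status as 0/1 int,
    nominal attributes as object with ``None`` for missing, numeric attributes
    as float with ``NaN`` for missing).
    """

    def __init__(self, schema: Sequence[AttributeSpec], df: pd.DataFrame,
                 check: bool = True):
        _check_schema(schema)
        self.schema: list[AttributeSpec] = list(schema)
        missing_cols = [s.name for s in schema if s.name not in df.columns]
        if missing_cols:
            raise ValueError(f"data frame lacks schema columns {missing_cols}")
        self.df = df.loc[:, [s.name for s in schema]].reset_index(drop=True)
        if check:
            self._check_records()

    # -- role lookups -------------------------------------------------------
    def _col(self, kind: str) -> str:
        for s in self.schema:
            if s.kind == kind:
                return s.name
        raise KeyError(kind)

    @property
    def id_column(self) -> str:
        return self._col("id")

    @property
    def time_column(self) -> str:
        return self._col("survival_time")

    @property
    def status_column(self) -> str:
        return self._col("survival_status")

    @property
    def arm_column(self) -> str | None:
        try:
            return self._col("arm")
        except KeyError:
            return None

    @property
    def descriptive(self) -> list[AttributeSpec]:
        """The nominal and numeric attributes (outcome and ID columns excluded)."""
        return [s for s in self.schema if s.kind in ("nominal", "numeric")]

    def spec(self, name: str) -> AttributeSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- array views --------------------------------------------------------
    @property
    def n_cases(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df[self.id_column].to_numpy(dtype=object)

    @property
    def times(self) -> np.ndarray:
        return self.df[self.time_column].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        """1 where the case is deceased (event observed), 0 where censored."""
        return self.df[self.status_column].to_numpy(dtype=int)

    # -- record access ------------------------------------------------------
    def _row_to_record(self, row: pd.Series) -> CaseRecord:
        vals = {}
        for s in self.descriptive:
            v = row[s.name]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                vals[s.name] = None
            else:
                vals[s.name] = v
        arm = row[self.arm_column] if self.arm_column else None
        return CaseRecord(
            id=row[self.id_column],
            values=vals,
            survival_time=float(row[self.time_column]),
            survival_status=int(row[self.status_column]),
            arm=None if arm is None else str(arm),
        )

    def record(self, case_id: str) -> CaseRecord:
        sel = self.df[self.df[self.id_column] == case_id]
        if sel.empty:
            raise KeyError(f"no case with id {case_id!r}")
        return self._row_to_record(sel.iloc[0])

    def records(self) -> Iterator[CaseRecord]:
        for _, row in self.df.iterrows():
            yield self._row_to_record(row)

    def index_of(self, case_id: str) -> int:
        pos = np.nonzero(self.ids == case_id)[0]
        if len(pos) == 0:
            raise KeyError(f"no case with id {case_id!r}")
        return int(pos[0])

    # -- integrity ----------------------------------------------------------
    def _check_records(self) -> None:
        ids = self.df[self.id_column]
        if ids.isna().any() or (ids.astype(str) == "").any():
            raise ValueError("case IDs must be non-empty")
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate case id {dup.iloc[0]!r}")
        t = self.df[self.time_column]
        if t.isna().any():
            bad = int(t.index[t.isna()][0])
            raise ValueError(f"missing survival_time in row {bad + 1}")
        if (t < 0).any():
            bad = int(t.index[t < 0][0])
            raise ValueError(f"negative survival_time in row {bad + 1}")
        st = self.df[self.status_column]
        if st.isna().any() or ~st.isin([0, 1]).all():
            raise ValueError("survival_status must be 0 (alive) or 1 (deceased) for every case")

    def copy(self) -> "CaseBase":
        return CaseBase(self.schema, self.df.copy(), check=False)

    def __len__(self) -> int:
        return self.n_cases

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaseBase):
            return NotImplemented
        return self.schema == other.schema and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_case_base(path: str | Path,
                   schema: Sequence[AttributeSpec],
                   missing_token: str = DEFAULT_MISSING_TOKEN,
                   status_map: Mapping[str, int] | None = None) -> CaseBase:
    """Read a CSV case base, type-checking every cell against the schema.

    Empty cells and ``missing_token`` parse as absent values.  A numeric
    column containing a non-numeric, non-missing token is a hard error naming
    the offending row and column; so is a duplicate or missing ID, and a
    missing survival time or status.
    """
    _check_schema(schema)
    status_map = {k.lower(): v for k, v in (status_map or DEFAULT_STATUS_MAP).items()}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [s.name for s in schema]
    if set(raw.columns) != set(names):
        raise ValueError(
            f"header {sorted(raw.columns)} does not match schema columns {sorted(names)}")
    raw = raw.loc[:, names]

    def is_missing(s: pd.Series) -> pd.Series:
        return (s == "") | (s == missing_token)

    out = {}
    for spec in schema:
        col = raw[spec.name]
        miss = is_missing(col)
        if spec.kind in ("id", "arm", "nominal"):
            out[spec.name] = col.where(~miss, None)
        elif spec.kind in ("numeric", "survival_time"):
            num = pd.to_numeric(col.where(~miss, None), errors="coerce")
            bad = num.isna() & ~miss
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"non-numeric value {col[row]!r} in numeric column "
                    f"{spec.name!r}, data row {row + 1}")
            if spec.kind == "survival_time" and miss.any():
                row = int(miss.idxmax())
                raise ValueError(f"missing survival_time in data row {row + 1}")
            out[spec.name] = num.astype(float)
        elif spec.kind == "survival_status":
            if miss.any():
                row = int(miss.idxmax())
                raise ValueError(f"missing survival_status in data row {row + 1}")
            low = col.str.strip().str.lower()
            unknown = ~low.isin(status_map)
            if unknown.any():
                row = int(unknown.idxmax())
                raise ValueError(
                    f"unrecognized survival_status token {col[row]!r} in data row "
                    f"{row + 1}; accepted: {sorted(status_map)}")
            out[spec.name] = low.map(status_map).astype(int)
    return CaseBase(list(schema), pd.DataFrame(out))


def write_case_base(cb: CaseBase, path: str | Path) -> None:
    """Write a case base as RFC-4180 CSV; missing values become empty cells.

    ``read_case_base(write_case_base(cb))`` reproduces ``cb`` exactly (floats
    are written in shortest round-trip representation, status as 1/0).
    """
    out = cb.df.copy()
    out[cb.status_column] = out[cb.status_column].astype(int).astype(str)

    def fmt(v: object) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return "" if math.isnan(v) else repr(v)
        return str(v)

    for s in cb.schema:
        if s.kind in ("numeric", "survival_time"):
            out[s.name] = out[s.name].map(fmt)
        elif s.kind in ("nominal", "arm"):
            out[s.name] = out[s.name].map(fmt)
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# validation & pooling
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only summary of a case base (never mutates the input)."""

    n_cases: int
    missing_counts: dict[str, int]
    nominal_value_counts: dict[str, dict[str, int]]
    rare_values: dict[str, list[str]]
    anomalies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.anomalies


def validate(cb: CaseBase, rare_min_count: int = 5) -> ValidationReport:
    """Summarize missingness, nominal value counts and outcome anomalies.

    Nominal values backed by fewer than ``rare_min_count`` cases are flagged
    as rare (few observations yield rough, unreliable survival curves).
    """
    missing: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    rare: dict[str, list[str]] = {}
    anomalies: list[str] = []
    for s in cb.descriptive:
        col = cb.df[s.name]
        if s.kind == "numeric":
            missing[s.name] = int(col.isna().sum())
        else:
            missing[s.name] = int(col.isna().sum())
            vc = col.dropna().value_counts()
            counts[s.name] = {str(k): int(v) for k, v in vc.items()}
            flagged = [str(k) for k, v in vc.items() if v < rare_min_count]
            if flagged:
                rare[s.name] = flagged
    t = cb.df[cb.time_column]
    for row in t.index[t < 0]:
        anomalies.append(f"negative survival_time in row {int(row) + 1}")
    for row in t.index[t.isna()]:
        anomalies.append(f"missing survival_time in row {int(row) + 1}")
    st = cb.df[cb.status_column]
    for row in st.index[~st.isin([0, 1])]:
        anomalies.append(f"invalid survival_status in row {int(row) + 1}")
    if (st == 1).sum() == 0:
        anomalies.append("case base contains no deceased case")
    if (st == 0).sum() == 0:
        anomalies.append("case base contains no censored (alive) case")
    return ValidationReport(cb.n_cases, missing, counts, rare, anomalies)


def pool_rare_values(cb: CaseBase, min_count: int,
                     pooled_label: str = RARE_LABEL) -> CaseBase:
    """Replace nominal values backed by fewer than ``min_count`` cases.

    All rare values of an attribute map to the same reserved ``pooled_label``;
    numeric attributes and the number of records are untouched.  Raises if the
    reserved label is already a genuine value of an affected attribute.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    df = cb.df.copy()
    for s in cb.descriptive:
        if s.kind != "nominal":
            continue
        vc = df[s.name].dropna().value_counts()
        rare = {v for v, n in vc.items() if n < min_count}
        if not rare:
            continue
        if pooled_label in vc.index and pooled_label not in rare:
            raise ValueError(
                f"pooled label {pooled_label!r} already occurs as a value of {s.name!r}")
        df[s.name] = df[s.name].map(lambda v: pooled_label if v in rare else v)
    return CaseBase(cb.schema, df, check=False)


# ---------------------------------------------------------------------------
# schema config files
# ---------------------------------------------------------------------------

def schema_from_yaml(path: str | Path) -> tuple[list[AttributeSpec], dict]:
    """Load a schema config: column roles plus reader options.

    Returns ``(schema, options)`` where options may contain ``missing_token``
    and ``status_map`` for :func:`read_case_base`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    schema = []
    for entry in doc["columns"]:
        if isinstance(entry, str):
            raise ValueError("each column entry must be a mapping with name and kind")
        schema.append(AttributeSpec(
            name=entry["name"], kind=entry["kind"],
            positive_label=entry.get("positive_label")))
    _check_schema(schema)
    options = {}
    if "missing_token" in doc:
        options["missing_token"] = doc["missing_token"]
    if "status_map" in doc:
        options["status_map"] = {str(k): int(v) for k, v in doc["status_map"].items()}
    return schema, options


def schema_to_yaml(schema: Sequence[AttributeSpec], path: str | Path,
                   missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    doc = {
        "columns": [
            {k: v for k, v in
             (("name", s.name), ("kind", s.kind), ("positive_label", s.positive_label))
             if v is not None}
            for s in schema
        ],
        "missing_token": missing_token,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
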