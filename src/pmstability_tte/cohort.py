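"""Cohort container, delimited-text I/O, standardisation and follow-up summaries.

A :class:`Cohort` holds one row per individual: numeric predictor columns
(continuous predictors and 0/1 dummy columns for categorical ones), optional
follow-up (time in years + event indicator) and optional subgroup label
columns that need not enter any model (e.g. menopausal status for fairness
checks).  Files are plain CSV (header row, UTF-8, '.' decimal); column roles
are declared in a small YAML/JSON schema.

Missing values are a hard error everywhere: silently imputing them would
corrupt the information matrix downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DegeneratePredictorError, SchemaError, StateError, ValidationError

__all__ = [
    "ColumnInfo",
    "PredictorSpec",
    "CohortSchema",
    "Cohort",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "standardise",
    "destandardise",
    "summarise_followup",
]

_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class ColumnInfo:
    """Metadata for one (already numeric) predictor column."""

    name: str
    kind: str  # 'continuous' | 'binary' | 'dummy'
    standardised: bool = False
    mean: float | None = None  # original mean/SD when standardised
    sd: float | None = None


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor as declared in a schema (before dummy coding)."""

    name: str
    kind: str = "continuous"
    reference: str | None = None  # required for categorical predictors

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(
                f"predictor {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if self.kind == "categorical" and self.reference is None:
            raise SchemaError(
                f"categorical predictor {self.name!r} needs an explicit reference level"
            )


@dataclass(frozen=True)
class CohortSchema:
    """Column-role mapping for a cohort CSV file."""

    predictors: tuple[PredictorSpec, ...]
    time: str | None = None
    event: str | None = None
    id: str | None = None
    subgroups: tuple[str, ...] = ()
    filter: str | None = None  # pandas query applied before validation

    def __post_init__(self) -> None:
        if (self.time is None) != (self.event is None):
            raise SchemaError("time and event columns must be declared together")
        if not self.predictors:
            raise SchemaError("schema declares no predictor columns")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        preds = tuple(
            PredictorSpec(
                name=p["name"],
                kind=p.get("kind", "continuous"),
                reference=None if p.get("reference") is None else str(p["reference"]),
            )
            for p in d.get("predictors", [])
        )
        return cls(
            predictors=preds,
            time=d.get("time"),
            event=d.get("event"),
            id=d.get("id"),
            subgroups=tuple(d.get("subgroups", ())),
            filter=d.get("filter"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d: dict = {
            "predictors": [
                {k: v for k, v in dataclasses.asdict(p).items() if v is not None}
                for p in self.predictors
            ]
        }
        for key in ("time", "event", "id", "filter"):
            if getattr(self, key) is not None:
                d[key] = getattr(self, key)
        if self.subgroups:
            d["subgroups"] = list(self.subgroups)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Cohort:
    """Validated in-memory cohort.

    ``predictors`` is an all-numeric DataFrame (dummy columns already
    expanded); ``columns`` maps each predictor column to its metadata;
    ``time``/``event`` are either both present or both absent.
    """

    predictors: pd.DataFrame
    columns: dict[str, ColumnInfo]
    ids: pd.Index | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    subgroups: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if set(self.predictors.columns) != set(self.columns):
            raise ValidationError("predictor columns and column metadata disagree")
        if self.predictors.isna().any().any():
            col = self.predictors.columns[self.predictors.isna().any()][0]
            row = int(self.predictors.index[self.predictors[col].isna()][0])
            raise ValidationError(f"missing value in predictor {col!r} at row {row}")
        if (self.time is None) != (self.event is None):
            raise ValidationError("time and event must be both present or both absent")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=float)
            if len(self.time) != self.n or len(self.event) != self.n:
                raise ValidationError("follow-up length does not match cohort size")
            if np.isnan(self.time).any():
                row = int(np.flatnonzero(np.isnan(self.time))[0])
                raise ValidationError(f"missing follow-up time at row {row}")
            if (self.time <= 0).any():
                row = int(np.flatnonzero(self.time <= 0)[0])
                raise ValidationError(f"non-positive follow-up time at row {row}")
            bad = ~np.isin(self.event, (0.0, 1.0))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(f"event indicator not in {{0,1}} at row {row}")
        if self.ids is None:
            self.ids = pd.RangeIndex(self.n)

    @property
    def n(self) -> int:
        return len(self.predictors)

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def has_followup(self) -> bool:
        return self.time is not None

    def with_followup(self, time: np.ndarray, event: np.ndarray) -> "Cohort":
        """Return a copy with (possibly simulated) follow-up attached."""
        return replace(self, time=np.asarray(time, float), event=np.asarray(event, float))

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, bool)
        return Cohort(
            predictors=self.predictors.loc[mask].reset_index(drop=True),
            columns=dict(self.columns),
            ids=self.ids[mask],
            time=None if self.time is None else self.time[mask],
            event=None if self.event is None else self.event[mask],
            subgroups=None
            if self.subgroups is None
            else self.subgroups.loc[mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive follow-up summary: counts, person-years and event rate
    (events per person-year)."""

    n: int
    events: int
    person_years: float
    mean_followup: float
    max_followup: float
    event_rate: float


def read_cohort(path: str | Path, schema: CohortSchema) -> Cohort:
    """Read and validate a cohort CSV according to ``schema``.

    Categorical predictors are dummy-coded against their declared reference
    level (a level ``L`` of column ``c`` becomes column ``c_L``).  Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for bad cells, naming the offending row (0-based data row).
    """
    df = pd.read_csv(path)
    if schema.filter:
        df = df.query(schema.filter).reset_index(drop=True)

    declared = [p.name for p in schema.predictors] + list(schema.subgroups)
    for col in ("time", "event", "id"):
        if getattr(schema, col) is not None:
            declared.append(getattr(schema, col))
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"columns declared in schema but absent from file: {missing}")

    for c in declared:
        if df[c].isna().any():
            row = int(df.index[df[c].isna()][0])
            raise ValidationError(f"missing value in column {c!r} at row {row}")

    pred = {}
    meta: dict[str, ColumnInfo] = {}
    for spec in schema.predictors:
        col = df[spec.name]
        if spec.kind == "categorical":
            levels = [str(v) for v in pd.unique(col.astype(str))]
            if spec.reference not in levels:
                raise SchemaError(
                    f"reference level {spec.reference!r} not found in column {spec.name!r}"
                )
            for level in sorted(lv for lv in levels if lv != spec.reference):
                name = f"{spec.name}_{level}"
                pred[name] = (col.astype(str) == level).astype(float).to_numpy()
                meta[name] = ColumnInfo(name=name, kind="dummy")
        else:
            values = pd.to_numeric(col, errors="coerce")
            if values.isna().any():
                row = int(values.index[values.isna()][0])
                raise ValidationError(
                    f"non-numeric value in column {spec.name!r} at row {row}"
                )
            if spec.kind == "binary" and not np.isin(values, (0.0, 1.0)).all():
                row = int(values.index[~values.isin((0.0, 1.0))][0])
                raise ValidationError(
                    f"binary predictor {spec.name!r} not in {{0,1}} at row {row}"
                )
            pred[spec.name] = values.to_numpy(dtype=float)
            meta[spec.name] = ColumnInfo(name=spec.name, kind=spec.kind)

    return Cohort(
        predictors=pd.DataFrame(pred),
        columns=meta,
        ids=pd.Index(df[schema.id]) if schema.id else None,
        time=df[schema.time].to_numpy(float) if schema.time else None,
        event=df[schema.event].to_numpy(float) if schema.event else None,
        subgroups=df[list(schema.subgroups)].copy() if schema.subgroups else None,
    )


def write_cohort(cohort: Cohort, path: str | Path, id_column: str = "id") -> None:
    """Write a cohort back to CSV (predictors already dummy-coded).

    Standardised columns are written back on their raw scale (the file
    format has no metadata channel), so a re-read cohort scores
    consistently against a model carrying standardisation constants.
    Floats are written with ``repr`` precision so a read → write → read
    round trip reproduces numeric columns bit-identically.
    """
    if any(info.standardised for info in cohort.columns.values()):
        cohort = destandardise(cohort)
    out = pd.DataFrame({id_column: np.asarray(cohort.ids)})
    for c in cohort.predictors.columns:
        out[c] = cohort.predictors[c].to_numpy()
    if cohort.has_followup:
        out["time"] = cohort.time
        out["event"] = cohort.event.astype(int)
    if cohort.subgroups is not None:
        for c in cohort.subgroups.columns:
            out[c] = cohort.subgroups[c].to_numpy()
    out.to_csv(path, index=False)


def standardise(cohort: Cohort, columns: list[str] | tuple[str, ...]) -> Cohort:
    """Replace each named continuous column by (x − mean)/SD (sample SD,
    n−1 denominator) and store the (mean, SD) pair for reuse on new data."""
    pred = cohort.predictors.copy()
    meta = dict(cohort.columns)
    for name in columns:
        if name not in meta:
            raise SchemaError(f"no predictor column named {name!r}")
        if meta[name].kind != "continuous":
            raise SchemaError(f"column {name!r} is {meta[name].kind}, not continuous")
        x = pred[name].to_numpy(float)
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        if s == 0.0 or not np.isfinite(s):
            raise DegeneratePredictorError(f"column {name!r} has zero standard deviation")
        z = (x - m) / s
        # standardisation on this cohort must be exact to tight tolerance
        assert abs(float(np.mean(z))) < 1e-8 and abs(float(np.std(z, ddof=1)) - 1) < 1e-8
        pred[name] = z
        if meta[name].standardised:
            # compose with the previous transform so metadata still maps raw -> current
            m0, s0 = meta[name].mean, meta[name].sd
            m, s = m0 + m * s0, s * s0
        meta[name] = ColumnInfo(name=name, kind="continuous", standardised=True, mean=m, sd=s)
    return replace(cohort, predictors=pred, columns=meta)


def destandardise(cohort: Cohort, columns: list[str] | tuple[str, ...] | None = None) -> Cohort:
    """Invert :func:`standardise` using the stored (mean, SD) metadata."""
    pred = cohort.predictors.copy()
    meta = dict(cohort.columns)
    if columns is None:
        columns = [c for c, info in meta.items() if info.standardised]
    for name in columns:
        info = meta[name]
        if not info.standardised:
            raise StateError(f"column {name!r} is not standardised")
        pred[name] = pred[name].to_numpy(float) * info.sd + info.mean
        meta[name] = ColumnInfo(name=name, kind="continuous")
    return replace(cohort, predictors=pred, columns=meta)


def summarise_followup(cohort: Cohort) -> CohortSummary:
    """Counts, person-years, mean/max follow-up and the event rate per
    person-year (events / person-years, exactly)."""
    if not cohort.has_followup:
        raise StateError("cohort has no follow-up columns")
    t = cohort.time
    events = int(cohort.event.sum())
    person_years = float(t.sum())
    return CohortSummary(
        n=cohort.n,
        events=events,
        person_years=person_years,
        mean_followup=float(t.mean()),
        max_followup=float(t.max()),
        event_rate=events / person_years,
    )
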