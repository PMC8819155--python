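"""Typed in-memory representation of survey and nomination data.

Survey rows carry opaque string ids, a positive design weight, binary sex
coded ``F``/``M``, and named item/outcome columns with declared domains.
Nomination rows are directed (ego, alter) pairs labelled by the name
generator that elicited them.  CSV readers validate against a schema
sidecar (YAML or JSON); empty cells map to explicit missing values and are
never imputed.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SEX_CODES = ("F", "M")

#: Column-name prefix for generator-truth columns that analysis modules
#: must never read.  Kept in one place so tests can assert the contract.
TRUTH_PREFIX = "truth_"


class IntegrityError(ValueError):
    """A table violates a schema invariant (duplicate id, bad domain, ...)."""


class ParameterError(ValueError):
    """An operation was called with out-of-range parameters."""


# ---------------------------------------------------------------------------
# Domains


@dataclasses.dataclass(frozen=True)
class Domain:
    """Declared value domain for an item or outcome column.

    kind: ``binary`` (0/1), ``ordinal`` (integers in [lo, hi]),
    ``real`` (reals, optionally bounded), or ``categorical`` (token set).
    """

    kind: str
    lo: float | None = None
    hi: float | None = None
    levels: tuple[str, ...] | None = None

    def check(self, value: Any) -> bool:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return True  # missing is always acceptable; handled downstream
        if self.kind == "binary":
            try:
                return float(value) in (0.0, 1.0)
            except (TypeError, ValueError):
                return False
        if self.kind in ("ordinal", "real"):
            try:
                v = float(value)
            except (TypeError, ValueError):
                return False
            if self.kind == "ordinal" and v != int(v):
                return False
            if self.lo is not None and v < self.lo:
                return False
            if self.hi is not None and v > self.hi:
                return False
            return True
        if self.kind == "categorical":
            return self.levels is None or str(value) in self.levels
        raise ParameterError(f"unknown domain kind {self.kind!r}")


def _parse_domain(obj: Any) -> Domain:
    if isinstance(obj, str):
        return Domain(kind=obj)
    if isinstance(obj, Mapping):
        levels = obj.get("levels")
        return Domain(
            kind=obj["kind"],
            lo=obj.get("lo"),
            hi=obj.get("hi"),
            levels=tuple(levels) if levels else None,
        )
    raise ParameterError(f"cannot parse domain spec {obj!r}")


@dataclasses.dataclass
class SurveySchema:
    """Column-role declaration for a survey CSV.

    ``weight`` may be None, in which case every row gets weight 1.0
    (unweighted analyses are permitted).
    """

    person_id: str = "person_id"
    cluster_id: str = "cluster_id"
    stratum_id: str | None = None
    weight: str | None = None
    sex: str | None = None
    age: str | None = None
    group_keys: tuple[str, ...] = ()
    items: dict[str, Domain] = dataclasses.field(default_factory=dict)
    outcomes: dict[str, Domain] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SurveySchema":
        return cls(
            person_id=d.get("person_id", "person_id"),
            cluster_id=d.get("cluster_id", "cluster_id"),
            stratum_id=d.get("stratum_id"),
            weight=d.get("weight"),
            sex=d.get("sex"),
            age=d.get("age"),
            group_keys=tuple(d.get("group_keys", ())),
            items={k: _parse_domain(v) for k, v in d.get("items", {}).items()},
            outcomes={k: _parse_domain(v) for k, v in d.get("outcomes", {}).items()},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SurveySchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        def dom(d: Domain) -> Any:
            out: dict[str, Any] = {"kind": d.kind}
            if d.lo is not None:
                out["lo"] = d.lo
            if d.hi is not None:
                out["hi"] = d.hi
            if d.levels is not None:
                out["levels"] = list(d.levels)
            return out

        return {
            "person_id": self.person_id,
            "cluster_id": self.cluster_id,
            "stratum_id": self.stratum_id,
            "weight": self.weight,
            "sex": self.sex,
            "age": self.age,
            "group_keys": list(self.group_keys),
            "items": {k: dom(v) for k, v in self.items.items()},
            "outcomes": {k: dom(v) for k, v in self.outcomes.items()},
        }

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Tables


@dataclasses.dataclass
class SchemaReport:
    valid: bool
    violations: list[dict[str, Any]]


class SurveyTable:
    """Respondent-level survey records backed by a pandas DataFrame.

    One row per respondent.  The DataFrame is the canonical store; the
    schema maps column names to roles and value domains.  Missing cells
    are ``NaN`` and are preserved through read/write round-trips.
    """

    def __init__(self, df: pd.DataFrame, schema: SurveySchema, check: bool = True):
        self.df = df.reset_index(drop=True)
        self.schema = schema
        if check:
            report = validate(self)
            if not report.valid:
                v = report.violations[0]
                raise IntegrityError(
                    f"survey table invalid: {len(report.violations)} violation(s); "
                    f"first: row {v['row']}, field {v['field']!r}: {v['rule']}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def weights(self) -> pd.Series:
        if self.schema.weight and self.schema.weight in self.df.columns:
            return self.df[self.schema.weight].astype(float)
        return pd.Series(1.0, index=self.df.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise IntegrityError(f"column {name!r} not present in survey table")
        return self.df[name]

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.df.copy(), self.schema, check=False)


class NominationTable:
    """Directed nomination edge list: (ego, alter, generator, village)."""

    COLUMNS = ("ego_id", "alter_id", "generator", "village_id")

    def __init__(self, df: pd.DataFrame, generators: Sequence[str], check: bool = True):
        self.df = df.reset_index(drop=True)
        self.generators = tuple(generators)
        if check:
            report = validate(self)
            if not report.valid:
                v = report.violations[0]
                raise IntegrityError(
                    f"nomination table invalid: {len(report.violations)} violation(s); "
                    f"first: row {v['row']}, field {v['field']!r}: {v['rule']}"
                )

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Validation


def _validate_survey(table: SurveyTable) -> list[dict[str, Any]]:
    df, sch = table.df, table.schema
    out: list[dict[str, Any]] = []
    if sch.person_id not in df.columns:
        return [{"row": -1, "field": sch.person_id, "rule": "id column missing"}]
    ids = df[sch.person_id].astype(str)
    dup = ids[ids.duplicated(keep=False)]
    for row in dup.index:
        out.append(
            {"row": int(row), "field": sch.person_id,
             "rule": f"duplicate person_id {ids[row]!r}"}
        )
    if sch.cluster_id not in df.columns:
        out.append({"row": -1, "field": sch.cluster_id, "rule": "cluster column missing"})
    else:
        miss = df[sch.cluster_id].isna()
        for row in df.index[miss]:
            out.append({"row": int(row), "field": sch.cluster_id, "rule": "missing cluster_id"})
    if sch.weight and sch.weight in df.columns:
        w = pd.to_numeric(df[sch.weight], errors="coerce")
        bad = ~(w > 0)
        for row in df.index[bad]:
            out.append({"row": int(row), "field": sch.weight, "rule": "weight must be > 0"})
    if sch.sex and sch.sex in df.columns:
        sexvals = df[sch.sex]
        bad = ~(sexvals.isna() | sexvals.isin(SEX_CODES))
        for row in df.index[bad]:
            out.append(
                {"row": int(row), "field": sch.sex,
                 "rule": f"sex must be one of {SEX_CODES}, got {sexvals[row]!r}"}
            )
    if sch.age and sch.age in df.columns:
        a = pd.to_numeric(df[sch.age], errors="coerce")
        bad = a.notna() & (a < 0)
        for row in df.index[bad]:
            out.append({"row": int(row), "field": sch.age, "rule": "age must be >= 0"})
    for name, domain in {**sch.items, **sch.outcomes}.items():
        if name not in df.columns:
            out.append({"row": -1, "field": name, "rule": "declared column missing"})
            continue
        col = df[name]
        if domain.kind in ("binary", "ordinal", "real"):
            v = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & v.isna()  # non-numeric where a number is required
            ok = v.notna()
            if domain.kind == "binary":
                bad |= ok & ~v.isin([0, 1])
            else:
                if domain.kind == "ordinal":
                    bad |= ok & (v != np.floor(v))
                if domain.lo is not None:
                    bad |= ok & (v < domain.lo)
                if domain.hi is not None:
                    bad |= ok & (v > domain.hi)
            bad_rows = df.index[bad]
        else:
            bad_rows = [r for r in df.index if not domain.check(col[r])]
        for row in bad_rows:
            out.append(
                {"row": int(row), "field": name,
                 "rule": f"value {col[row]!r} outside declared {domain.kind} domain"}
            )
    return out


def _validate_nominations(table: NominationTable) -> list[dict[str, Any]]:
    df = table.df
    out: list[dict[str, Any]] = []
    for c in NominationTable.COLUMNS:
        if c not in df.columns:
            return [{"row": -1, "field": c, "rule": "column missing"}]
    selfties = df["ego_id"].astype(str) == df["alter_id"].astype(str)
    for row in df.index[selfties]:
        out.append({"row": int(row), "field": "alter_id", "rule": "self-nomination"})
    unknown = ~df["generator"].isin(table.generators)
    for row in df.index[unknown]:
        out.append(
            {"row": int(row), "field": "generator",
             "rule": f"unknown generator label {df['generator'][row]!r}"}
        )
    trip = df[["ego_id", "alter_id", "generator"]].astype(str)
    dup = trip.duplicated(keep="first")
    for row in df.index[dup]:
        out.append(
            {"row": int(row), "field": "generator",
             "rule": "duplicate (ego, alter, generator) triple"}
        )
    return out


def validate(table: SurveyTable | NominationTable) -> SchemaReport:
    """Enumerate every invariant violation; never raises."""
    if isinstance(table, SurveyTable):
        violations = _validate_survey(table)
    else:
        violations = _validate_nominations(table)
    return SchemaReport(valid=not violations, violations=violations)


# ---------------------------------------------------------------------------
# Readers / writers


def read_survey(path: str | Path | io.IOBase, schema: SurveySchema | str | Path) -> SurveyTable:
    """Read a survey CSV against a schema; missing cells stay missing.

    Raises IntegrityError on duplicate ids, zero/negative weights, or
    values outside a declared domain (naming the row and field).
    """
    if not isinstance(schema, SurveySchema):
        schema = SurveySchema.from_file(schema)
    try:
        df = pd.read_csv(path, dtype={schema.person_id: str, schema.cluster_id: str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParameterError(f"malformed CSV: {exc}") from exc
    return SurveyTable(df, schema)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write the table back out, mirroring the reader's column order."""
    table.df.to_csv(path, index=False)


def read_nominations(path: str | Path | io.IOBase, generators: Sequence[str]) -> NominationTable:
    """Read a nomination edge list, de-duplicating (ego, alter, generator).

    Up to 14 generator labels may be declared; unknown labels and
    self-nominations are integrity errors.
    """
    if len(generators) > 14:
        raise ParameterError("at most 14 name generators are supported")
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParameterError(f"malformed CSV: {exc}") from exc
    table = NominationTable(df, generators, check=False)
    # duplicates are silently collapsed; anything else is an integrity error
    hard = [v for v in validate(table).violations
            if "duplicate" not in v["rule"]]
    if hard:
        v = hard[0]
        raise IntegrityError(
            f"nomination table invalid: {len(hard)} violation(s); "
            f"first: row {v['row']}, field {v['field']!r}: {v['rule']}"
        )
    deduped = df.drop_duplicates(subset=["ego_id", "alter_id", "generator"])
    return NominationTable(deduped, generators, check=False)


def write_nominations(table: NominationTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
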