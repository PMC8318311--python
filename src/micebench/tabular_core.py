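"""Typed tabular data model with explicit missing cells.

A :class:`TypedTable` is a column-typed table (categorical or numeric
columns, exactly one of them a classification target) in which missingness
is first-class: a missing cell is representable in every column and is
distinguishable from every observed value, including the empty string.
Categorical domains are frozen when a table is constructed, so that
imputation can never invent a level that was not observed in the source
data and so that mode pooling and accuracy scoring operate over a closed
set of levels.

Tables are stored as a :class:`pandas.DataFrame` with ``float64`` numeric
columns (missing = NaN) and ``object`` categorical columns of strings
(missing = ``None``).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

DEFAULT_MISSING_TOKENS = frozenset({"?", "NA", ""})


class ColumnKind(str, enum.Enum):
    CATEGORICAL = "categorical"
    NUMERIC = "numeric"


class ColumnRole(str, enum.Enum):
    FEATURE = "feature"
    TARGET = "target"


class Mechanism(str, enum.Enum):
    """Missingness mechanism: cell loss independent of everything (MCAR)
    or driven by an observed covariate (MAR)."""

    MCAR = "MCAR"
    MAR = "MAR"


class SchemaError(ValueError):
    """Schema is invalid or does not match the data it describes."""


class TypedParseError(ValueError):
    """A cell could not be parsed under its declared column kind."""


@dataclass(frozen=True)
class ColumnSchema:
    """Declared name, kind and role of one column."""

    name: str
    kind: ColumnKind
    role: ColumnRole = ColumnRole.FEATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ColumnKind(self.kind))
        object.__setattr__(self, "role", ColumnRole(self.role))


def _validate_schema(schema: Sequence[ColumnSchema]) -> None:
    names = [c.name for c in schema]
    if len(set(names)) != len(names):
        raise SchemaError(f"duplicate column names in schema: {names}")
    targets = [c.name for c in schema if c.role is ColumnRole.TARGET]
    if len(targets) != 1:
        raise SchemaError(
            f"schema must declare exactly one target column, got {targets}"
        )


class TypedTable:
    """A column-typed table with explicit missing cells and a frozen
    categorical domain per categorical column.

    Parameters
    ----------
    schema:
        One :class:`ColumnSchema` per column, in column order.  Exactly one
        column must have ``role=target``.
    df:
        The cell grid.  Numeric columns must be coercible to float with NaN
        marking missing cells; categorical columns hold strings with
        ``None``/NaN marking missing cells.
    domains:
        Optional frozen level sets for categorical columns.  When omitted
        they are frozen from the observed values of ``df``.  Observed
        categorical cells must lie inside the frozen domain.
    """

    def __init__(
        self,
        schema: Sequence[ColumnSchema],
        df: pd.DataFrame,
        domains: dict[str, tuple[str, ...]] | None = None,
    ) -> None:
        _validate_schema(schema)
        schema = tuple(schema)
        names = [c.name for c in schema]
        if list(df.columns) != names:
            if set(df.columns) != set(names):
                raise SchemaError(
                    f"data columns {sorted(df.columns)} do not match schema "
                    f"columns {sorted(names)}"
                )
            df = df[names]
        df = df.copy()
        df.index = pd.RangeIndex(len(df))
        frozen: dict[str, tuple[str, ...]] = {}
        for col in schema:
            s = df[col.name]
            if col.kind is ColumnKind.NUMERIC:
                try:
                    s = s.astype(float)
                except (TypeError, ValueError) as exc:
                    raise TypedParseError(
                        f"column {col.name!r}: {exc}"
                    ) from None
                if np.isinf(s.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise TypedParseError(
                        f"column {col.name!r} contains non-finite values"
                    )
                df[col.name] = s
            else:
                vals = s.to_numpy(dtype=object)
                cleaned = np.array(
                    [None if _is_na(v) else str(v) for v in vals], dtype=object
                )
                df[col.name] = cleaned
                observed = sorted({v for v in cleaned if v is not None})
                if domains is not None and col.name in domains:
                    dom = tuple(domains[col.name])
                    outside = [v for v in observed if v not in dom]
                    if outside:
                        raise SchemaError(
                            f"column {col.name!r}: observed levels {outside} "
                            f"outside frozen domain {dom}"
                        )
                    frozen[col.name] = dom
                else:
                    frozen[col.name] = tuple(observed)
        self.schema: tuple[ColumnSchema, ...] = schema
        self.df: pd.DataFrame = df
        self.domains: dict[str, tuple[str, ...]] = frozen

    # -- basic accessors ---------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.schema]

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.schema if c.role is ColumnRole.FEATURE]

    @property
    def target_name(self) -> str:
        return next(c.name for c in self.schema if c.role is ColumnRole.TARGET)

    def column(self, name: str) -> ColumnSchema:
        for c in self.schema:
            if c.name == name:
                return c
        raise KeyError(name)

    def kind_of(self, name: str) -> ColumnKind:
        return self.column(name).kind

    # -- missingness -------------------------------------------------------

    def missing_frame(self) -> pd.DataFrame:
        """Boolean grid over all columns; True marks a MISSING cell."""
        return self.df.isna()

    def feature_missing_values(self) -> np.ndarray:
        """Boolean (n_rows, n_features) array over feature columns only."""
        return self.df[self.feature_names].isna().to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.missing_frame().to_numpy().sum())

    # -- structural helpers ------------------------------------------------

    def copy(self) -> "TypedTable":
        return TypedTable(self.schema, self.df, domains=self.domains)

    def with_values(self, df: pd.DataFrame) -> "TypedTable":
        """Same schema and frozen domains, new cell grid."""
        return TypedTable(self.schema, df, domains=self.domains)

    def select_columns(self, names: Sequence[str]) -> "TypedTable":
        keep = [c for c in self.schema if c.name in set(names)]
        return TypedTable(
            keep,
            self.df[[c.name for c in keep]],
            domains={k: v for k, v in self.domains.items()
                     if k in {c.name for c in keep}},
        )

    def equals(self, other: "TypedTable") -> bool:
        if self.schema != other.schema or self.domains != other.domains:
            return False
        for col in self.schema:
            a, b = self.df[col.name], other.df[col.name]
            if col.kind is ColumnKind.NUMERIC:
                an = a.to_numpy(dtype=float)
                bn = b.to_numpy(dtype=float)
                if an.shape != bn.shape:
                    return False
                same = (an == bn) | (np.isnan(an) & np.isnan(bn))
                if not same.all():
                    return False
            else:
                if not a.fillna("\x00NA").equals(b.fillna("\x00NA")):
                    return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TypedTable({self.n_rows} rows, "
            f"{len(self.feature_names)} features, target "
            f"{self.target_name!r}, {self.n_missing} missing)"
        )


def _is_na(v: object) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


@dataclass(frozen=True)
class MissingnessMask:
    """Record of which feature cells of a companion table were amputed.

    ``values`` is a boolean (n_rows, n_features) grid aligned with the
    companion table's feature columns; the target column is never masked.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    rate: float
    mechanism: Mechanism
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if v.ndim != 2 or v.shape[1] != len(self.feature_names):
            raise ValueError("mask shape does not match feature names")

    @property
    def n_missing(self) -> int:
        return int(self.values.sum())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def matches(self, table: TypedTable) -> bool:
        """True iff mask True-cells correspond exactly to the table's
        MISSING feature cells."""
        if tuple(table.feature_names) != self.feature_names:
            return False
        return bool(
            np.array_equal(table.feature_missing_values(), self.values)
        )


# -- CSV / schema I/O ------------------------------------------------------


def read_table(
    path: str | Path | io.TextIOBase,
    schema: Sequence[ColumnSchema],
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    drop_preexisting_missing: bool = False,
) -> TypedTable:
    """Read a header-bearing CSV into a :class:`TypedTable`.

    Any cell whose raw text is in ``missing_tokens`` becomes MISSING.
    ``drop_preexisting_missing`` removes rows containing any MISSING cell
    after parsing, for workflows that require a complete ground-truth table
    from a source file that already carries missing markers.
    """
    _validate_schema(schema)
    tokens = set(missing_tokens)
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[], skip_blank_lines=True
    )
    names = [c.name for c in schema]
    if set(raw.columns) != set(names):
        raise SchemaError(
            f"CSV header {sorted(raw.columns)} does not match schema "
            f"columns {sorted(names)}"
        )
    raw = raw[names]
    data: dict[str, object] = {}
    for col in schema:
        cells = raw[col.name].to_numpy(dtype=object)
        is_missing = np.array([c in tokens for c in cells], dtype=bool)
        if col.kind is ColumnKind.NUMERIC:
            out = np.full(len(cells), np.nan)
            for i, (c, miss) in enumerate(zip(cells, is_missing)):
                if miss:
                    continue
                try:
                    out[i] = float(c)
                except ValueError:
                    raise TypedParseError(
                        f"row {i}, column {col.name!r}: cannot parse "
                        f"{c!r} as numeric"
                    ) from None
                if not np.isfinite(out[i]):
                    raise TypedParseError(
                        f"row {i}, column {col.name!r}: non-finite value {c!r}"
                    )
            data[col.name] = out
        else:
            data[col.name] = np.array(
                [None if miss else str(c) for c, miss in zip(cells, is_missing)],
                dtype=object,
            )
    table = TypedTable(schema, pd.DataFrame(data))
    if drop_preexisting_missing:
        keep = ~table.missing_frame().any(axis=1)
        table = table.with_values(table.df.loc[keep])
    return table


def write_table(
    table: TypedTable, path: str | Path | io.TextIOBase, missing_token: str = "?"
) -> None:
    """Write a TypedTable as a header-bearing CSV, rendering MISSING cells
    as ``missing_token``.  ``read_table`` with the same schema and
    ``missing_tokens={missing_token}`` inverts it exactly (numeric cells are
    written with ``repr``, which round-trips floats)."""
    for col in table.schema:
        if col.kind is ColumnKind.CATEGORICAL:
            if missing_token in table.domains.get(col.name, ()):
                raise ValueError(
                    f"missing token {missing_token!r} collides with an "
                    f"observed level of column {col.name!r}"
                )
    out = {}
    for col in table.schema:
        s = table.df[col.name]
        if col.kind is ColumnKind.NUMERIC:
            out[col.name] = [
                missing_token if np.isnan(v) else repr(float(v))
                for v in s.to_numpy(dtype=float)
            ]
        else:
            out[col.name] = [
                missing_token if v is None else v
                for v in s.to_numpy(dtype=object)
            ]
    pd.DataFrame(out).to_csv(path, index=False)


def schema_from_yaml(path: str | Path | io.TextIOBase) -> list[ColumnSchema]:
    """Load a sidecar schema: a YAML list of {name, kind, role} mappings."""
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            spec = yaml.safe_load(fh)
    else:
        spec = yaml.safe_load(path)
    cols = [
        ColumnSchema(
            name=str(entry["name"]),
            kind=ColumnKind(entry["kind"]),
            role=ColumnRole(entry.get("role", "feature")),
        )
        for entry in spec
    ]
    _validate_schema(cols)
    return cols


def schema_to_yaml(schema: Sequence[ColumnSchema], path: str | Path) -> None:
    payload = [
        {"name": c.name, "kind": c.kind.value, "role": c.role.value}
        for c in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
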