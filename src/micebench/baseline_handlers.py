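"""Baseline missing-data handlers: marginal replacement and deletion.

These are the simple strategies the chained-equation engine is benchmarked
against: replacing missing values with a column's mean/median (numeric) or
mode (categorical), deleting every row with a missing cell (listwise /
complete-case analysis), or deleting every feature column containing a
missing cell.
"""

from __future__ import annotations

import enum

import numpy as np

from .tabular_core import ColumnKind, ColumnRole, TypedTable


class HandlerName(str, enum.Enum):
    MICE = "mice"
    MEAN_MODE = "mean_mode"
    MEDIAN = "median"
    LISTWISE = "listwise"
    DROP_VARIABLES = "drop_variables"


class HandlerError(RuntimeError):
    pass


def column_mode(values: np.ndarray) -> str:
    """Most frequent observed level; ties go to the lexicographically
    smallest level."""
    observed = [v for v in values if v is not None]
    if not observed:
        raise HandlerError("mode of a fully-missing column is undefined")
    levels, counts = np.unique(np.array(observed, dtype=object), return_counts=True)
    return str(levels[np.argmax(counts)])  # np.unique sorts, argmax keeps first


def impute_marginal(
    amputed: TypedTable, statistic: str | HandlerName = HandlerName.MEAN_MODE
) -> TypedTable:
    """Fill numeric MISSING cells with the observed column mean (or median)
    and categorical MISSING cells with the observed column mode."""
    statistic = HandlerName(statistic)
    if statistic not in (HandlerName.MEAN_MODE, HandlerName.MEDIAN):
        raise ValueError(f"not a marginal statistic: {statistic}")
    df = amputed.df.copy()
    for col in amputed.schema:
        if col.role is ColumnRole.TARGET:
            continue
        if col.kind is ColumnKind.NUMERIC:
            vals = df[col.name].to_numpy(dtype=float).copy()
            miss = np.isnan(vals)
            if not miss.any():
                continue
            observed = vals[~miss]
            if observed.size == 0:
                raise HandlerError(
                    f"column {col.name!r} is fully missing; marginal "
                    "imputation is undefined"
                )
            fill = (
                float(np.mean(observed))
                if statistic is HandlerName.MEAN_MODE
                else float(np.median(observed))
            )
            vals[miss] = fill
            df[col.name] = vals
        else:
            vals = df[col.name].to_numpy(dtype=object).copy()
            miss = np.array([v is None for v in vals])
            if not miss.any():
                continue
            vals[miss] = column_mode(vals)
            df[col.name] = vals
    return amputed.with_values(df)


def listwise_delete(amputed: TypedTable) -> TypedTable:
    """Keep only rows with zero MISSING feature cells (complete-case
    analysis).  Raises if no row survives."""
    miss = amputed.feature_missing_values()
    keep = ~miss.any(axis=1)
    if not keep.any():
        raise HandlerError(
            "listwise deletion removed every row: no complete case remains"
        )
    return amputed.with_values(amputed.df.loc[keep])


def drop_variables(amputed: TypedTable) -> TypedTable:
    """Keep only feature columns with zero MISSING cells, plus the target.
    Raises if no feature column survives."""
    miss = amputed.feature_missing_values()
    names = amputed.feature_names
    survivors = [n for n, dead in zip(names, miss.any(axis=0)) if not dead]
    if not survivors:
        raise HandlerError(
            "dropping variables removed every feature column"
        )
    return amputed.select_columns(survivors + [amputed.target_name])
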