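"""Imputation-quality scoring against the complete original table.

Metrics are computed strictly on the originally-missing cells identified by
the amputation mask: MAE and RMSE for numeric features (on min-max
normalised values by default, using the complete original column's range,
so errors are comparable across features with different scales) and
accuracy — the fraction of imputed categorical cells that match the true
level — for categorical features.  A distribution-shift summary (total
variation distance between the original and imputed marginal of a column)
quantifies how much an imputation method distorts a variable's
distribution.

Metrics on an empty cell set are undefined and reported as NaN, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amputation import AmputedInstance
from .tabular_core import ColumnKind, TypedTable

OVERALL = "OVERALL"


@dataclass(frozen=True)
class CellPredictions:
    """(predicted, true) value pairs for the originally-missing cells of
    one feature.  ``value_range`` is the complete original column's
    (min, max), used for min-max normalisation of numeric errors."""

    feature: str
    kind: ColumnKind
    y_pred: np.ndarray
    y_true: np.ndarray
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.y_pred) != len(self.y_true):
            raise ValueError("prediction/truth length mismatch")

    @property
    def n(self) -> int:
        return len(self.y_true)


def _normalised_errors(preds: CellPredictions) -> np.ndarray:
    if preds.kind is not ColumnKind.NUMERIC:
        raise ValueError(f"{preds.feature!r} is not numeric")
    pred = np.asarray(preds.y_pred, dtype=float)
    true = np.asarray(preds.y_true, dtype=float)
    if preds.value_range is not None:
        lo, hi = preds.value_range
        span = hi - lo
        if span > 0:
            pred = (pred - lo) / span
            true = (true - lo) / span
    return pred - true


def mae(preds: CellPredictions) -> float:
    """Mean absolute error over the originally-missing cells; NaN when the
    cell set is empty."""
    if preds.n == 0:
        return math.nan
    return float(np.mean(np.abs(_normalised_errors(preds))))


def rmse(preds: CellPredictions) -> float:
    """Root mean squared error over the originally-missing cells; NaN when
    the cell set is empty."""
    if preds.n == 0:
        return math.nan
    return float(np.sqrt(np.mean(_normalised_errors(preds) ** 2)))


def imputation_accuracy(preds: CellPredictions) -> float:
    """Fraction of imputed categorical cells equal to the true level
    (the complement of the misclassification-rate view of imputation
    error); NaN when the cell set is empty."""
    if preds.kind is not ColumnKind.CATEGORICAL:
        raise ValueError(f"{preds.feature!r} is not categorical")
    if preds.n == 0:
        return math.nan
    pred = np.asarray(preds.y_pred, dtype=object)
    true = np.asarray(preds.y_true, dtype=object)
    return float(np.mean(pred == true))


def collect_predictions(
    instance: AmputedInstance,
    imputed: TypedTable,
    normalize: bool = True,
) -> list[CellPredictions]:
    """Pair imputed against true values on the masked cells of every
    feature that lost at least one cell."""
    out = []
    original = instance.original
    for name in original.feature_names:
        col_mask = instance.mask.column(name)
        if not col_mask.any():
            continue
        kind = original.kind_of(name)
        if kind is ColumnKind.NUMERIC:
            true = original.df[name].to_numpy(dtype=float)[col_mask]
            pred = imputed.df[name].to_numpy(dtype=float)[col_mask]
            rng_ = None
            if normalize:
                full = original.df[name].to_numpy(dtype=float)
                rng_ = (float(np.min(full)), float(np.max(full)))
            out.append(CellPredictions(name, kind, pred, true, rng_))
        else:
            true = original.df[name].to_numpy(dtype=object)[col_mask]
            pred = imputed.df[name].to_numpy(dtype=object)[col_mask]
            out.append(CellPredictions(name, kind, pred, true))
    return out


_METRIC_FUNCS = {
    "MAE": (ColumnKind.NUMERIC, mae),
    "RMSE": (ColumnKind.NUMERIC, rmse),
    "accuracy": (ColumnKind.CATEGORICAL, imputation_accuracy),
}


def _pool_cells(preds: list[CellPredictions], kind: ColumnKind) -> CellPredictions:
    """Concatenate the masked cells of all features of one kind into a
    single pseudo-feature.  Numeric cells are normalised per-feature first
    (ranges are per-column), so the pooled metric is the cell-count-weighted
    combination of the per-feature metrics."""
    sel = [p for p in preds if p.kind is kind]
    if kind is ColumnKind.NUMERIC:
        errs = [_normalised_errors(p) for p in sel]
        flat = np.concatenate(errs) if errs else np.array([])
        return CellPredictions(OVERALL, kind, flat, np.zeros_like(flat))
    preds_flat = (
        np.concatenate([np.asarray(p.y_pred, dtype=object) for p in sel])
        if sel
        else np.array([], dtype=object)
    )
    true_flat = (
        np.concatenate([np.asarray(p.y_true, dtype=object) for p in sel])
        if sel
        else np.array([], dtype=object)
    )
    return CellPredictions(OVERALL, kind, preds_flat, true_flat)


def quality_rows(
    dataset: str,
    rate: float,
    replicate_id: int,
    handler: str,
    preds: list[CellPredictions],
) -> list[dict]:
    """Tidy per-replicate metric rows: one per (feature, applicable
    metric), plus OVERALL rows pooling all masked cells of each kind."""
    rows = []
    for metric, (kind, func) in _METRIC_FUNCS.items():
        for p in preds:
            if p.kind is not kind:
                continue
            rows.append(
                dict(
                    dataset=dataset,
                    rate=rate,
                    replicate_id=replicate_id,
                    handler=handler,
                    feature=p.feature,
                    metric=metric,
                    value=func(p),
                    level="per-replicate",
                )
            )
        pooled = _pool_cells(preds, kind)
        rows.append(
            dict(
                dataset=dataset,
                rate=rate,
                replicate_id=replicate_id,
                handler=handler,
                feature=OVERALL,
                metric=metric,
                value=func(pooled),
                level="per-replicate",
            )
        )
    return rows


def overall_and_per_feature(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a tidy per-replicate report: per (dataset, rate, handler,
    feature, metric), the mean over replicates.  Returns both levels
    concatenated, flagged in the ``level`` column."""
    agg = (
        per_replicate.groupby(
            ["dataset", "rate", "handler", "feature", "metric"],
            as_index=False,
            dropna=False,
        )["value"]
        .mean()
        .assign(replicate_id=-1, level="mean-over-replicates")
    )
    return pd.concat([per_replicate, agg], ignore_index=True)[
        [
            "dataset",
            "rate",
            "replicate_id",
            "handler",
            "feature",
            "metric",
            "value",
            "level",
        ]
    ]


def distribution_shift(
    original: TypedTable, imputed: TypedTable, feature: str, n_bins: int = 20
) -> float:
    """Total-variation distance between a column's marginal in the
    complete original and in the imputed table.

    Categorical columns compare level-frequency vectors over the union of
    observed levels.  Numeric columns compare histograms over ``n_bins``
    equal-width bins spanning the original column's range; imputed values
    outside that range fall into the nearest edge bin."""
    kind = original.kind_of(feature)
    a = original.df[feature]
    b = imputed.df[feature]
    if kind is ColumnKind.CATEGORICAL:
        av = a.to_numpy(dtype=object)
        bv = b.to_numpy(dtype=object)
        levels = sorted({v for v in av if v is not None}
                        | {v for v in bv if v is not None})
        pa = np.array([np.mean(av == lvl) for lvl in levels])
        pb = np.array([np.mean(bv == lvl) for lvl in levels])
        return float(0.5 * np.abs(pa - pb).sum())
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    lo, hi = float(np.nanmin(av)), float(np.nanmax(av))
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(np.clip(av, lo, hi), bins=edges)
    pb, _ = np.histogram(np.clip(bv, lo, hi), bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(0.5 * np.abs(pa - pb).sum())


def mean_feature_shift(
    original: TypedTable, imputed: TypedTable, n_bins: int = 20
) -> float:
    """Mean distribution shift across all feature columns."""
    names = original.feature_names
    return float(
        np.mean([distribution_shift(original, imputed, n, n_bins) for n in names])
    )
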