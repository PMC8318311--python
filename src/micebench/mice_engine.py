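"""Multivariate imputation by chained equations (fully conditional
specification), with multiple imputation and value pooling.

The engine follows the classic chained-equations cycle:

1. give every missing cell a basic fill (column mean for numeric, column
   mode for categorical);
2. for one feature at a time, set its originally-missing cells back aside,
   train a conditional model on the rows where the feature was observed —
   linear (ridge-stabilised) regression for numeric features, (multinomial)
   logistic regression for categorical features — with every other feature
   as a predictor, and overwrite the missing cells with the model's
   predictions;
3. a pass over all incomplete features is one iteration; the cycle is run
   for ``n_iterations`` and the table after the final cycle is the imputed
   dataset.

Repeating the whole procedure ``m_imputations`` times yields multiple
imputations, which are pooled value-wise into a single completed table:
the mean of the m predictions for numeric cells, their mode (lexicographic
tie-break) for categorical cells.

Conditional predictions are deterministic conditional means/classes (no
posterior draws or predictive-mean matching), so chains are decorrelated by
shuffling the feature visit order per chain; this choice is recorded in the
run metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .amputation import AmputedInstance
from .baseline_handlers import column_mode
from .tabular_core import (
    ColumnKind,
    ColumnRole,
    MissingnessMask,
    TypedTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equation settings.

    ``n_iterations`` is the number of full cycles per chain; ``m_imputations``
    the number of chains pooled into the final table (literature guidance:
    5-10).  ``include_target_as_predictor`` adds the class target to every
    conditional model's design matrix.  ``ridge_penalty`` stabilises the
    linear fits on collinear one-hot designs.  ``clip_numeric`` clips
    numeric predictions to the observed range of the column.
    """

    n_iterations: int = 10
    m_imputations: int = 5
    include_target_as_predictor: bool = False
    seed: int = 0
    numeric_model: str = "linear_regression"
    categorical_model: str = "logistic_regression"
    ridge_penalty: float = 1e-6
    clip_numeric: bool = False
    visit_order: str = "schema"  # or "ascending_missingness"

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.m_imputations < 1:
            raise ValueError("n_iterations and m_imputations must be >= 1")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be non-negative")
        if self.numeric_model != "linear_regression":
            raise ValueError(f"unknown numeric model {self.numeric_model!r}")
        if self.categorical_model != "logistic_regression":
            raise ValueError(
                f"unknown categorical model {self.categorical_model!r}"
            )
        if self.visit_order not in ("schema", "ascending_missingness"):
            raise ValueError(f"unknown visit order {self.visit_order!r}")


@dataclass(frozen=True)
class ImputationResult:
    """m completed tables, their pooled table, and run metadata."""

    completed: tuple[TypedTable, ...]
    pooled: TypedTable
    config: ImputationConfig
    source: AmputedInstance
    metadata: dict = field(default_factory=dict)


class ImputationError(RuntimeError):
    pass


# -- step 1: basic fill ----------------------------------------------------


def initial_fill(amputed: TypedTable) -> TypedTable:
    """Column mean (numeric) / column mode (categorical, lexicographic
    tie-break) fill of every MISSING cell."""
    df = amputed.df.copy()
    for col in amputed.schema:
        s = df[col.name]
        if col.kind is ColumnKind.NUMERIC:
            vals = s.to_numpy(dtype=float).copy()
            miss = np.isnan(vals)
            if not miss.any():
                continue
            if miss.all():
                raise ImputationError(
                    f"column {col.name!r} is fully missing; no basic fill"
                )
            vals[miss] = float(np.mean(vals[~miss]))
            df[col.name] = vals
        else:
            vals = s.to_numpy(dtype=object).copy()
            miss = np.array([v is None for v in vals])
            if not miss.any():
                continue
            if miss.all():
                raise ImputationError(
                    f"column {col.name!r} is fully missing; no basic fill"
                )
            vals[miss] = column_mode(vals)
            df[col.name] = vals
    return amputed.with_values(df)


# -- design matrices -------------------------------------------------------


def _encode_predictors(
    working: TypedTable, exclude: str, include_target: bool
) -> np.ndarray:
    """One-hot-encode the predictor columns (all features except
    ``exclude``; the target too when requested).  Encoding is deterministic
    from the frozen categorical domains."""
    blocks: list[np.ndarray] = []
    cols = [
        c
        for c in working.schema
        if c.name != exclude
        and (c.role is ColumnRole.FEATURE or include_target)
    ]
    for col in cols:
        s = working.df[col.name]
        if col.kind is ColumnKind.NUMERIC:
            blocks.append(s.to_numpy(dtype=float)[:, None])
        else:
            domain = working.domains[col.name]
            vals = s.to_numpy(dtype=object)
            onehot = np.zeros((len(vals), len(domain)))
            index = {lvl: i for i, lvl in enumerate(domain)}
            for i, v in enumerate(vals):
                onehot[i, index[v]] = 1.0
            blocks.append(onehot)
    if not blocks:
        return np.zeros((working.n_rows, 0))
    return np.hstack(blocks)


# -- steps 2-4: one conditional model --------------------------------------


def impute_feature(
    working: TypedTable,
    fx: str,
    mask: MissingnessMask,
    config: ImputationConfig,
) -> TypedTable:
    """Re-impute the originally-missing cells of one feature from a
    conditional model trained on the rows where it was observed.

    ``working`` must already be complete (post :func:`initial_fill`); only
    the cells that ``mask`` marks missing for ``fx`` are overwritten.
    Degenerate responses (zero variance / a single observed level) fall
    back to the marginal fill with a logged warning.
    """
    miss = mask.column(fx)
    if not miss.any():
        return working
    obs = ~miss
    X = _encode_predictors(working, fx, config.include_target_as_predictor)
    df = working.df.copy()
    kind = working.kind_of(fx)
    if kind is ColumnKind.NUMERIC:
        y = df[fx].to_numpy(dtype=float)
        y_obs = y[obs]
        if np.ptp(y_obs) == 0.0:
            logger.warning(
                "feature %r has zero observed variance; falling back to "
                "marginal fill",
                fx,
            )
            pred = np.full(int(miss.sum()), float(y_obs[0]))
        else:
            model = Ridge(alpha=config.ridge_penalty)
            model.fit(X[obs], y_obs)
            pred = model.predict(X[miss])
        if config.clip_numeric:
            pred = np.clip(pred, y_obs.min(), y_obs.max())
        y = y.copy()
        y[miss] = pred
        df[fx] = y
    else:
        y = df[fx].to_numpy(dtype=object).copy()
        y_obs = y[obs]
        levels = sorted(set(y_obs))
        if len(levels) < 2:
            logger.warning(
                "feature %r has a single observed level; falling back to "
                "marginal fill",
                fx,
            )
            pred = np.array([levels[0]] * int(miss.sum()), dtype=object)
        else:
            model = LogisticRegression(max_iter=500)
            model.fit(X[obs], y_obs.astype(str))
            pred = model.predict(X[miss]).astype(object)
        y[miss] = pred
        df[fx] = y
    return working.with_values(df)


# -- steps 5-6: cycles and chains ------------------------------------------


def _visit_order(
    amputed: TypedTable, mask: MissingnessMask, config: ImputationConfig
) -> list[str]:
    incomplete = [
        n for n in amputed.feature_names if mask.column(n).any()
    ]
    if config.visit_order == "ascending_missingness":
        incomplete.sort(key=lambda n: (int(mask.column(n).sum()),
                                       amputed.feature_names.index(n)))
    return incomplete


def run_chain(
    amputed: AmputedInstance,
    config: ImputationConfig,
    chain_seed: int,
    shuffle_order: bool = False,
) -> TypedTable:
    """One chained-equation run: basic fill, then ``n_iterations`` full
    cycles over every incomplete feature.  Visit order is the schema column
    order (or ascending missingness per config); ``shuffle_order`` permutes
    it with ``chain_seed`` to decorrelate chains in multiple imputation."""
    mask = amputed.mask
    order = _visit_order(amputed.table, mask, config)
    if not order:
        return amputed.table
    if shuffle_order:
        rng = np.random.default_rng(chain_seed)
        order = [order[i] for i in rng.permutation(len(order))]
    working = initial_fill(amputed.table)
    for _ in range(config.n_iterations):
        for fx in order:
            working = impute_feature(working, fx, mask, config)
    return working


def chain_seeds(config: ImputationConfig) -> list[int]:
    ss = np.random.SeedSequence(entropy=int(config.seed))
    return [int(s % (2**31)) for s in ss.generate_state(config.m_imputations)]


def run_mice(
    amputed: AmputedInstance, config: ImputationConfig | None = None
) -> ImputationResult:
    """Multiple imputation: m independent chains pooled into one table.

    The first chain visits features in the configured deterministic order;
    subsequent chains shuffle the visit order under per-chain derived
    seeds (predictions themselves are deterministic conditional means).
    """
    config = config or ImputationConfig()
    seeds = chain_seeds(config)
    completed = tuple(
        run_chain(amputed, config, seed, shuffle_order=(i > 0))
        for i, seed in enumerate(seeds)
    )
    pooled = pool(completed)
    metadata = {
        "method": "mice",
        "n_iterations": config.n_iterations,
        "m_imputations": config.m_imputations,
        "include_target_as_predictor": config.include_target_as_predictor,
        "chain_seeds": seeds,
        "chain_decorrelation": "visit-order shuffle (chains after the first)",
        "rate": amputed.rate,
        "replicate_id": amputed.replicate_id,
        "amputation_seed": amputed.seed,
    }
    return ImputationResult(
        completed=completed,
        pooled=pooled,
        config=config,
        source=amputed,
        metadata=metadata,
    )


def pool(completed: tuple[TypedTable, ...] | list[TypedTable]) -> TypedTable:
    """Pool m completed tables cell-wise: mean for numeric columns, mode
    (lexicographic tie-break) for categorical.  Observed cells are
    identical across chains by construction, so pooling passes them
    through unchanged."""
    completed = list(completed)
    if not completed:
        raise ValueError("nothing to pool")
    first = completed[0]
    for other in completed[1:]:
        if other.schema != first.schema:
            raise ValueError("cannot pool tables with differing schemas")
    if len(completed) == 1:
        return first.copy()
    df = first.df.copy()
    for col in first.schema:
        stack = [t.df[col.name] for t in completed]
        if col.kind is ColumnKind.NUMERIC:
            arr = np.column_stack([s.to_numpy(dtype=float) for s in stack])
            # cells on which all chains agree (observed cells always do)
            # pass through bit-exactly rather than via a float mean
            same = (arr == arr[:, [0]]).all(axis=1)
            df[col.name] = np.where(same, arr[:, 0], arr.mean(axis=1))
        else:
            arr = np.column_stack([s.to_numpy(dtype=object) for s in stack])
            pooled = np.empty(len(arr), dtype=object)
            for i, row in enumerate(arr):
                if all(v == row[0] for v in row[1:]):
                    pooled[i] = row[0]
                else:
                    pooled[i] = column_mode(row)
            df[col.name] = pooled
    return first.with_values(df)
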