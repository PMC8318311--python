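"""Benchmark orchestration: ampute, handle, score, select, compare.

Two experiments are provided:

* the imputation-quality experiment runs a rates x replicates MCAR grid,
  imputes every instance with each imputing handler (chained equations,
  mean/mode, median) and emits a tidy per-replicate + aggregated quality
  report (MAE / RMSE / accuracy, per feature and overall);
* the feature-selection stability experiment draws one (or more) amputed
  instance per rate, applies each handler — including the deletion
  handlers — runs all five selectors on the handled table, and compares
  every selected set against the complete-table reference set by
  intersection size, Jaccard index and symmetric-difference count.

A handler that destroys the data for an instance (listwise wipe-out, all
feature columns hit) is recorded as a failed cell; in the stability report
the failed cell carries an empty selected set and Jaccard 0, which scores
"the handler left nothing to select from" as total instability rather than
dropping the cell silently.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from .amputation import AmputationGrid, ampute_mcar, build_grid, derive_seed
from .baseline_handlers import (
    HandlerError,
    HandlerName,
    drop_variables,
    impute_marginal,
    listwise_delete,
)
from .feature_selection import ALGORITHMS, SelectedSet, run_all_selectors
from .mice_engine import ImputationConfig, run_mice
from .quality_metrics import (
    collect_predictions,
    overall_and_per_feature,
    quality_rows,
)
from .tabular_core import TypedTable

logger = logging.getLogger(__name__)

IMPUTING_HANDLERS = (
    HandlerName.MICE,
    HandlerName.MEAN_MODE,
    HandlerName.MEDIAN,
)
FS_HANDLERS = (
    HandlerName.MICE,
    HandlerName.MEAN_MODE,
    HandlerName.LISTWISE,
    HandlerName.DROP_VARIABLES,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment run needs."""

    table: TypedTable
    dataset_id: str
    grid: AmputationGrid
    handlers: tuple[HandlerName, ...] = (HandlerName.MICE, HandlerName.MEAN_MODE)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    k_map: dict | int = 3
    normalize_errors: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "handlers", tuple(HandlerName(h) for h in self.handlers)
        )


def apply_handler(
    handler: HandlerName,
    instance,
    imputation: ImputationConfig,
    handler_seed: int,
) -> TypedTable:
    """Run one handler on one amputed instance, returning the handled
    table (imputed, row-reduced, or column-reduced)."""
    handler = HandlerName(handler)
    if handler is HandlerName.MICE:
        cfg = ImputationConfig(
            **{**imputation.__dict__, "seed": handler_seed}
        )
        return run_mice(instance, cfg).pooled
    if handler in (HandlerName.MEAN_MODE, HandlerName.MEDIAN):
        return impute_marginal(instance.table, handler)
    if handler is HandlerName.LISTWISE:
        return listwise_delete(instance.table)
    if handler is HandlerName.DROP_VARIABLES:
        return drop_variables(instance.table)
    raise ValueError(f"unknown handler {handler}")


# -- quality experiment ----------------------------------------------------


def run_quality_experiment(config: RunConfig) -> pd.DataFrame:
    """Full rates x replicates grid, scored per handler.

    Only imputing handlers receive quality metrics (deletion handlers
    impute nothing).  Returns the tidy report with both per-replicate and
    mean-over-replicates levels; a handler failure on an instance is
    recorded as a row with status ``failed`` instead of aborting the grid.
    """
    handlers = [h for h in config.handlers if h in IMPUTING_HANDLERS]
    rows: list[dict] = []
    failures: list[dict] = []
    for instance in build_grid(config.table, config.grid):
        for handler in handlers:
            t0 = time.perf_counter()
            try:
                handled = apply_handler(
                    handler,
                    instance,
                    config.imputation,
                    handler_seed=derive_seed(
                        config.grid.master_seed + 1,
                        instance.rate,
                        instance.replicate_id,
                    ),
                )
                preds = collect_predictions(
                    instance, handled, normalize=config.normalize_errors
                )
                rows.extend(
                    quality_rows(
                        config.dataset_id,
                        instance.rate,
                        instance.replicate_id,
                        handler.value,
                        preds,
                    )
                )
            except (HandlerError, RuntimeError) as exc:
                logger.warning(
                    "handler %s failed at rate %.2f rep %d: %s",
                    handler.value,
                    instance.rate,
                    instance.replicate_id,
                    exc,
                )
                failures.append(
                    dict(
                        dataset=config.dataset_id,
                        rate=instance.rate,
                        replicate_id=instance.replicate_id,
                        handler=handler.value,
                        feature=None,
                        metric="failed",
                        value=float("nan"),
                        level="per-replicate",
                    )
                )
            logger.debug(
                "quality cell handler=%s rate=%.2f rep=%d seed=%d wall=%.2fs",
                handler.value,
                instance.rate,
                instance.replicate_id,
                instance.seed,
                time.perf_counter() - t0,
            )
    report = overall_and_per_feature(pd.DataFrame(rows))
    if failures:
        report = pd.concat(
            [report, pd.DataFrame(failures)], ignore_index=True
        )
    return report


def win_fraction(
    report: pd.DataFrame,
    metric: str,
    handler_a: str,
    handler_b: str,
    lower_is_better: bool | None = None,
) -> float:
    """Fraction of missingness rates at which handler_a beats handler_b on
    the mean-over-replicates OVERALL metric (the descriptive "% of rates
    won" summary)."""
    if lower_is_better is None:
        lower_is_better = metric in ("MAE", "RMSE")
    sel = report[
        (report["level"] == "mean-over-replicates")
        & (report["feature"] == "OVERALL")
        & (report["metric"] == metric)
    ]
    piv = sel.pivot_table(index="rate", columns="handler", values="value")
    a, b = piv[handler_a], piv[handler_b]
    wins = (a < b) if lower_is_better else (a > b)
    return float(wins.mean())


# -- feature-selection stability experiment --------------------------------


def compare_sets(reference: SelectedSet, candidate: SelectedSet) -> dict:
    """Intersection size, Jaccard index and symmetric-difference count
    between a reference and a candidate selected set of the same
    algorithm."""
    if reference.algorithm != candidate.algorithm:
        raise ValueError(
            f"algorithm mismatch: {reference.algorithm} vs "
            f"{candidate.algorithm}"
        )
    ref, cand = set(reference.features), set(candidate.features)
    union = ref | cand
    inter = ref & cand
    return dict(
        algorithm=reference.algorithm,
        selected=",".join(sorted(cand)),
        reference=",".join(sorted(ref)),
        intersection=len(inter),
        jaccard=(len(inter) / len(union)) if union else 1.0,
        n_differing=len(ref ^ cand),
    )


def run_fs_experiment(config: RunConfig) -> pd.DataFrame:
    """Reference selections on the complete table, then per (rate,
    replicate, handler) selections on the handled table, compared
    algorithm-by-algorithm.

    Deletion-handler wipe-outs are emitted with status ``failed``, an
    empty candidate set and Jaccard 0.  Candidate sets from
    column-reduced tables (dropping variables) can only contain surviving
    features; sizes are clipped accordingly.
    """
    handlers = [h for h in config.handlers if h in FS_HANDLERS]
    seed = derive_seed(config.grid.master_seed + 2, 0.5, 0)
    reference = {
        s.algorithm: s
        for s in run_all_selectors(config.table, config.k_map, seed=seed)
    }
    rows: list[dict] = []
    for rate in config.grid.rates:
        for rep in range(config.grid.n_replicates):
            inst_seed = derive_seed(config.grid.master_seed, rate, rep)
            instance = ampute_mcar(
                config.table, rate, inst_seed, replicate_id=rep
            )
            for handler in handlers:
                base = dict(
                    dataset=config.dataset_id,
                    rate=rate,
                    replicate_id=rep,
                    handler=handler.value,
                )
                try:
                    handled = apply_handler(
                        handler,
                        instance,
                        config.imputation,
                        handler_seed=derive_seed(
                            config.grid.master_seed + 1, rate, rep
                        ),
                    )
                    candidates = run_all_selectors(
                        handled, config.k_map, seed=seed
                    )
                except (HandlerError, RuntimeError, ValueError) as exc:
                    # deletion can leave a degenerate table (e.g. a single
                    # target class) on which selectors are undefined
                    logger.warning(
                        "handler %s failed at rate %.2f rep %d: %s",
                        handler.value,
                        rate,
                        rep,
                        exc,
                    )
                    for alg in ALGORITHMS:
                        empty = SelectedSet(alg, 0, ())
                        rows.append(
                            base
                            | compare_sets(reference[alg], empty)
                            | dict(status="failed")
                        )
                    continue
                for cand in candidates:
                    rows.append(
                        base
                        | compare_sets(reference[cand.algorithm], cand)
                        | dict(status="ok")
                    )
    return pd.DataFrame(rows)
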