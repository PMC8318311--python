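"""Amputation: simulating missing data in a complete table.

MCAR amputation removes an exact count of feature cells
(``round(rate * n_feature_cells)``) chosen uniformly without replacement,
so every replicate realises the nominal missingness level exactly.  MAR
amputation makes each cell's loss probability a logistic function of a
fully observed numeric driver feature, rescaled so the expected overall
rate matches the nominal one.  The target column is never amputed, and no
feature column is allowed to lose all of its values (chained-equation
models need at least one observed value per column to train on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .tabular_core import (
    ColumnKind,
    Mechanism,
    MissingnessMask,
    TypedTable,
)

_MAX_REDRAWS = 100


class AmputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AmputedInstance:
    """An incomplete table together with its mask and complete original."""

    table: TypedTable
    mask: MissingnessMask
    original: TypedTable
    rate: float
    replicate_id: int
    seed: int


@dataclass(frozen=True)
class AmputationGrid:
    """Missingness rates x replicates design with a master seed."""

    rates: tuple[float, ...]
    n_replicates: int
    master_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(self.rates))
        if not all(0 < r < 1 for r in self.rates):
            raise ValueError("rates must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def derive_seed(master_seed: int, rate: float, replicate_id: int) -> int:
    """Stable per-instance seed from (master seed, rate in basis points,
    replicate id); reproducible across processes."""
    key = (int(round(rate * 10_000)), int(replicate_id))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _check_complete_features(original: TypedTable) -> None:
    if original.feature_missing_values().any():
        raise AmputationError(
            "original table already has MISSING feature cells; "
            "ampute requires a complete table"
        )


def _apply_mask(original: TypedTable, flat_mask: np.ndarray) -> TypedTable:
    names = original.feature_names
    grid = flat_mask.reshape(original.n_rows, len(names))
    df = original.df.copy()
    for j, name in enumerate(names):
        col_mask = grid[:, j]
        if not col_mask.any():
            continue
        if original.kind_of(name) is ColumnKind.NUMERIC:
            vals = df[name].to_numpy(dtype=float).copy()
            vals[col_mask] = np.nan
            df[name] = vals
        else:
            vals = df[name].to_numpy(dtype=object).copy()
            vals[col_mask] = None
            df[name] = vals
    return original.with_values(df)


def ampute_mcar(
    original: TypedTable,
    rate: float,
    seed: int,
    replicate_id: int = 0,
) -> AmputedInstance:
    """Remove exactly ``round(rate * n_feature_cells)`` feature cells,
    uniformly without replacement.  Re-draws (bounded) if a feature column
    would lose all of its values.  Deterministic given ``seed``."""
    if not 0 <= rate < 1:
        raise AmputationError(f"rate must lie in [0, 1), got {rate}")
    _check_complete_features(original)
    names = original.feature_names
    n_rows, p = original.n_rows, len(names)
    n_cells = n_rows * p
    k = int(round(rate * n_cells))
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        flat = np.zeros(n_cells, dtype=bool)
        if k:
            flat[rng.choice(n_cells, size=k, replace=False)] = True
        grid = flat.reshape(n_rows, p)
        dead = grid.all(axis=0)
        if not dead.any():
            break
    else:
        raise AmputationError(
            f"could not avoid a fully-missing column (first offender "
            f"{names[int(np.argmax(dead))]!r}) after {_MAX_REDRAWS} re-draws"
        )
    mask = MissingnessMask(
        values=grid,
        feature_names=tuple(names),
        rate=rate,
        mechanism=Mechanism.MCAR,
        seed=seed,
    )
    return AmputedInstance(
        table=_apply_mask(original, flat),
        mask=mask,
        original=original,
        rate=rate,
        replicate_id=replicate_id,
        seed=seed,
    )


def ampute_mar(
    original: TypedTable,
    rate: float,
    driver: str,
    steepness: float,
    seed: int,
    replicate_id: int = 0,
) -> AmputedInstance:
    """Ampute non-driver feature cells with probability proportional to a
    logistic function of the (fully observed, numeric) driver feature,
    rescaled so the expected overall feature-cell missingness equals
    ``rate``.  ``steepness=0`` reduces to MCAR.  The driver itself is never
    amputed."""
    if not 0 <= rate < 1:
        raise AmputationError(f"rate must lie in [0, 1), got {rate}")
    _check_complete_features(original)
    names = original.feature_names
    if driver not in names:
        raise AmputationError(f"driver {driver!r} is not a feature column")
    if original.kind_of(driver) is not ColumnKind.NUMERIC:
        raise AmputationError(f"driver {driver!r} must be numeric")
    x = original.df[driver].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise AmputationError(f"driver {driver!r} contains MISSING cells")
    n_rows, p = original.n_rows, len(names)
    if p < 2:
        raise AmputationError("MAR amputation needs at least one non-driver feature")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    w = expit(steepness * z)
    # calibrate: expected missing over ALL feature cells equals rate
    n_nondriver = n_rows * (p - 1)
    target_missing = rate * n_rows * p
    probs = w * (target_missing / (w.sum() * (p - 1)))
    probs = np.clip(probs, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    j_driver = names.index(driver)
    for _ in range(_MAX_REDRAWS):
        grid = rng.random(size=(n_rows, p)) < probs[:, None]
        grid[:, j_driver] = False
        dead = grid.all(axis=0)
        if not dead.any():
            break
    else:
        raise AmputationError(
            f"could not avoid a fully-missing column "
            f"({names[int(np.argmax(dead))]!r}) after {_MAX_REDRAWS} re-draws"
        )
    mask = MissingnessMask(
        values=grid,
        feature_names=tuple(names),
        rate=rate,
        mechanism=Mechanism.MAR,
        seed=seed,
    )
    return AmputedInstance(
        table=_apply_mask(original, grid.ravel()),
        mask=mask,
        original=original,
        rate=rate,
        replicate_id=replicate_id,
        seed=seed,
    )


def build_grid(
    original: TypedTable, grid: AmputationGrid
) -> list[AmputedInstance]:
    """All |rates| x n_replicates MCAR instances, with per-instance seeds
    derived reproducibly from the master seed."""
    out = []
    for rate in grid.rates:
        for rep in range(grid.n_replicates):
            seed = derive_seed(grid.master_seed, rate, rep)
            out.append(ampute_mcar(original, rate, seed, replicate_id=rep))
    return out
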