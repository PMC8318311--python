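"""Synthetic complete tables with known dependency structure and a planted
set of relevant features.

The generator draws every feature from a single-latent-factor Gaussian
model: with dependency strength ``rho`` each latent is
``sqrt(rho) * Z + sqrt(1 - rho) * eps`` for a shared standard-normal factor
``Z``, so any two latents have correlation exactly ``rho`` in expectation.
Numeric features expose the latent directly; categorical features are
produced by cutting additional latents at fixed standard-normal quantiles,
which balances the level marginals.  The class target follows a multinomial
logit whose linear predictor loads on the *idiosyncratic* components
``eps`` of the planted relevant features, with coefficient scale
``effect_size``.  Loading on the idiosyncratic part rather than the full
latent keeps the planted structure clean: irrelevant features are
correlated with relevant ones (through ``Z``) but carry no association
with the target of their own, so selector recovery of the planted set is
well defined even under strong inter-feature dependence.

Because the inter-feature dependence and the relevant set are known by
construction, every downstream stage — conditional-model imputation beating
marginal replacement, and selector recovery of the relevant set — is
testable without external data.  Replication presets mirror the column-type
mix and row counts of four classic UCI benchmark shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tabular_core import ColumnKind, ColumnRole, ColumnSchema, TypedTable

TARGET_NAME = "target"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one synthetic complete table.

    ``dependency_strength`` is the common pairwise latent correlation in
    [0, 1); ``relevant_features`` names the features (F1..Fp, numerics
    first) that drive the target; ``effect_size`` scales the logit
    coefficients; ``noise_sd`` is the standard deviation of extra
    class-specific noise added to the logits.
    """

    n_rows: int = 500
    n_numeric: int = 6
    n_categorical: int = 4
    n_levels: int = 3
    dependency_strength: float = 0.6
    relevant_features: tuple[str, ...] = ("F1", "F2", "F7")
    effect_size: float = 1.5
    n_classes: int = 2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "relevant_features", tuple(self.relevant_features)
        )
        if not 0 <= self.dependency_strength < 1:
            raise ValueError("dependency_strength must lie in [0, 1)")
        if self.n_rows < 1 or self.n_numeric + self.n_categorical < 1:
            raise ValueError("need at least one row and one feature")
        if self.n_levels < 2 or self.n_classes < 2:
            raise ValueError("n_levels and n_classes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = set(self.feature_names)
        bad = [f for f in self.relevant_features if f not in names]
        if bad:
            raise ValueError(
                f"relevant features {bad} not among generated names "
                f"F1..F{len(names)}"
            )
        if not self.relevant_features:
            raise ValueError("at least one relevant feature is required")

    @property
    def feature_names(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_numeric + self.n_categorical)]

    def schema(self) -> list[ColumnSchema]:
        cols = []
        for i, name in enumerate(self.feature_names):
            kind = (
                ColumnKind.NUMERIC
                if i < self.n_numeric
                else ColumnKind.CATEGORICAL
            )
            cols.append(ColumnSchema(name, kind))
        cols.append(
            ColumnSchema(TARGET_NAME, ColumnKind.CATEGORICAL, ColumnRole.TARGET)
        )
        return cols


def generate(spec: SyntheticSpec) -> TypedTable:
    """Draw one complete table from the latent-factor design.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_numeric + spec.n_categorical
    rho = spec.dependency_strength
    z = rng.normal(size=spec.n_rows)
    eps = rng.normal(size=(spec.n_rows, p))
    latents = np.sqrt(rho) * z[:, None] + np.sqrt(1.0 - rho) * eps

    names = spec.feature_names
    data: dict[str, object] = {}
    # equal-probability cuts of the N(0,1) marginal -> balanced levels
    cuts = norm.ppf(np.arange(1, spec.n_levels) / spec.n_levels)
    for j, name in enumerate(names):
        if j < spec.n_numeric:
            data[name] = latents[:, j]
        else:
            codes = np.searchsorted(cuts, latents[:, j])
            data[name] = np.array([f"l{c}" for c in codes], dtype=object)

    rel_idx = [names.index(f) for f in spec.relevant_features]
    # random class direction per relevant feature, normalised so every
    # relevant feature carries the same class-contrast magnitude
    betas = rng.normal(size=(len(rel_idx), spec.n_classes))
    betas -= betas.mean(axis=1, keepdims=True)
    scale = np.sqrt((betas**2).mean(axis=1, keepdims=True))
    betas = spec.effect_size * betas / scale
    eta = eps[:, rel_idx] @ betas
    eta += spec.noise_sd * rng.normal(size=eta.shape)
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(size=spec.n_rows)
    y_codes = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    width = len(str(spec.n_classes - 1))
    data[TARGET_NAME] = np.array(
        [f"c{c:0{width}d}" for c in y_codes], dtype=object
    )
    return TypedTable(spec.schema(), pd.DataFrame(data))


# Presets mirroring the column-type mix of four classic UCI benchmark
# shapes (an all-categorical oncology-style table; a large all-numeric
# letter-image table, rows scaled down 10x; a mixed cardiology-style table;
# a wide all-numeric spam table, rows scaled down ~4.6x).
REPLICATION_PROFILES: dict[str, SyntheticSpec] = {
    "small_categorical": SyntheticSpec(
        n_rows=286,
        n_numeric=0,
        n_categorical=9,
        n_levels=3,
        dependency_strength=0.6,
        relevant_features=("F3", "F4", "F5", "F6"),
        effect_size=1.5,
        n_classes=2,
    ),
    "large_numeric": SyntheticSpec(
        n_rows=2000,
        n_numeric=16,
        n_categorical=0,
        dependency_strength=0.5,
        relevant_features=("F7", "F11", "F13"),
        effect_size=1.5,
        n_classes=26,
    ),
    "mixed": SyntheticSpec(
        n_rows=269,
        n_numeric=6,
        n_categorical=7,
        n_levels=3,
        dependency_strength=0.8,
        relevant_features=("F3", "F9", "F12", "F13"),
        effect_size=1.5,
        n_classes=2,
    ),
    "wide_numeric": SyntheticSpec(
        n_rows=1000,
        n_numeric=57,
        n_categorical=0,
        dependency_strength=0.5,
        relevant_features=("F7", "F21", "F27", "F53", "F55"),
        effect_size=1.5,
        n_classes=2,
    ),
}


def make_replication_suite(profile: str, seed: int = 0) -> TypedTable:
    """Generate the preset table for one replication profile."""
    try:
        base = REPLICATION_PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; choose from "
            f"{sorted(REPLICATION_PROFILES)}"
        ) from None
    spec = SyntheticSpec(
        **{**base.__dict__, "seed": seed}
    )
    return generate(spec)
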