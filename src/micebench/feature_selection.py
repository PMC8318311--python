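"""Univariate, wrapper and embedded feature selectors on complete tables.

Five selectors are provided, all returning named feature sets against the
classification target:

* Select K Best under three univariate scores — the chi-squared statistic
  of the feature x target contingency table, the regression F statistic
  (feature against the target's integer class code treated as continuous),
  and the one-way ANOVA F statistic across target classes;
* recursive feature elimination (RFE) around an L2-penalised logistic
  model on standardised predictors;
* Gini importance from a random-forest ensemble (importances form a
  probability vector over features).

Scorers that need numeric input receive categorical features as
deterministic integer codes over the frozen level domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif, f_regression
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .tabular_core import ColumnKind, TypedTable

logger = logging.getLogger(__name__)

ALGORITHMS = ("skb_chi2", "skb_f", "skb_anova_f", "rfe", "importance")


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    score: float
    scorer: str


@dataclass(frozen=True)
class SelectedSet:
    """The k features one algorithm judged relevant, in schema order."""

    algorithm: str
    k: int
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))


def _require_complete(table: TypedTable) -> None:
    if table.n_missing:
        raise ValueError("feature selection requires a complete table")


def encode_numeric(table: TypedTable) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with categorical features/target as integer codes over the
    frozen domains (deterministic)."""
    cols = []
    for name in table.feature_names:
        s = table.df[name]
        if table.kind_of(name) is ColumnKind.NUMERIC:
            cols.append(s.to_numpy(dtype=float))
        else:
            index = {lvl: i for i, lvl in enumerate(table.domains[name])}
            cols.append(
                np.array([index[v] for v in s.to_numpy(dtype=object)], dtype=float)
            )
    X = np.column_stack(cols)
    t = table.target_name
    index = {lvl: i for i, lvl in enumerate(table.domains[t])}
    y = np.array(
        [index[v] for v in table.df[t].to_numpy(dtype=object)], dtype=int
    )
    return X, y


# -- chi-squared -----------------------------------------------------------


_CHI2_MAX_NUMERIC_LEVELS = 10


def chi2_scores(table: TypedTable) -> list[FeatureScore]:
    """Pearson chi-squared statistic of each feature against the target,
    from the feature-level x target-class contingency table (no continuity
    correction).  Numeric features use their distinct observed values as
    levels when few, and equal-frequency bins (at most 10) otherwise — a
    saturated table of unique values would score ~n for any continuous
    feature.  Cells with zero expected frequency contribute 0 (with a
    warning); they can only arise from empty rows/columns."""
    _require_complete(table)
    y = table.df[table.target_name].to_numpy(dtype=object)
    classes, y_idx = np.unique(y.astype(str), return_inverse=True)
    n = len(y)
    out = []
    for name in table.feature_names:
        s = table.df[name]
        if table.kind_of(name) is ColumnKind.NUMERIC:
            vals = s.to_numpy(dtype=float)
            if len(np.unique(vals)) > _CHI2_MAX_NUMERIC_LEVELS:
                qs = np.quantile(
                    vals,
                    np.linspace(0, 1, _CHI2_MAX_NUMERIC_LEVELS + 1)[1:-1],
                )
                vals = np.searchsorted(qs, vals).astype(float)
        else:
            vals = s.to_numpy(dtype=object).astype(str)
        levels, f_idx = np.unique(vals, return_inverse=True)
        observed = np.zeros((len(levels), len(classes)))
        np.add.at(observed, (f_idx, y_idx), 1.0)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (observed - expected) ** 2 / expected
        if (expected == 0).any():
            logger.warning(
                "feature %r: zero expected frequency; cell contributes 0",
                name,
            )
            terms = np.where(expected == 0, 0.0, terms)
        out.append(FeatureScore(name, float(terms.sum()), "chi2"))
    return out


# -- univariate F scores ---------------------------------------------------


def f_value_scores(table: TypedTable) -> list[FeatureScore]:
    """Regression F statistic of each feature against the target's integer
    class code treated as a continuous response."""
    _require_complete(table)
    X, y = encode_numeric(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_regression(X, y.astype(float))
    # a perfectly correlated feature can underflow 1 - r^2 below zero;
    # a negative F is impossible and means "off the top of the scale"
    f = np.where(f < 0, np.inf, f)
    return [
        FeatureScore(n, float(v), "f_value")
        for n, v in zip(table.feature_names, f)
    ]


def anova_f_scores(table: TypedTable) -> list[FeatureScore]:
    """One-way ANOVA F statistic of each feature across target classes."""
    _require_complete(table)
    X, y = encode_numeric(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    return [
        FeatureScore(n, float(v), "anova_f")
        for n, v in zip(table.feature_names, f)
    ]


def gini_scores(
    table: TypedTable, n_trees: int = 100, seed: int = 0
) -> list[FeatureScore]:
    """Gini importances from a random forest; the vector sums to 1 over
    features (uniform if the forest makes no informative split)."""
    _require_complete(table)
    X, y = encode_numeric(table)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    imp = forest.feature_importances_
    if imp.sum() == 0:
        imp = np.full(len(imp), 1.0 / len(imp))
    return [
        FeatureScore(n, float(v), "gini_importance")
        for n, v in zip(table.feature_names, imp)
    ]


# -- selectors -------------------------------------------------------------


def _top_k(scores: list[FeatureScore], k: int, algorithm: str) -> SelectedSet:
    vals = np.array(
        [-np.inf if np.isnan(s.score) else s.score for s in scores]
    )
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], i))
    chosen = set(order[:k])
    feats = [s.feature for i, s in enumerate(scores) if i in chosen]
    return SelectedSet(algorithm, k, tuple(feats))


_SKB_SCORERS = {
    "chi2": (chi2_scores, "skb_chi2"),
    "f_value": (f_value_scores, "skb_f"),
    "anova_f": (anova_f_scores, "skb_anova_f"),
}


def skb(table: TypedTable, scorer: str, k: int) -> SelectedSet:
    """Select the k features with the highest univariate score; ties break
    to the earlier schema column."""
    _require_complete(table)
    if scorer not in _SKB_SCORERS:
        raise ValueError(f"unknown scorer {scorer!r}")
    _check_k(table, k)
    func, algorithm = _SKB_SCORERS[scorer]
    return _top_k(func(table), k, algorithm)


def _check_k(table: TypedTable, k: int) -> None:
    p = len(table.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")


def rfe_select(table: TypedTable, k: int, seed: int = 0) -> SelectedSet:
    """Recursive feature elimination around an L2 logistic model: refit,
    drop the smallest-coefficient feature, repeat until k remain.
    Predictors are standardised so coefficient magnitudes are comparable."""
    _require_complete(table)
    _check_k(table, k)
    names, ranking = _rfe_ranking(table, k, seed)
    feats = [n for n, r in zip(names, ranking) if r == 1]
    return SelectedSet("rfe", k, tuple(feats))


def rfe_elimination_trace(
    table: TypedTable, k: int, seed: int = 0
) -> list[str]:
    """Features in elimination order (worst first); length = p - k."""
    names, ranking = _rfe_ranking(table, k, seed)
    eliminated = [(r, n) for n, r in zip(names, ranking) if r > 1]
    return [n for _, n in sorted(eliminated, reverse=True)]


def _rfe_ranking(table: TypedTable, k: int, seed: int):
    X, y = encode_numeric(table)
    X = StandardScaler().fit_transform(X)
    est = LogisticRegression(max_iter=1000, random_state=seed)
    rfe = RFE(est, n_features_to_select=k, step=1)
    rfe.fit(X, y)
    return table.feature_names, rfe.ranking_


def importance_select(
    table: TypedTable, k: int, n_trees: int = 100, seed: int = 0
) -> SelectedSet:
    """Top-k features by random-forest Gini importance."""
    _require_complete(table)
    _check_k(table, k)
    return _top_k(gini_scores(table, n_trees, seed), k, "importance")


def run_all_selectors(
    table: TypedTable, k_map: dict[str, int] | int, seed: int = 0
) -> list[SelectedSet]:
    """All five selectors on one complete table.  ``k_map`` maps algorithm
    name to set size (an int applies to all); sizes are clipped to the
    number of available features so reduced tables (e.g. after dropping
    variables) remain selectable."""
    _require_complete(table)
    p = len(table.feature_names)
    if isinstance(k_map, int):
        k_map = {a: k_map for a in ALGORITHMS}
    missing = [a for a in ALGORITHMS if a not in k_map]
    if missing:
        raise ValueError(f"k_map lacks entries for {missing}")
    k = {a: min(int(k_map[a]), p) for a in ALGORITHMS}
    return [
        skb(table, "chi2", k["skb_chi2"]),
        skb(table, "f_value", k["skb_f"]),
        skb(table, "anova_f", k["skb_anova_f"]),
        rfe_select(table, k["rfe"], seed=seed),
        importance_select(table, k["importance"], seed=seed),
    ]
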