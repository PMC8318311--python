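import math

import numpy as np
import pandas as pd
import pytest

from micebench import (
    AmputationGrid,
    CellPredictions,
    HandlerName,
    RunConfig,
    SyntheticSpec,
    ampute_mcar,
    collect_predictions,
    distribution_shift,
    generate,
    impute_marginal,
    imputation_accuracy,
    mae,
    overall_and_per_feature,
    quality_rows,
    rmse,
    run_quality_experiment,
)
from micebench.quality_metrics import _pool_cells
from micebench.tabular_core import ColumnKind

from conftest import make_table


def num_preds(pred, true, value_range=None):
    return CellPredictions(
        "f", ColumnKind.NUMERIC, np.asarray(pred, float),
        np.asarray(true, float), value_range,
    )


def cat_preds(pred, true):
    return CellPredictions(
        "f", ColumnKind.CATEGORICAL,
        np.asarray(pred, dtype=object), np.asarray(true, dtype=object),
    )


class TestPointMetrics:
    def test_mae_by_hand(self):
        assert mae(num_preds([1, 2, 4], [1, 2, 3])) == pytest.approx(1 / 3)

    def test_rmse_by_hand(self):
        assert rmse(num_preds([1, 2, 4], [1, 2, 3])) == pytest.approx(
            math.sqrt(1 / 3)
        )

    def test_perfect_imputation_scores_zero_and_one(self):
        assert mae(num_preds([1, 2], [1, 2])) == 0.0
        assert rmse(num_preds([1, 2], [1, 2])) == 0.0
        assert imputation_accuracy(cat_preds(["a", "b"], ["a", "b"])) == 1.0

    def test_accuracy_fraction(self):
        assert imputation_accuracy(
            cat_preds(["a", "b", "a", "a"], ["a", "b", "b", "a"])
        ) == 0.75

    def test_empty_cell_set_is_nan_not_zero(self):
        assert math.isnan(mae(num_preds([], [])))
        assert math.isnan(rmse(num_preds([], [])))
        assert math.isnan(imputation_accuracy(cat_preds([], [])))

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(cat_preds(["a"], ["a"]))
        with pytest.raises(ValueError):
            imputation_accuracy(num_preds([1.0], [1.0]))

    def test_minmax_normalisation_uses_original_range(self):
        p = num_preds([5.0], [10.0], value_range=(0.0, 20.0))
        assert mae(p) == pytest.approx(0.25)

    def test_brute_force_oracle(self):
        """MAE/RMSE match an elementwise pure-Python recomputation to
        1e-12, and RMSE >= MAE, on 1000 random pair vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            pred = rng.normal(size=n) * 10
            true = rng.normal(size=n) * 10
            p = num_preds(pred, true)
            mae_oracle = sum(abs(a - b) for a, b in zip(pred, true)) / n
            rmse_oracle = math.sqrt(
                sum((a - b) ** 2 for a, b in zip(pred, true)) / n
            )
            assert abs(mae(p) - mae_oracle) < 1e-12
            assert abs(rmse(p) - rmse_oracle) < 1e-12
            assert rmse(p) >= mae(p)

    def test_random_categorical_null_accuracy(self):
        """Random predictions over K uniform levels score about 1/K."""
        rng = np.random.default_rng(1)
        K, n = 4, 20000
        levels = np.array([f"l{i}" for i in range(K)], dtype=object)
        acc = imputation_accuracy(
            cat_preds(rng.choice(levels, n), rng.choice(levels, n))
        )
        se = math.sqrt((1 / K) * (1 - 1 / K) / n)
        assert abs(acc - 1 / K) <= 3 * se


class TestCollectPredictions:
    def test_restricted_to_masked_cells(self):
        t = make_table(
            {"f": [1.0, 2.0, 3.0, 4.0], "g": ["a", "b", "a", "b"],
             "y": ["p", "q", "p", "q"]}
        )
        inst = ampute_mcar(t, 0.25, seed=3)  # 2 of 8 feature cells
        imputed = impute_marginal(inst.table)
        preds = collect_predictions(inst, imputed, normalize=False)
        assert sum(p.n for p in preds) == inst.mask.n_missing
        # truths are the original values at masked cells only
        for p in preds:
            col_mask = inst.mask.column(p.feature)
            if p.kind is ColumnKind.NUMERIC:
                want = t.df[p.feature].to_numpy(float)[col_mask]
                assert np.array_equal(np.asarray(p.y_true, float), want)


class TestAggregation:
    def test_overall_is_cell_weighted_combination(self):
        a = num_preds([1, 2, 3], [0, 0, 0])  # MAE 2, 3 cells
        b = num_preds([4], [0])              # MAE 4, 1 cell
        pooled = _pool_cells([a, b], ColumnKind.NUMERIC)
        assert mae(pooled) == pytest.approx((3 * 2 + 1 * 4) / 4)

    def test_all_correct_categorical_overall(self):
        preds = [
            cat_preds(["a", "b"], ["a", "b"]),
            cat_preds(["c"], ["c"]),
        ]
        rows = quality_rows("d", 0.1, 0, "mean_mode", preds)
        overall = [
            r for r in rows
            if r["feature"] == "OVERALL" and r["metric"] == "accuracy"
        ]
        assert overall[0]["value"] == 1.0

    def test_report_grid_shape(self):
        """2 rates x 3 replicates x 2 imputing handlers gives 12 OVERALL
        rows per metric at the per-replicate level, plus the aggregate."""
        t = generate(SyntheticSpec(n_rows=50, n_numeric=4, n_categorical=2,
                                   relevant_features=("F1",), seed=5))
        cfg = RunConfig(
            table=t,
            dataset_id="synth",
            grid=AmputationGrid(rates=(0.1, 0.3), n_replicates=3,
                                master_seed=2),
            handlers=(HandlerName.MEAN_MODE, HandlerName.MEDIAN),
        )
        report = run_quality_experiment(cfg)
        per_rep = report[
            (report.level == "per-replicate") & (report.feature == "OVERALL")
        ]
        for metric in ("MAE", "RMSE", "accuracy"):
            assert len(per_rep[per_rep.metric == metric]) == 12
        agg = report[
            (report.level == "mean-over-replicates")
            & (report.feature == "OVERALL")
        ]
        for metric in ("MAE", "RMSE", "accuracy"):
            assert len(agg[agg.metric == metric]) == 4  # 2 rates x 2 handlers

    def test_aggregate_is_mean_over_replicates(self):
        rows = []
        for rep, val in enumerate((0.2, 0.4)):
            rows.append(dict(dataset="d", rate=0.1, replicate_id=rep,
                             handler="h", feature="F1", metric="MAE",
                             value=val, level="per-replicate"))
        out = overall_and_per_feature(pd.DataFrame(rows))
        agg = out[out.level == "mean-over-replicates"]
        assert agg.value.iloc[0] == pytest.approx(0.3)


class TestDistributionShift:
    def test_identical_columns_zero(self, tiny_mixed):
        for name in tiny_mixed.feature_names:
            assert distribution_shift(tiny_mixed, tiny_mixed, name) == 0.0

    def test_categorical_tv_by_hand(self):
        a = make_table({"f": ["u", "v"], "y": ["p", "q"]})
        b = make_table({"f": ["u", "u"], "y": ["p", "q"]},
                       domains={"f": ("u", "v")})
        # (0.5, 0.5) vs (1.0, 0.0) -> TV 0.5
        assert distribution_shift(a, b, "f") == pytest.approx(0.5)

    def test_numeric_shift_detects_mean_pileup(self):
        t = generate(SyntheticSpec(n_rows=200, n_numeric=3, n_categorical=0,
                                   dependency_strength=0.5,
                                   relevant_features=("F1",), seed=8))
        inst = ampute_mcar(t, 0.4, seed=9)
        imputed = impute_marginal(inst.table)
        assert distribution_shift(t, imputed, "F1") > 0.05
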