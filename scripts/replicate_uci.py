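"""Replication harness for the UCI breast-cancer dataset (requires a
download; not part of the test suite).

Fetch the data file yourself, e.g.:

    curl -o breast-cancer.data \
      https://archive.ics.uci.edu/ml/machine-learning-databases/breast-cancer/breast-cancer.data

then run:

    python scripts/replicate_uci.py --data breast-cancer.data \
      [--replicates 20] [--seed 0] [--out uci_quality.csv]

The script reruns the 10-level missingness grid (5%..50%) at a reduced
replicate count on the real table (rows with pre-existing '?' markers are
dropped first), imputes with chained equations and with mode replacement,
and reports the overall categorical imputation accuracy per rate.  The
expected qualitative pattern is chained-equation accuracy above mode
replacement at every rate.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

from micebench import (
    AmputationGrid,
    ColumnKind,
    ColumnRole,
    ColumnSchema,
    HandlerName,
    ImputationConfig,
    RunConfig,
    read_table,
    run_quality_experiment,
)

# UCI breast-cancer.data: headerless; class label first, then 9
# categorical attributes
UCI_COLUMNS = [
    ("class", ColumnRole.TARGET),
    ("age", ColumnRole.FEATURE),
    ("menopause", ColumnRole.FEATURE),
    ("tumor-size", ColumnRole.FEATURE),
    ("inv-nodes", ColumnRole.FEATURE),
    ("node-caps", ColumnRole.FEATURE),
    ("deg-malig", ColumnRole.FEATURE),
    ("breast", ColumnRole.FEATURE),
    ("breast-quad", ColumnRole.FEATURE),
    ("irradiat", ColumnRole.FEATURE),
]

RATES = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))


def load_breast_cancer(path: Path):
    schema = [
        ColumnSchema(name, ColumnKind.CATEGORICAL, role)
        for name, role in UCI_COLUMNS
    ]
    # the raw file has no header; prepend one
    raw = path.read_text().strip().splitlines()
    header = ",".join(name for name, _ in UCI_COLUMNS)
    import io

    buf = io.StringIO("\n".join([header] + raw))
    return read_table(
        buf, schema, missing_tokens={"?"}, drop_preexisting_missing=True
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True)
    parser.add_argument("--replicates", type=int, default=20)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    table = load_breast_cancer(args.data)
    print(f"loaded {table.n_rows} complete rows, "
          f"{len(table.feature_names)} categorical features")

    config = RunConfig(
        table=table,
        dataset_id="breast-cancer",
        grid=AmputationGrid(rates=RATES, n_replicates=args.replicates,
                            master_seed=args.seed),
        handlers=(HandlerName.MICE, HandlerName.MEAN_MODE),
        imputation=ImputationConfig(seed=args.seed),
    )
    report = run_quality_experiment(config)
    if args.out:
        report.to_csv(args.out, index=False)

    agg = report[
        (report.level == "mean-over-replicates")
        & (report.feature == "OVERALL")
        & (report.metric == "accuracy")
    ].pivot_table(index="rate", columns="handler", values="value")
    print("\nRATE   MICE    MODE")
    wins = 0
    for rate, row in agg.iterrows():
        mark = "+" if row["mice"] > row["mean_mode"] else "-"
        wins += row["mice"] > row["mean_mode"]
        print(f"{rate:.2f}  {row['mice']:.3f}  {row['mean_mode']:.3f}  {mark}")
    print(f"\nchained equations beat mode replacement at "
          f"{wins}/{len(agg)} rates")
    sys.exit(0 if wins == len(agg) else 1)


if __name__ == "__main__":
    main()
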