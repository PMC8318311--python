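import numpy as np
import pandas as pd
import pytest

from micebench import ColumnKind, ColumnRole, ColumnSchema, TypedTable


def make_table(columns, target=None, domains=None):
    """Build a TypedTable from {name: values}; values of float dtype become
    numeric columns (NaN = missing), everything else categorical
    (None = missing).  ``target`` defaults to the last column."""
    names = list(columns)
    target = target if target is not None else names[-1]
    schema = []
    data = {}
    for name in names:
        vals = columns[name]
        observed = [v for v in vals if v is not None]
        numeric = bool(observed) and all(
            isinstance(v, (int, float)) and not isinstance(v, bool)
            for v in observed
        )
        kind = ColumnKind.NUMERIC if numeric else ColumnKind.CATEGORICAL
        role = ColumnRole.TARGET if name == target else ColumnRole.FEATURE
        schema.append(ColumnSchema(name, kind, role))
        if numeric:
            data[name] = np.array(
                [np.nan if v is None else float(v) for v in vals]
            )
        else:
            data[name] = np.array(
                [None if v is None else str(v) for v in vals], dtype=object
            )
    return TypedTable(schema, pd.DataFrame(data), domains=domains)


@pytest.fixture
def tiny_mixed():
    """Complete 8-row table: two numeric features, one categorical feature,
    binary target."""
    return make_table(
        {
            "x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "x2": [2.1, 4.2, 5.9, 8.1, 9.8, 12.2, 14.1, 15.8],
            "c1": ["a", "a", "b", "b", "a", "b", "a", "b"],
            "y": ["p", "p", "p", "p", "q", "q", "q", "q"],
        }
    )
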