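import numpy as np
import pandas as pd
import pytest

from detargets import ExpressionTable, IntervalTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_expr():
    """4 genes x 4 samples, two groups, log2 scale."""
    values = pd.DataFrame(
        [[7.0, 7.2, 3.1, 3.0],
         [5.0, 5.1, 5.2, 4.9],
         [2.0, 2.2, 6.0, 6.1],
         [8.0, 8.1, 8.0, 8.2]],
        index=["g1", "g2", "g3", "g4"],
        columns=["a1", "a2", "b1", "b2"],
    )
    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return ExpressionTable(values, groups)


def make_intervals(*records):
    """records: (chrom, start, end, name[, strand]) tuples."""
    rows = [
        (r[0], r[1], r[2], r[3], r[4] if len(r) > 4 else ".")
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    if not len(df):
        df = df.astype({"start": np.int64, "end": np.int64})
    return IntervalTable(df)


@pytest.fixture
def intervals():
    return make_intervals
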