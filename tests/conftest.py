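import numpy as np
import pandas as pd
import pytest

from roughstack import DecisionTable, load_fixture


@pytest.fixture
def toy_table():
    """Four discrete objects whose discernibility function is
    {a,c} (weight 2) and {b} (weight 2)."""
    df = pd.DataFrame({
        "a": [0, 1, 0, 1],
        "b": [0, 0, 1, 1],
        "c": [0, 1, 0, 1],
        "target": [0, 1, 1, 0],
    })
    return DecisionTable(df, "target", frozenset("abc"))


@pytest.fixture(scope="session")
def table3():
    """Embedded five-stack performance matrix with its criterion
    directions (MAE and training time cost, the rest benefit)."""
    return load_fixture("stack_performance_table3")


@pytest.fixture(scope="session")
def separable_data():
    """Two well-separated Gaussian clouds: every sensible classifier
    should be near-perfect."""
    rng = np.random.default_rng(7)
    n = 80
    X0 = rng.normal(0.0, 1.0, (n, 2))
    X1 = rng.normal(6.0, 1.0, (n, 2))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]
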