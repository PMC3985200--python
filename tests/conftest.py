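import numpy as np
import pandas as pd
import pytest

from difreg import ExpressionMatrix


def make_matrix(values, gene_ids=None, n_a=None, n_b=None):
    """Build an ExpressionMatrix from a 2-d array split into A then B columns."""
    values = np.asarray(values, dtype=float)
    n_total = values.shape[1]
    if n_a is None:
        n_a = n_total // 2
    if n_b is None:
        n_b = n_total - n_a
    assert n_a + n_b == n_total
    samples = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=gene_ids, columns=samples)
    conditions = pd.Series([s[0] for s in samples], index=samples)
    return ExpressionMatrix(data, conditions)


def pearson_oracle(x, y):
    """Textbook correlation formula, independent of the package code."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xm * ym).sum() / denom)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(size=(30, 16)), n_a=7, n_b=9)
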