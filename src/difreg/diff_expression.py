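"""Differential expression screening between the two conditions.

The test is the classical pooled-variance two-sample t statistic with a
two-sided p from the t distribution on ``n_A + n_B - 2`` degrees of freedom,
followed by Benjamini–Hochberg step-up adjustment. Genes with adjusted value
(q) strictly below the threshold — 0.05 by default — are called
differentially expressed (DEGs).

This is deliberately a transparent, closed-form surrogate for
moderated-variance pipelines: the downstream network and impact-factor
stages consume only the DEG list and per-condition means, so any external
DE caller can be substituted via a plain gene list (``--deg-list`` on the
CLI).

Degenerate genes (zero pooled variance) are handled explicitly:

* equal means → no signal: t = 0, p = 1, flag ``"constant"``;
* unequal means → infinitely strong signal under the model: p = 0, flag
  ``"degenerate"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

__all__ = ["two_sample_t", "bh_adjust", "deg_table", "select_degs"]


def two_sample_t(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene pooled two-sample t statistic (condition A minus B).

    Returns a DataFrame indexed by gene with columns ``mean_A``, ``mean_B``,
    ``t``, ``p`` and ``flag`` (empty string, ``"constant"`` or
    ``"degenerate"``).
    """
    matrix.require_min_samples(2)
    a = matrix.values_in("A")
    b = matrix.values_in("B")
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    dof = n_a + n_b - 2
    pooled_var = (ss_a + ss_b) / dof
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))

    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = np.empty_like(t)
    ok = se > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), dof)

    flags = np.array([""] * len(t), dtype=object)
    zero_var = ~ok
    const = zero_var & (delta == 0)
    degen = zero_var & (delta != 0)
    t[const], p[const] = 0.0, 1.0
    flags[const] = "constant"
    t[degen] = np.sign(delta[degen]) * np.inf
    p[degen] = 0.0
    flags[degen] = "degenerate"

    return pd.DataFrame(
        {"mean_A": mean_a, "mean_B": mean_b, "t": t, "p": p, "flag": flags},
        index=matrix.data.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def deg_table(matrix: ExpressionMatrix, threshold: float = 0.05) -> pd.DataFrame:
    """Full differential-expression table with BH-adjusted q and DEG flag.

    ``is_deg`` is true iff ``q < threshold`` (strict, per the FDR < 0.05
    screening rule).
    """
    table = two_sample_t(matrix)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["is_deg"] = table["q"] < threshold
    return table


def select_degs(table: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Genes with q strictly below threshold, ordered by (q, gene id)."""
    hits = table[table["q"] < threshold]
    order = hits.assign(_id=hits.index.astype(str)).sort_values(["q", "_id"])
    return list(order.index)
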