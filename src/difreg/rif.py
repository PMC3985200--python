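"""Regulatory Impact Factor (RIF) scoring of transcription factors.

For TF *i*, with DEGs indexed by *j*:

    RIF_i = (1 / n_de) * sum_j [ (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2 ]

where e1_j / e2_j are DEG *j*'s mean expression in condition A (normal) and
condition B (disease), and r1_ij / r2_ij are the Pearson correlations
between TF *i* and DEG *j* within each condition. A large positive score
marks a TF whose coordinated control of the differentially expressed genes
is strong in the normal condition and lost or weakened in disease; swapping
the condition labels negates every score exactly.

TF–DEG pairs with undefined correlation (zero-variance profile) contribute
0 to the sum but are tallied per TF, so that n_de is identical across TFs.
Ranking is by raw RIF descending (rank 1 = highest), ties broken by TF id;
``rank_by="abs"`` ranks by magnitude instead.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diff_coexpression import _unit_rows
from .expression_io import ExpressionMatrix

__all__ = ["condition_means", "rif_scores", "rank_tfs"]


def condition_means(matrix: ExpressionMatrix,
                    genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-gene mean expression in each condition (columns e1, e2)."""
    genes = list(matrix.gene_ids if genes is None else genes)
    unknown = [g for g in genes if g not in matrix.data.index]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown[:5]}")
    e1 = matrix.values_in("A", genes).mean(axis=1)
    e2 = matrix.values_in("B", genes).mean(axis=1)
    return pd.DataFrame({"e1": e1, "e2": e2}, index=pd.Index(genes, name="gene_id"))


def rif_scores(tfs: Sequence[str], degs: Sequence[str], means: pd.DataFrame,
               matrix: ExpressionMatrix) -> pd.DataFrame:
    """Score every TF by the impact formula above.

    ``means`` must provide e1/e2 for every DEG (see :func:`condition_means`).
    Returns a DataFrame with columns tf_id, rif, n_de, n_excluded_pairs,
    one row per TF in input order.
    """
    tfs = list(tfs)
    degs = list(degs)
    if not degs:
        raise ValueError("n_de = 0: at least one DEG is required")
    missing_tf = [t for t in tfs if t not in matrix.data.index]
    if missing_tf:
        raise KeyError(f"TFs not in expression matrix: {missing_tf[:5]}")
    missing_deg = [g for g in degs if g not in means.index]
    if missing_deg:
        raise KeyError(f"DEGs without condition means: {missing_deg[:5]}")
    matrix.require_min_samples(3)

    ua_tf, ok_a_tf = _unit_rows(matrix.values_in("A", tfs))
    ub_tf, ok_b_tf = _unit_rows(matrix.values_in("B", tfs))
    ua_dg, ok_a_dg = _unit_rows(matrix.values_in("A", degs))
    ub_dg, ok_b_dg = _unit_rows(matrix.values_in("B", degs))

    r1 = np.clip(ua_tf @ ua_dg.T, -1.0, 1.0)  # (n_tf, n_de)
    r2 = np.clip(ub_tf @ ub_dg.T, -1.0, 1.0)
    defined = (ok_a_tf & ok_b_tf)[:, None] & (ok_a_dg & ok_b_dg)[None, :]

    e1 = means.loc[degs, "e1"].to_numpy(dtype=float)
    e2 = means.loc[degs, "e2"].to_numpy(dtype=float)
    terms = (e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2
    terms = np.where(defined, terms, 0.0)

    n_de = len(degs)
    return pd.DataFrame({
        "tf_id": tfs,
        "rif": terms.sum(axis=1) / n_de,
        "n_de": n_de,
        "n_excluded_pairs": (~defined).sum(axis=1),
    })


def rank_tfs(scores: pd.DataFrame, rank_by: str = "value") -> pd.DataFrame:
    """Attach 1-based ranks: highest score first, ties broken by TF id.

    ``rank_by`` is ``"value"`` (raw RIF, the default) or ``"abs"``
    (magnitude).
    """
    if rank_by not in ("value", "abs"):
        raise ValueError(f"rank_by must be 'value' or 'abs', got {rank_by!r}")
    key = scores["rif"].abs() if rank_by == "abs" else scores["rif"]
    ranked = (scores.assign(_key=key)
              .sort_values(["_key", "tf_id"], ascending=[False, True],
                           kind="mergesort")
              .drop(columns="_key")
              .reset_index(drop=True))
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked
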