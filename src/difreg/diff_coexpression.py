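"""Differential coexpression: per-condition Pearson correlations and Diff.

For a gene (or gene/TF) pair the coexpression change between conditions is

    Diff = | r1 - r2 |

where r1 is the Pearson correlation of the two expression profiles across
the condition-A (normal) samples and r2 across the condition-B (disease)
samples. Pairs with Diff strictly greater than 1 are called differentially
coexpressed. A pair whose correlation flips sign between conditions is
additionally classified as a positive-to-negative or negative-to-positive
reversal.

All-vs-all computation is blockwise: gene profiles are centred and scaled
once per condition, correlations for a block pair are a single matrix
product, and no more than ``block_size**2`` correlations are materialised at
a time. Pairs involving a zero-variance profile have undefined correlation;
they are emitted with ``defined = False`` and excluded from selection.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

__all__ = [
    "pearson",
    "classify_sign",
    "pairwise_diff",
    "iter_pairwise_diff",
    "select_differential",
    "PAIR_COLUMNS",
]

PAIR_COLUMNS = ["id_i", "id_j", "r1", "r2", "diff", "sign_class", "defined"]

SAME_SIGN = "same_sign"
POS_TO_NEG = "reversal_pos_to_neg"
NEG_TO_POS = "reversal_neg_to_pos"


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance.

    Requires equal lengths of at least 3 samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def classify_sign(r1: float, r2: float) -> str:
    """Sign-reversal class of a defined (r1, r2) pair; zeros are same_sign."""
    if r1 > 0 and r2 < 0:
        return POS_TO_NEG
    if r1 < 0 and r2 > 0:
        return NEG_TO_POS
    return SAME_SIGN


def _unit_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre rows and scale to unit norm; zero-variance rows flagged."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    ok = norms > 0
    unit = np.zeros_like(centred)
    unit[ok] = centred[ok] / norms[ok, None]
    return unit, ok


def _classify_vec(r1: np.ndarray, r2: np.ndarray, defined: np.ndarray) -> np.ndarray:
    out = np.full(r1.shape, SAME_SIGN, dtype=object)
    with np.errstate(invalid="ignore"):
        out[defined & (r1 > 0) & (r2 < 0)] = POS_TO_NEG
        out[defined & (r1 < 0) & (r2 > 0)] = NEG_TO_POS
    out[~defined] = ""
    return out


def _chunk_frame(ids_i, ids_j, r1, r2, defined) -> pd.DataFrame:
    # canonical unordered key: id_i is the lexicographically smaller id
    ids_i = np.asarray(ids_i, dtype=object)
    ids_j = np.asarray(ids_j, dtype=object)
    swap = ids_i > ids_j
    ids_i[swap], ids_j[swap] = ids_j[swap], ids_i[swap]
    r1 = np.where(defined, np.clip(r1, -1.0, 1.0), np.nan)
    r2 = np.where(defined, np.clip(r2, -1.0, 1.0), np.nan)
    diff = np.abs(r1 - r2)
    return pd.DataFrame(
        {
            "id_i": ids_i,
            "id_j": ids_j,
            "r1": r1,
            "r2": r2,
            "diff": diff,
            "sign_class": _classify_vec(r1, r2, defined),
            "defined": defined,
        }
    )


def iter_pairwise_diff(matrix: ExpressionMatrix,
                       pairs: Iterable[tuple[str, str]] | str = "all",
                       block_size: int = 512) -> Iterator[pd.DataFrame]:
    """Yield chunks of the per-pair (r1, r2, diff) table.

    ``pairs`` is either the string ``"all"`` (all unordered gene pairs) or an
    iterable of (id_i, id_j) tuples, e.g. the TF-target relation set. With
    ``"all"`` the G x G correlation structure is traversed in blocks of at
    most ``block_size`` genes per axis.
    """
    matrix.require_min_samples(3)
    unit_a, ok_a = _unit_rows(matrix.values_in("A"))
    unit_b, ok_b = _unit_rows(matrix.values_in("B"))
    ok = ok_a & ok_b
    genes = np.asarray(matrix.gene_ids, dtype=object)

    if isinstance(pairs, str):
        if pairs != "all":
            raise ValueError(f"pairs must be 'all' or an iterable, got {pairs!r}")
        n = len(genes)
        for b0 in range(0, n, block_size):
            b1 = min(b0 + block_size, n)
            for c0 in range(b0, n, block_size):
                c1 = min(c0 + block_size, n)
                r1 = unit_a[b0:b1] @ unit_a[c0:c1].T
                r2 = unit_b[b0:b1] @ unit_b[c0:c1].T
                rows, cols = np.indices(r1.shape)
                rows, cols = rows + b0, cols + c0
                keep = rows < cols  # strict upper triangle in global indices
                if not keep.any():
                    continue
                ri, ci = rows[keep], cols[keep]
                yield _chunk_frame(genes[ri], genes[ci], r1[keep], r2[keep],
                                   ok[ri] & ok[ci])
        return

    index = {g: i for i, g in enumerate(genes)}
    pair_list = list(pairs)
    for p0 in range(0, len(pair_list), block_size * block_size):
        chunk = pair_list[p0:p0 + block_size * block_size]
        try:
            ii = np.array([index[a] for a, _ in chunk], dtype=int)
            jj = np.array([index[b] for _, b in chunk], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in the matrix") from None
        r1 = np.einsum("ij,ij->i", unit_a[ii], unit_a[jj])
        r2 = np.einsum("ij,ij->i", unit_b[ii], unit_b[jj])
        yield _chunk_frame(genes[ii], genes[jj], r1, r2, ok[ii] & ok[jj])


def pairwise_diff(matrix: ExpressionMatrix,
                  pairs: Iterable[tuple[str, str]] | str = "all",
                  block_size: int = 512) -> pd.DataFrame:
    """Full per-pair table (see :func:`iter_pairwise_diff`) as one DataFrame."""
    chunks = list(iter_pairwise_diff(matrix, pairs, block_size))
    if not chunks:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


def select_differential(pairs: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Pairs with defined correlations and diff strictly above threshold."""
    keep = pairs["defined"] & (pairs["diff"] > threshold)
    return pairs[keep].reset_index(drop=True)
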