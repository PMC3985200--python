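"""Hypergeometric pathway enrichment of network genes against GMT gene sets.

For a query of n genes drawn from a universe of N genes, a pathway with K
members inside the universe and an observed overlap of k genes, the
enrichment p-value is the hypergeometric upper tail P(X >= k). The optional
EASE variant scores P(X >= k) with one overlap gene removed (k - 1), a more
conservative score used by the DAVID service. BH-adjusted q-values are
computed over the tested pathways, and rows with p below the significance
level (0.05 by default) are flagged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diff_expression import bh_adjust

__all__ = ["hypergeom_upper_tail", "enrich", "read_gmt", "write_gmt",
           "RESULT_COLUMNS"]

RESULT_COLUMNS = ["pathway_id", "pathway_name", "K", "n", "k", "p", "q",
                  "significant", "overlap_genes"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read GMT: one gene set per line, ``id<TAB>name<TAB>gene...``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line needs id, name and >=1 gene: {line!r}")
            pathway_id, name, genes = fields[0], fields[1], fields[2:]
            if pathway_id in sets:
                raise ValueError(f"duplicate pathway id {pathway_id!r}")
            sets[pathway_id] = (name, [g for g in genes if g])
    return sets


def write_gmt(gene_sets: Mapping[str, tuple[str, Sequence[str]]],
              path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for pathway_id, (name, genes) in gene_sets.items():
            handle.write("\t".join([pathway_id, name, *genes]) + "\n")


def enrich(query: Iterable[str],
           gene_sets: Mapping[str, tuple[str, Sequence[str]]],
           universe: Iterable[str],
           alpha: float = 0.05,
           ease: bool = False) -> pd.DataFrame:
    """Test every pathway for over-representation of the query genes.

    Query genes outside the universe are dropped (their count is recorded in
    ``DataFrame.attrs["n_query_dropped"]``); each pathway is intersected
    with the universe and skipped if empty afterwards. Results are sorted by
    p ascending with pathway id as the deterministic tie-break.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_all = set(query)
    query_set = query_all & universe_set
    n_dropped = len(query_all) - len(query_set)
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for pathway_id in sorted(gene_sets):
        name, genes = gene_sets[pathway_id]
        members = set(genes) & universe_set
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & query_set)
        k = len(overlap)
        if ease:
            p = hypergeom_upper_tail(max(k - 1, 0), K, n, N)
        else:
            p = hypergeom_upper_tail(k, K, n, N)
        rows.append({"pathway_id": pathway_id, "pathway_name": name,
                     "K": K, "n": n, "k": k, "p": p,
                     "overlap_genes": ",".join(overlap)})
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                         if c not in ("q", "significant")])
    if result.empty:
        result["q"] = []
        result["significant"] = []
        result.attrs["n_query_dropped"] = n_dropped
        return result[RESULT_COLUMNS]
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["p"] < alpha
    result = (result.sort_values(["p", "pathway_id"], kind="mergesort")
              .reset_index(drop=True))
    result.attrs["n_query_dropped"] = n_dropped
    return result[RESULT_COLUMNS]
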