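"""Differential regulatory network: relations ∩ differential pairs.

An edge TF → target enters the network iff (a) the (TF, target) relation was
derived from promoter binding and (b) the unordered pair passed the
differential-coexpression screen. Each edge carries the pair's r1, r2 and
diff. When both members of a differential pair are TFs with relations in both
orientations, both directed edges are present.

"Top" truncation (the top 25% for visualisation, or a fixed top-k for
enrichment) ranks edges by diff descending, ties broken lexicographically by
(tf_id, target_id) so output files are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable
from xml.sax.saxutils import escape

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DiffRegNetwork", "build_network", "top_edges", "export_network",
           "read_edge_tsv", "EDGE_COLUMNS"]

EDGE_COLUMNS = ["tf_id", "target_id", "r1", "r2", "diff", "sign_class"]


@dataclass
class DiffRegNetwork:
    """Directed TF → target edge table plus node role labels."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns {missing}")
        self.edges = self.edges[EDGE_COLUMNS].reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> set[str]:
        return set(self.edges["tf_id"])

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target_id"])

    @property
    def nodes(self) -> set[str]:
        return self.tfs | self.targets

    def node_roles(self) -> pd.DataFrame:
        """Per-node role: TF, target, or both."""
        rows = []
        for node in sorted(self.nodes):
            is_tf = node in self.tfs
            is_target = node in self.targets
            role = "both" if (is_tf and is_target) else ("TF" if is_tf else "target")
            rows.append({"node": node, "role": role})
        return pd.DataFrame(rows, columns=["node", "role"])


def build_network(diff_pairs: pd.DataFrame,
                  relations: Iterable[tuple[str, str]]) -> DiffRegNetwork:
    """Intersect selected differential pairs with the TF→target relations.

    ``diff_pairs`` is a selected pair table (columns id_i, id_j, r1, r2,
    diff, sign_class) with canonical unordered keys; ``relations`` is the
    deduplicated (tf, gene) set from promoter mapping.
    """
    by_key = {
        (i, j): (r1, r2, diff, sign)
        for i, j, r1, r2, diff, sign in zip(
            diff_pairs["id_i"], diff_pairs["id_j"], diff_pairs["r1"],
            diff_pairs["r2"], diff_pairs["diff"], diff_pairs["sign_class"],
        )
    }

    records = []
    for tf, gene in sorted(set(relations)):
        key = (tf, gene) if tf <= gene else (gene, tf)
        hit = by_key.get(key)
        if hit is None:
            continue
        r1, r2, diff, sign = hit
        records.append({
            "tf_id": tf, "target_id": gene,
            "r1": r1, "r2": r2, "diff": diff, "sign_class": sign,
        })
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    return DiffRegNetwork(edges)


def top_edges(network: DiffRegNetwork, k: int | None = None,
              fraction: float | None = None) -> DiffRegNetwork:
    """Highest-diff edges: first ``k``, or ``ceil(fraction * n_edges)``.

    Exactly one of ``k`` / ``fraction`` must be given. A ``k`` larger than
    the edge count is clamped (with a warning) to the whole network.
    """
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    n = network.n_edges
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        k = math.ceil(fraction * n)
    else:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > n:
            logger.warning("requested top %d edges but network has only %d", k, n)
            k = n
    ranked = network.edges.sort_values(
        ["diff", "tf_id", "target_id"], ascending=[False, True, True],
        kind="mergesort",
    )
    return DiffRegNetwork(ranked.head(k).reset_index(drop=True))


def export_network(network: DiffRegNetwork, path: str | Path,
                   format: str = "tsv") -> None:
    """Write the network as SIF, edge TSV, or GraphML.

    SIF lines read ``tf_id<TAB>regulates<TAB>target_id``; the edge TSV
    carries r1, r2, diff and sign_class and round-trips losslessly through
    :func:`read_edge_tsv`.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as handle:
            for _, row in network.edges.iterrows():
                handle.write(f"{row['tf_id']}\tregulates\t{row['target_id']}\n")
    elif format == "tsv":
        network.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "graphml":
        _write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def _write_graphml(network: DiffRegNetwork, path: Path) -> None:
    import networkx as nx

    graph = nx.DiGraph()
    roles = {r["node"]: r["role"] for _, r in network.node_roles().iterrows()}
    for node, role in sorted(roles.items()):
        graph.add_node(escape(node), role=role)
    for _, row in network.edges.iterrows():
        graph.add_edge(escape(row["tf_id"]), escape(row["target_id"]),
                       r1=float(row["r1"]), r2=float(row["r2"]),
                       diff=float(row["diff"]), sign_class=row["sign_class"])
    nx.write_graphml(graph, path)


def read_edge_tsv(path: str | Path) -> DiffRegNetwork:
    edges = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "target_id": str})
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    return DiffRegNetwork(edges)
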