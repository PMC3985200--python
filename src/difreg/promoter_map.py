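"""TF → target mapping by intersecting binding sites with promoter windows.

A gene's promoter window runs from 1 kb upstream to 0.5 kb downstream of its
transcription start site (TSS), oriented by strand: upstream means 5' of the
TSS on the gene's own strand. Any binding site of a transcription factor that
overlaps the window by at least one base yields a (TF, gene) regulatory
relation; multiple overlapping sites of the same TF collapse to one relation.

All coordinates are 0-based half-open (BED convention). Overlap of intervals
[a, b) and [c, d) means ``a < d and c < b``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

__all__ = [
    "GeneAnchor",
    "TfbsSite",
    "promoter_window",
    "map_tfbs_to_genes",
    "read_tfbs_bed",
    "read_anchor_bed",
    "write_relations",
    "read_relations",
]


@dataclass(frozen=True)
class GeneAnchor:
    """A gene's TSS location: chromosome, 0-based position and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be non-negative, got {self.tss}")


@dataclass(frozen=True)
class TfbsSite:
    """One binding-site interval of a transcription factor (half-open)."""

    tf_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


def promoter_window(anchor: GeneAnchor, upstream: int = 1000, downstream: int = 500,
                    ignore_strand: bool = False) -> tuple[str, int, int]:
    """Half-open promoter interval around the TSS, clipped at position 0.

    On the + strand (or with ``ignore_strand``) the window is
    ``[tss - upstream, tss + downstream)``; on the - strand it is mirrored to
    ``[tss - downstream, tss + upstream)``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if anchor.strand == "+" or ignore_strand:
        start, end = anchor.tss - upstream, anchor.tss + downstream
    else:
        start, end = anchor.tss - downstream, anchor.tss + upstream
    return anchor.chrom, max(start, 0), max(end, 0)


def map_tfbs_to_genes(sites: Iterable[TfbsSite], anchors: Iterable[GeneAnchor],
                      upstream: int = 1000, downstream: int = 500,
                      ignore_strand: bool = False) -> set[tuple[str, str]]:
    """Deduplicated (tf_id, gene_id) relations from site/promoter overlap.

    A relation is present iff at least one site of the TF overlaps the gene's
    promoter window by >= 1 base on the same chromosome. The result does not
    depend on input ordering.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for anchor in anchors:
        chrom, start, end = promoter_window(anchor, upstream, downstream, ignore_strand)
        if start < end:  # zero-width windows cannot overlap anything
            trees[chrom].addi(start, end, anchor.gene_id)

    relations: set[tuple[str, str]] = set()
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(site.start, site.end):
            relations.add((site.tf_id, hit.data))
    return relations


def read_tfbs_bed(path: str | Path) -> list[TfbsSite]:
    """Read binding sites from BED: chrom, start, end, name (= tf id)."""
    sites = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            sites.append(TfbsSite(name, chrom, int(start), int(end)))
    return sites


def read_anchor_bed(path: str | Path) -> list[GeneAnchor]:
    """Read gene TSS anchors from BED6: chrom, tss, tss+1, gene, score, strand."""
    anchors = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, _end, gene_id = fields[:4]
            strand = fields[5] if len(fields) > 5 else "+"
            anchors.append(GeneAnchor(gene_id, chrom, int(start), strand))
    return anchors


def write_relations(relations: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write relations as a sorted two-column TSV ``tf_id<TAB>gene_id``."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("tf_id\tgene_id\n")
        for tf, gene in sorted(set(relations)):
            handle.write(f"{tf}\t{gene}\n")


def read_relations(path: str | Path) -> set[tuple[str, str]]:
    relations = set()
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if header.strip() and not header.startswith("tf_id"):
            tf, gene = header.rstrip("\n").split("\t")[:2]
            relations.add((tf, gene))
        for line in handle:
            if not line.strip():
                continue
            tf, gene = line.rstrip("\n").split("\t")[:2]
            relations.add((tf, gene))
    return relations
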