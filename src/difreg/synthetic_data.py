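"""Synthetic two-condition expression data with planted regulatory structure.

The generator emulates the study design every pipeline stage expects: two
small, unequal sample groups (7 normal vs 9 disease by default), a TF→target
relation set realised as binding-site and TSS coordinates on one artificial
chromosome, a designated high-impact TF whose correlation to its targets is
rewired between conditions, and differentially expressed genes with a fixed
mean shift over Gaussian measurement noise.

Planted scenario
----------------
One TF (the *impact TF*, always the first) drives a set of target genes in
the normal condition (correlation ``r_a = +0.9``); in the disease condition
the coupling is rewired (``r_b = -0.9``) and the same targets lose
expression (shift of two noise standard deviations downward). This is the
loss-of-activation picture under which a regulator earns a large positive
Regulatory Impact Factor: strong coordinated control of highly expressed
targets in the normal state, inverted control of down-regulated targets in
disease. All remaining genes are independent Gaussian noise around a common
baseline, and background TF→target relations carry no planted signal.

Values are on a log2-microarray-like scale (baseline 8.0, noise sd 1.0).
Everything is deterministic given the seed (NumPy PCG64 streams).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .promoter_map import GeneAnchor, TfbsSite

__all__ = ["SimulationTruth", "generate_truth", "simulate_expression",
           "simulate_dataset", "write_fixture_files"]

# Each relation (tf, g) is realised as one binding site [tss-200, tss-180),
# which sits inside the default 1 kb / 0.5 kb promoter window on either
# strand, while the 20 kb gene spacing keeps windows disjoint.
_CHROM = "chrS"
_GENE_SPACING = 20_000
_FIRST_TSS = 100_000
_SITE_OFFSET = 200
_SITE_WIDTH = 20


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    n_tfs: int
    n_genes: int
    n_samples_a: int
    n_samples_b: int
    noise_sd: float
    baseline: float
    impact_tf: str
    tf_ids: list[str]
    gene_ids: list[str]
    planted_de_genes: dict[str, float]  # gene -> mean shift (B minus A)
    planted_rewired_pairs: list[tuple[str, str, float, float]]  # (tf, g, r_a, r_b)
    planted_relations: set[tuple[str, str]]
    tss_table: list[GeneAnchor] = field(repr=False)
    tfbs_table: list[TfbsSite] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_samples_a < 3 or self.n_samples_b < 3:
            raise ValueError("each condition needs at least 3 samples")
        for tf, gene, r_a, r_b in self.planted_rewired_pairs:
            if (tf, gene) not in self.planted_relations:
                raise ValueError(f"rewired pair ({tf}, {gene}) not in relations")
            if abs(r_a) > 1 or abs(r_b) > 1:
                raise ValueError(f"planted correlations must lie in [-1, 1]")


def generate_truth(n_tfs: int, n_genes: int, n_rewired: int, n_de: int,
                   seed: int, *, n_samples_a: int = 7, n_samples_b: int = 9,
                   noise_sd: float = 1.0, baseline: float = 8.0,
                   r_a: float = 0.9, r_b: float = -0.9,
                   de_shift: float | None = None,
                   n_relations: int | None = None) -> SimulationTruth:
    """Draw the planted structure for one dataset.

    The rewired pairs all belong to the impact TF and their targets are
    drawn from the planted DE genes first, so the impact TF's signal acts
    through genes that enter the DEG screen. ``de_shift`` is the condition-B
    minus condition-A mean difference of a DE gene; the default is a loss of
    two noise standard deviations in disease. ``n_relations`` is the total
    relation count including background relations drawn uniformly (default
    ``n_rewired + 15 * n_tfs``).
    """
    if n_tfs < 1 or n_genes < 1:
        raise ValueError("need at least one TF and one gene")
    if n_de > n_genes:
        raise ValueError(f"n_de = {n_de} exceeds n_genes = {n_genes}")
    if n_rewired > n_genes:
        raise ValueError(f"n_rewired = {n_rewired} exceeds n_genes = {n_genes}")
    if n_relations is None:
        n_relations = min(n_rewired + 15 * n_tfs, n_tfs * n_genes)
    if n_relations > n_tfs * n_genes:
        raise ValueError("n_relations exceeds the number of possible pairs")
    if n_relations < n_rewired:
        raise ValueError("n_relations must cover the rewired pairs")
    if de_shift is None:
        de_shift = -2.0 * noise_sd

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    impact_tf = tf_ids[0]

    de_genes = [str(g) for g in rng.choice(gene_ids, size=n_de, replace=False)]
    # rewired targets come from the DE set first, then the remainder
    pool = de_genes + [g for g in gene_ids if g not in set(de_genes)]
    rewired_targets = pool[:n_rewired]
    rewired = [(impact_tf, g, float(r_a), float(r_b)) for g in rewired_targets]

    relations = {(impact_tf, g) for g in rewired_targets}
    all_pairs = [(t, g) for t in tf_ids for g in gene_ids
                 if (t, g) not in relations]
    extra = n_relations - len(relations)
    if extra > 0:
        chosen = rng.choice(len(all_pairs), size=extra, replace=False)
        relations.update(all_pairs[i] for i in chosen)

    anchors = []
    for idx, name in enumerate(tf_ids + gene_ids):
        tss = _FIRST_TSS + idx * _GENE_SPACING
        strand = "+" if idx % 2 == 0 else "-"
        anchors.append(GeneAnchor(name, _CHROM, tss, strand))
    tss_of = {a.gene_id: a.tss for a in anchors}
    sites = [TfbsSite(tf, _CHROM, tss_of[g] - _SITE_OFFSET,
                      tss_of[g] - _SITE_OFFSET + _SITE_WIDTH)
             for tf, g in sorted(relations)]

    return SimulationTruth(
        seed=seed, n_tfs=n_tfs, n_genes=n_genes,
        n_samples_a=n_samples_a, n_samples_b=n_samples_b,
        noise_sd=noise_sd, baseline=baseline, impact_tf=impact_tf,
        tf_ids=tf_ids, gene_ids=gene_ids,
        planted_de_genes={g: float(de_shift) for g in de_genes},
        planted_rewired_pairs=rewired,
        planted_relations=relations,
        tss_table=anchors, tfbs_table=sites,
    )


def simulate_expression(truth: SimulationTruth) -> ExpressionMatrix:
    """Draw one expression matrix realising the planted truth.

    Every TF row is an independent standard-normal profile (scaled by
    ``noise_sd`` around ``baseline``). A rewired target of the impact TF is
    built by regression on the TF profile, ``x = r*z_tf + sqrt(1-r^2)*eps``,
    so its correlation with the TF equals the planted value in expectation.
    DE genes receive their mean shift in condition B.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    rewired_by_gene = {g: (tf, r_a, r_b) for tf, g, r_a, r_b
                       in truth.planted_rewired_pairs}
    tf_index = {t: i for i, t in enumerate(truth.tf_ids)}

    blocks = []
    for cond_idx, n_c in enumerate([truth.n_samples_a, truth.n_samples_b]):
        z_tf = rng.standard_normal((truth.n_tfs, n_c))
        z_gene = np.empty((truth.n_genes, n_c))
        eps = rng.standard_normal((truth.n_genes, n_c))
        for gi, g in enumerate(truth.gene_ids):
            planted = rewired_by_gene.get(g)
            if planted is None:
                z_gene[gi] = eps[gi]
            else:
                tf, r_a, r_b = planted
                r = r_b if cond_idx else r_a
                z_gene[gi] = r * z_tf[tf_index[tf]] + np.sqrt(1 - r * r) * eps[gi]
        values = truth.baseline + truth.noise_sd * np.vstack([z_tf, z_gene])
        if cond_idx == 1:
            gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
            for g, shift in truth.planted_de_genes.items():
                values[truth.n_tfs + gene_index[g]] += shift
        blocks.append(values)

    sample_ids = ([f"A{i + 1}" for i in range(truth.n_samples_a)]
                  + [f"B{i + 1}" for i in range(truth.n_samples_b)])
    conditions = pd.Series([s[0] for s in sample_ids], index=sample_ids)
    data = pd.DataFrame(np.hstack(blocks), index=truth.tf_ids + truth.gene_ids,
                        columns=sample_ids)
    return ExpressionMatrix(data, conditions)


def simulate_dataset(n_tfs: int = 10, n_genes: int = 300, n_rewired: int = 20,
                     n_de: int = 50, seed: int = 0,
                     **kwargs) -> tuple[SimulationTruth, ExpressionMatrix]:
    """Default fixture: 10 TFs, 300 genes, 20 rewired pairs, 50 DE genes."""
    truth = generate_truth(n_tfs, n_genes, n_rewired, n_de, seed, **kwargs)
    return truth, simulate_expression(truth)


def _build_gmt(truth: SimulationTruth, rng: np.random.Generator
               ) -> dict[str, tuple[str, list[str]]]:
    """One pathway enriched in planted DE genes (>= 80% DE members by
    construction) plus two size-matched null pathways."""
    de = sorted(truth.planted_de_genes)
    non_de = [g for g in truth.gene_ids if g not in truth.planted_de_genes]
    n_pad = min(len(non_de), len(de) // 4)
    pad = list(rng.choice(non_de, size=n_pad, replace=False)) if n_pad else []
    sets = {"PW_DE": ("planted differential pathway", de + pad)}
    size = max(len(de), 5)
    for idx in range(2):
        members = sorted(rng.choice(truth.gene_ids, size=min(size, truth.n_genes),
                                    replace=False))
        sets[f"PW_NULL{idx + 1}"] = (f"null pathway {idx + 1}", list(members))
    return sets


def write_fixture_files(truth: SimulationTruth, matrix: ExpressionMatrix,
                        out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set for one simulated dataset.

    Emits expression.tsv, conditions.tsv, probe_map.tsv (identity mapping),
    tss.bed, tfbs.bed (realising exactly the planted relations under the
    default promoter window), pathways.gmt and truth.json. Returns a name →
    path mapping.
    """
    from .enrichment import write_gmt
    from .expression_io import write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("expression", "expression.tsv"), ("conditions", "conditions.tsv"),
        ("probe_map", "probe_map.tsv"), ("tss", "tss.bed"),
        ("tfbs", "tfbs.bed"), ("gmt", "pathways.gmt"),
        ("truth", "truth.json")]}

    write_expression_matrix(matrix, paths["expression"])
    with open(paths["conditions"], "w", encoding="utf-8") as handle:
        for sample in matrix.sample_ids:
            handle.write(f"{sample}\t{matrix.conditions[sample]}\n")
    with open(paths["probe_map"], "w", encoding="utf-8") as handle:
        for gene in matrix.gene_ids:
            handle.write(f"{gene}\t{gene}\n")
    with open(paths["tss"], "w", encoding="utf-8") as handle:
        for a in truth.tss_table:
            handle.write(f"{a.chrom}\t{a.tss}\t{a.tss + 1}\t{a.gene_id}\t0\t{a.strand}\n")
    with open(paths["tfbs"], "w", encoding="utf-8") as handle:
        for s in truth.tfbs_table:
            handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.tf_id}\n")

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    write_gmt(_build_gmt(truth, rng), paths["gmt"])

    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump({
            "seed": truth.seed, "n_tfs": truth.n_tfs, "n_genes": truth.n_genes,
            "n_samples_a": truth.n_samples_a, "n_samples_b": truth.n_samples_b,
            "noise_sd": truth.noise_sd, "baseline": truth.baseline,
            "impact_tf": truth.impact_tf,
            "planted_de_genes": truth.planted_de_genes,
            "planted_rewired_pairs": [list(p) for p in truth.planted_rewired_pairs],
            "planted_relations": sorted(list(r) for r in truth.planted_relations),
        }, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return paths
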