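"""End-to-end pipeline: preprocess → DEG → relations → differential
coexpression → network → RIF → enrichment.

Every stage writes its result as a plain-text intermediate file (the stage
contract), so runs are inspectable and restartable, and a ``manifest.json``
records the configuration, input checksums and per-stage row counts. Given
identical inputs and configuration the outputs are byte-identical across
runs; the manifest deliberately contains no timestamps.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diff_coexpression import (PAIR_COLUMNS, iter_pairwise_diff,
                                select_differential)
from .diff_expression import deg_table, select_degs
from .enrichment import enrich, read_gmt
from .expression_io import (collapse_probes, read_expression_matrix,
                            read_probe_map)
from .promoter_map import (map_tfbs_to_genes, read_anchor_bed, read_tfbs_bed,
                           write_relations)
from .regulatory_network import build_network, export_network, top_edges
from .rif import condition_means, rank_tfs, rif_scores

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All paths and thresholds of one pipeline run.

    Exactly one of ``top_fraction`` / ``top_k`` must be set; the default
    keeps the whole network (``top_fraction = 1.0``).
    """

    expression: str
    conditions: str
    tss: str
    tfbs: str
    out_dir: str
    probe_map: str | None = None
    gmt: str | None = None
    deg_list: str | None = None
    deg_fdr: float = 0.05
    diff_threshold: float = 1.0
    top_fraction: float | None = 1.0
    top_k: int | None = None
    upstream: int = 1000
    downstream: int = 500
    ignore_strand: bool = False
    pairs: str = "tf-target"  # or "all"
    block_size: int = 512
    compress_pairs: bool = False
    ease: bool = False
    alpha: float = 0.05
    rank_by: str = "value"
    seed: int = 0

    def validate(self) -> None:
        if (self.top_fraction is None) == (self.top_k is None):
            raise ValueError("set exactly one of top_fraction / top_k")
        if self.deg_fdr <= 0 or self.diff_threshold < 0:
            raise ValueError("thresholds must be positive")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("promoter window extents must be non-negative")
        if self.pairs not in ("tf-target", "all"):
            raise ValueError(f"pairs must be 'tf-target' or 'all', got {self.pairs!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        for name in ("expression", "conditions", "tss", "tfbs"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        required = ("expression", "conditions", "tss", "tfbs", "out_dir")
        missing = [key for key in required if key not in raw]
        if missing:
            raise ValueError(f"missing required config keys: {missing}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "difreg", "version": __version__,
        "config": asdict(config), "inputs": {}, "stages": {}, "notes": [],
    }
    for name in ("expression", "conditions", "probe_map", "tss", "tfbs",
                 "gmt", "deg_list"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # stage 1: expression input (+ optional probe collapse)
    matrix = read_expression_matrix(config.expression, config.conditions)
    if config.probe_map:
        matrix = collapse_probes(matrix, read_probe_map(config.probe_map))
    logger.info("expression: %d genes x %d samples (%d A, %d B)",
                len(matrix.gene_ids), len(matrix.sample_ids),
                matrix.n_samples("A"), matrix.n_samples("B"))
    manifest["stages"]["expression"] = {
        "genes": len(matrix.gene_ids), "samples": len(matrix.sample_ids),
        "samples_A": matrix.n_samples("A"), "samples_B": matrix.n_samples("B"),
    }

    # stage 2: differential expression
    table = deg_table(matrix, config.deg_fdr)
    deg_path = out / "deg_table.tsv"
    table.rename_axis("id").to_csv(deg_path, sep="\t", float_format="%.10g")
    if config.deg_list:
        with open(config.deg_list, encoding="utf-8") as handle:
            degs = [line.strip() for line in handle if line.strip()]
        manifest["notes"].append("DEG list supplied externally")
    else:
        degs = select_degs(table, config.deg_fdr)
    logger.info("deg: %d of %d genes at FDR < %g",
                len(degs), len(table), config.deg_fdr)
    manifest["stages"]["deg"] = {"n_genes": len(table), "n_degs": len(degs),
                                 "rows": len(table)}

    # stage 3: promoter mapping
    relations = map_tfbs_to_genes(
        read_tfbs_bed(config.tfbs), read_anchor_bed(config.tss),
        config.upstream, config.downstream, config.ignore_strand)
    relations = {(tf, g) for tf, g in relations if g in matrix.data.index
                 and tf in matrix.data.index}
    write_relations(relations, out / "relations.tsv")
    n_tfs_rel = len({tf for tf, _ in relations})
    logger.info("relations: %d pairs on %d TFs", len(relations), n_tfs_rel)
    manifest["stages"]["relations"] = {"rows": len(relations),
                                       "n_tfs": n_tfs_rel}

    # stage 4: differential coexpression
    pair_spec = sorted(relations) if config.pairs == "tf-target" else "all"
    pairs_path = out / ("diff_pairs.tsv.gz" if config.compress_pairs
                        else "diff_pairs.tsv")
    opener = gzip.open if config.compress_pairs else open
    selected_chunks = []
    n_pairs = n_undefined = 0
    with opener(pairs_path, "wt", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(PAIR_COLUMNS) + "\n")
        for chunk in iter_pairwise_diff(matrix, pair_spec, config.block_size):
            chunk.to_csv(handle, sep="\t", header=False, index=False,
                         float_format="%.10g")
            n_pairs += len(chunk)
            n_undefined += int((~chunk["defined"]).sum())
            kept = select_differential(chunk, config.diff_threshold)
            if len(kept):
                selected_chunks.append(kept)
    selected = (pd.concat(selected_chunks, ignore_index=True)
                if selected_chunks else pd.DataFrame(columns=PAIR_COLUMNS))
    logger.info("diffcoexp: %d pairs, %d selected (diff > %g), %d undefined",
                n_pairs, len(selected), config.diff_threshold, n_undefined)
    manifest["stages"]["diff_pairs"] = {
        "rows": n_pairs, "selected": len(selected), "undefined": n_undefined,
    }

    # stage 5: network construction and truncation
    network = build_network(selected, relations)
    network = top_edges(network, k=config.top_k, fraction=config.top_fraction)
    export_network(network, out / "network_edges.tsv", "tsv")
    export_network(network, out / "network.sif", "sif")
    network.node_roles().to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    logger.info("network: %d edges, %d TFs, %d targets",
                network.n_edges, len(network.tfs), len(network.targets))
    manifest["stages"]["network"] = {
        "rows": network.n_edges, "n_tfs": len(network.tfs),
        "n_targets": len(network.targets),
    }

    # stage 6: regulatory impact factors for the network TFs
    rif_path = out / "rif.tsv"
    tfs = sorted(network.tfs)
    if tfs and degs:
        scores = rank_tfs(
            rif_scores(tfs, degs, condition_means(matrix, degs), matrix),
            config.rank_by)
        scores.to_csv(rif_path, sep="\t", index=False, float_format="%.10g")
        manifest["stages"]["rif"] = {"rows": len(scores), "n_de": len(degs)}
    else:
        pd.DataFrame(columns=["tf_id", "rif", "n_de", "n_excluded_pairs",
                              "rank"]).to_csv(rif_path, sep="\t", index=False)
        manifest["stages"]["rif"] = {"rows": 0, "n_de": len(degs)}
        manifest["notes"].append("rif skipped: empty network or no DEGs")

    # stage 7: pathway enrichment of network genes (optional)
    if config.gmt:
        query = sorted(network.nodes)
        if query:
            result = enrich(query, read_gmt(config.gmt), matrix.gene_ids,
                            alpha=config.alpha, ease=config.ease)
            result.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.10g")
            manifest["stages"]["enrichment"] = {
                "rows": len(result),
                "significant": int(result["significant"].sum()),
            }
        else:
            manifest["notes"].append("enrichment skipped: empty network")

    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest
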