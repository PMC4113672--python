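"""End-to-end orchestration: filter -> correlate -> select -> score -> scan -> enrich -> network.

Each stage is a function that reads and writes plain TSV intermediates,
so the one-shot :func:`run_pipeline` and the CLI subcommands share code
paths and produce byte-identical tables. A JSON manifest records input
hashes, realized cutoffs and counts at every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, io, network, seedmatch
from . import sensitivity as sens

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-serializable)."""

    expression: str
    annotation: str
    mirna_fasta: str
    utr_fasta: str
    lnc_fasta: str
    outdir: str
    metadata: str | None = None
    condition: str | None = None
    max_missing_frac: float = 0.10
    min_utr_len: int = 500
    min_pairs: int = 30
    log2: bool = False
    pair_percentile: float = 99.0
    pair_tail: str = "positive"
    s_mode: str = "fixed"
    s_threshold: float = 0.3
    s_percentile: float = 99.0
    enrichment_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_filter(cfg: PipelineConfig, outdir: Path) -> dict:
    """Read, condition-filter, missing-filter, partition and UTR-filter."""
    matrix = io.read_expression(
        cfg.expression, condition_filter=cfg.condition, metadata_path=cfg.metadata
    )
    if cfg.log2:
        matrix = matrix.log2_transform()
    matrix = io.filter_missing(matrix, cfg.max_missing_frac)
    annotation = io.read_annotation(cfg.annotation)
    mrna, lncrna, mirna = io.partition_by_biotype(matrix, annotation)
    utrs = io.read_fasta(cfg.utr_fasta, "utr3")
    mrna = io.filter_by_utr(mrna, utrs, cfg.min_utr_len)
    io.write_expression(mrna, outdir / "mrna.tsv")
    io.write_expression(lncrna, outdir / "lncrna.tsv")
    io.write_expression(mirna, outdir / "mirna.tsv")
    return {
        "n_samples": matrix.n_samples,
        "n_mrna": mrna.n_genes,
        "n_lncrna": lncrna.n_genes,
        "n_mirna": mirna.n_genes,
    }


def stage_correlate(mrna_tsv, lncrna_tsv, out_tsv, min_pairs: int = 30) -> dict:
    """mRNA x lncRNA Pearson matrix, written wide (NA = undefined)."""
    mrna = io.read_expression(mrna_tsv)
    lncrna = io.read_expression(lncrna_tsv)
    corr = correlation.pearson_matrix(mrna, lncrna, min_pairs=min_pairs, compute_p=False)
    frame = corr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(out_tsv, sep="\t", na_rep="NA")
    defined = corr.defined_values()
    return {"n_cells": int(corr.r.size), "n_defined": int(defined.size)}


def _read_corr_matrix(path) -> correlation.CorrelationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    r = frame.to_numpy(dtype=float)
    n_used = np.zeros_like(r, dtype=int)
    return correlation.CorrelationMatrix(
        list(frame.index), list(frame.columns), r, None, n_used
    )


def stage_select_pairs(
    corr_tsv, out_pairs, out_meta, percentile: float = 99.0, tail: str = "positive"
) -> dict:
    corr = _read_corr_matrix(corr_tsv)
    pairs = correlation.select_top_pairs(corr, percentile=percentile, tail=tail)
    pairs.frame.to_csv(out_pairs, sep="\t", index=False)
    meta = {
        "threshold_r": pairs.threshold_r,
        "percentile": pairs.percentile,
        "tail": pairs.tail,
        "n_pairs": len(pairs),
    }
    Path(out_meta).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta


def _read_pairs(path) -> correlation.PairSet:
    frame = pd.read_csv(path, sep="\t", dtype={"mrna": str, "lncrna": str})
    return correlation.PairSet(frame, float(frame["r"].min()), float("nan"))


def stage_sensitivity(
    pairs_tsv,
    mrna_tsv,
    lncrna_tsv,
    mirna_tsv,
    out_triplets,
    out_heatmap,
    out_meta,
    mode: str = "fixed",
    s_threshold: float = 0.3,
    s_percentile: float = 99.0,
    min_pairs: int = 30,
) -> dict:
    pairs = _read_pairs(pairs_tsv)
    mrna = io.read_expression(mrna_tsv)
    lncrna = io.read_expression(lncrna_tsv)
    mirna = io.read_expression(mirna_tsv)
    scan = sens.scan_triplets(pairs, mrna, lncrna, mirna, min_pairs=min_pairs)
    selection = sens.select_triplets(
        scan, mode=mode, s_threshold=s_threshold, percentile=s_percentile
    )
    selection.frame.to_csv(out_triplets, sep="\t", index=False, na_rep="NA")
    heatmap = scan.to_heatmap()
    heatmap.index.name = "pair"
    heatmap.to_csv(out_heatmap, sep="\t", na_rep="NA")
    meta = {
        "mode": selection.mode,
        "realized_s_cutoff": selection.cutoff,
        "n_triplets_scanned": scan.n_triplets,
        "n_triplets_selected": len(selection),
    }
    Path(out_meta).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta


def stage_seed_scan(
    mirna_fasta, utr_fasta, lnc_fasta, out_seeds, out_index
) -> dict:
    mature = io.read_fasta(mirna_fasta, "mature_mirna")
    utrs = io.read_fasta(utr_fasta, "utr3")
    lncs = io.read_fasta(lnc_fasta, "lnc_transcript")
    seeds = seedmatch.seeds_from_sequences(mature)
    pd.DataFrame(
        [(s.mirna_id, s.mature_seq, s.seed, s.site) for s in seeds],
        columns=["mirna", "mature_seq", "seed", "site"],
    ).to_csv(out_seeds, sep="\t", index=False)
    index = seedmatch.build_seed_index(seeds, utrs, lncs)
    # positions are 1-based inclusive start coordinates on the given transcript
    index.to_frame().to_csv(out_index, sep="\t", index=False)
    roles = {tid: "utr3" for tid in utrs.records}
    roles.update({tid: "lnc_transcript" for tid in lncs.records})
    Path(str(out_index) + ".roles.json").write_text(json.dumps(roles, sort_keys=True))
    return {"n_seeds": len(seeds), "n_site_rows": len(index.to_frame())}


def _read_index(index_tsv) -> seedmatch.SeedIndex:
    frame = pd.read_csv(
        index_tsv, sep="\t", dtype={"transcript_id": str, "role": str, "mirna": str}
    )
    roles_path = Path(str(index_tsv) + ".roles.json")
    roles = json.loads(roles_path.read_text()) if roles_path.exists() else None
    return seedmatch.SeedIndex.from_frame(frame, roles)


def stage_enrich(
    triplets_tsv, pairs_tsv, index_tsv, out_tsv, alpha: float = 0.01
) -> dict:
    selection = pd.read_csv(triplets_tsv, sep="\t", dtype=str)
    pairs = _read_pairs(pairs_tsv)
    index = _read_index(index_tsv)
    table = seedmatch.enrichment_table(selection, pairs.pairs(), index)
    table.to_csv(out_tsv, sep="\t", index=False, na_rep="NA")
    n_sig = int((table["p_raw"] < alpha).sum())
    return {"n_mirnas_tested": len(table), "n_significant_raw": n_sig, "alpha": alpha}


def stage_network(
    triplets_tsv, index_tsv, pairs_tsv, outdir: Path, seeds_tsv=None
) -> dict:
    selection = pd.read_csv(triplets_tsv, sep="\t", na_values=["NA"])
    index = _read_index(index_tsv)
    net = network.build_mmi_network(selection, index)
    network.write_edge_list(net, outdir / "mmi_edges.tsv")
    network.write_gml(net, outdir / "mmi_network.gml")
    network.collapse_weights(net).to_csv(outdir / "mmi_weights.tsv", sep="\t", index=False)
    pairs = _read_pairs(pairs_tsv)
    corr_net = network.build_correlation_network(pairs)
    pd.DataFrame(
        sorted((u, v) for u, v in corr_net.edges()), columns=["node1", "node2"]
    ).to_csv(outdir / "correlation_edges.tsv", sep="\t", index=False)
    return {
        "n_nodes": net.n_nodes,
        "n_lncrna_nodes": len(net.lncrnas),
        "n_mrna_nodes": len(net.mrnas),
        "n_edges": net.n_edges,
        "n_correlation_edges": corr_net.number_of_edges(),
    }


def _read_network(edges_tsv) -> network.MMINetwork:
    frame = pd.read_csv(edges_tsv, sep="\t", dtype=str)
    frame = frame.rename(
        columns={"node1": "lncrna", "node2": "mrna", "interaction": "mirna"}
    )
    return network.build_mmi_network(frame)


def stage_net_stats(edges_tsv, out_components, out_hubs, seeds_tsv=None) -> dict:
    net = _read_network(edges_tsv)
    comps = network.connected_components(net)
    network.components_frame(comps).to_csv(out_components, sep="\t", index=False)
    families = None
    if seeds_tsv is not None:
        seed_table = pd.read_csv(seeds_tsv, sep="\t", dtype=str)
        families = dict(zip(seed_table["mirna"], seed_table["seed"]))
    network.rank_hubs(net, families=families).to_csv(out_hubs, sep="\t", index=False)
    return {"n_components": len(comps)}


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in {
                "expression": cfg.expression,
                "annotation": cfg.annotation,
                "mirna_fasta": cfg.mirna_fasta,
                "utr_fasta": cfg.utr_fasta,
                "lnc_fasta": cfg.lnc_fasta,
            }.items()
        },
        "stages": {},
        "complete": False,
    }
    stages = [
        ("filter", lambda: stage_filter(cfg, outdir)),
        (
            "correlate",
            lambda: stage_correlate(
                outdir / "mrna.tsv",
                outdir / "lncrna.tsv",
                outdir / "mrna_lncrna_corr.tsv",
                cfg.min_pairs,
            ),
        ),
        (
            "select-pairs",
            lambda: stage_select_pairs(
                outdir / "mrna_lncrna_corr.tsv",
                outdir / "pairs.tsv",
                outdir / "pairs_meta.json",
                cfg.pair_percentile,
                cfg.pair_tail,
            ),
        ),
        (
            "sensitivity",
            lambda: stage_sensitivity(
                outdir / "pairs.tsv",
                outdir / "mrna.tsv",
                outdir / "lncrna.tsv",
                outdir / "mirna.tsv",
                outdir / "triplets_selected.tsv",
                outdir / "s_heatmap.tsv",
                outdir / "triplets_meta.json",
                cfg.s_mode,
                cfg.s_threshold,
                cfg.s_percentile,
                cfg.min_pairs,
            ),
        ),
        (
            "seed-scan",
            lambda: stage_seed_scan(
                cfg.mirna_fasta,
                cfg.utr_fasta,
                cfg.lnc_fasta,
                outdir / "seeds.tsv",
                outdir / "site_index.tsv",
            ),
        ),
        (
            "enrich",
            lambda: stage_enrich(
                outdir / "triplets_selected.tsv",
                outdir / "pairs.tsv",
                outdir / "site_index.tsv",
                outdir / "enrichment.tsv",
                cfg.enrichment_alpha,
            ),
        ),
        (
            "build-network",
            lambda: stage_network(
                outdir / "triplets_selected.tsv",
                outdir / "site_index.tsv",
                outdir / "pairs.tsv",
                outdir,
            ),
        ),
        (
            "net-stats",
            lambda: stage_net_stats(
                outdir / "mmi_edges.tsv",
                outdir / "components.tsv",
                outdir / "hubs.tsv",
                outdir / "seeds.tsv",
            ),
        ),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        manifest["stages"][name]["seconds"] = round(elapsed, 3)
        logger.info("stage %s done in %.2fs", name, elapsed)
    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
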