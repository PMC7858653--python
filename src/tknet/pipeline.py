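"""One-command pipeline: preprocess -> correlate -> network -> topology -> null.

A :class:`PipelineConfig` carries every stage parameter (defaults are the
published analysis settings), serializes to/from YAML, and hashes to a
config fingerprint stamped into every output file so that outputs from
different runs cannot be silently mixed.  All randomness flows from one
top-level seed expanded into per-stage seeds recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, io, netbuild, nullmodel, preprocess

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults match the published analysis: 99.5% cumulative-abundance
    cutoff, log2(x+1), per-group Spearman with the p < 0.6 microbe-host
    prefilter, BH FDR tiers 0.05 / 0.15 / 0.10, and a 10,000-graph
    G(n, m) null ensemble.
    """

    cumulative_threshold: float = 0.995
    pseudocount: float = 1.0
    cohort_stat: str = "mean"           # 'mean' or 'median'
    quantile_normalize_host: bool = False
    p_prefilter: float = 0.6
    rescue_edges: list = field(default_factory=list)
    fdr_microbe_microbe: float = 0.05
    fdr_microbe_host: float = 0.15
    fdr_host_host: float = 0.10
    fdr_method: str = "fdr_bh"          # or 'fdr_by'
    use_causality_filter: bool = True
    n_null_networks: int = 10_000
    null_mode: str = "all-nodes"        # or 'top-node'
    top_k: int = 3
    seed: int = 0

    def fdr_thresholds(self) -> dict:
        return {
            "microbe-microbe": self.fdr_microbe_microbe,
            "microbe-host": self.fdr_microbe_host,
            "host-host": self.fdr_host_host,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds (< 2^31) derived from the top seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(2)
        return {
            "null": int(children[0].generate_state(1, dtype=np.uint32)[0] % (2**31)),
            "reserved": int(children[1].generate_state(1, dtype=np.uint32)[0] % (2**31)),
        }


@dataclass
class PipelineResult:
    features: preprocess.FeatureTable
    fc_scale: pd.DataFrame
    fold_changes: pd.DataFrame
    edges: pd.DataFrame
    network: object
    scores: pd.DataFrame
    top_candidates: dict
    null_summary: object | None
    report: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def analyze(
    counts: preprocess.AsvCountTable,
    host: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    run_null: bool = True,
) -> PipelineResult:
    """In-memory pipeline on already-loaded tables (no file output)."""
    config = config or PipelineConfig()
    preprocess.validate_metadata(metadata, counts.sample_ids)
    preprocess.validate_metadata(metadata, host.index)

    # --- preprocessing ---------------------------------------------------
    microbes = preprocess.preprocess_microbes(
        counts, metadata, config.cumulative_threshold, config.pseudocount)
    if config.quantile_normalize_host:
        host = preprocess.quantile_normalize(host, metadata)
    host_z, host_stage1, _ = preprocess.normalize_host_by_cohort(
        host, metadata, stat=config.cohort_stat)
    host_table = preprocess.FeatureTable(
        host_z, pd.Series("host", index=host_z.columns),
        {"cohort_normalized": True, "cross_study_standardized": True})
    features = preprocess.FeatureTable.concat(microbes, host_table)

    # fold-change scale: back-transformed microbe abundances, stage-1 hosts
    microbes_bt = (2.0 ** microbes.values) - config.pseudocount
    fc_scale = pd.concat([microbes_bt, host_stage1], axis=1)
    fold_changes = assoc.compute_fold_changes(fc_scale, metadata)

    # --- edge inference ---------------------------------------------------
    partition = assoc.make_group_partition(metadata, features.values.index)
    edges = assoc.build_edge_table(
        features, partition, fold_changes,
        p_prefilter=config.p_prefilter,
        rescue=config.rescue_edges,
        fdr_thresholds=config.fdr_thresholds(),
        fdr_method=config.fdr_method,
        use_causality_filter=config.use_causality_filter,
    )
    stage_counts = assoc.filter_stage_counts(edges)

    # --- network & topology ----------------------------------------------
    abundance = microbes_bt.mean(axis=0)
    network = netbuild.build_network(
        edges[edges["kept"]], fold_changes, abundance, features.kinds)

    report: dict = {"filter_stage_counts": stage_counts,
                    "n_nodes": network.number_of_nodes(),
                    "n_edges": network.number_of_edges()}
    scores = pd.DataFrame(columns=["node_type", "degree", "bibc_raw", "bibc_normalized"])
    top: dict = {}
    null_summary = None
    microbe_nodes = [v for v, d in network.nodes(data=True) if d.get("node_type") == "microbe"]
    host_nodes = [v for v, d in network.nodes(data=True) if d.get("node_type") == "host"]
    if microbe_nodes and host_nodes:
        scores = netbuild.topology_scores(network)
        top = netbuild.rank_candidates(scores, top_k=config.top_k)
        report["top_candidates"] = top
        if run_null:
            seeds = config.stage_seeds()
            null_summary = nullmodel.build_null_ensemble(
                n=network.number_of_nodes(), m=network.number_of_edges(),
                n_a=len(microbe_nodes), n_b=len(host_nodes),
                n_networks=config.n_null_networks, seed=seeds["null"],
                mode=config.null_mode)
            tails = {}
            for node_type, nodes in top.items():
                for v in nodes:
                    tails[v] = nullmodel.tail_probability(
                        null_summary, scores.loc[v, "degree"],
                        scores.loc[v, "bibc_normalized"])
            report["tail_probabilities"] = tails

    report["positive_edges"] = int((edges["kept"] & (edges["average_rho"] > 0)).sum())
    report["negative_edges"] = int((edges["kept"] & (edges["average_rho"] < 0)).sum())
    return PipelineResult(features, fc_scale, fold_changes, edges, network,
                          scores, top, null_summary, report)


def run_pipeline(
    config: PipelineConfig,
    counts_path,
    host_path,
    metadata_path,
    taxonomy_path,
    out_dir,
) -> Path:
    """File-to-file pipeline run; returns the run directory.

    Writes features.tsv, edges.tsv, network.graphml, nodes.tsv,
    network_edges.tsv, scores.tsv, null_summary.json, report.json and a
    manifest.json with the config hash, input checksums and stage seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    metadata = io.read_metadata(metadata_path)
    counts = io.read_counts(counts_path, taxonomy_path, metadata=metadata)
    host = io.read_host(host_path)

    result = analyze(counts, host, metadata, config, run_null=True)

    io.write_feature_table(result.features, out_dir / "features.tsv", chash)
    io.write_edges(result.edges, out_dir / "edges.tsv", chash)
    io.write_graphml(result.network, out_dir / "network.graphml")
    if not result.scores.empty:
        result.scores.to_csv(out_dir / "scores.tsv", sep="\t", index_label="node")
        io.write_network_tables(result.network, result.scores, out_dir)

    if result.null_summary is not None:
        ns = result.null_summary
        null_json = {
            "n_networks": ns.n_networks, "n": ns.n, "m": ns.m,
            "n_a": ns.n_a, "n_b": ns.n_b, "seed": ns.seed, "mode": ns.mode,
            "pooled_mean_degree": float(ns.degrees.mean()),
            "tail_probabilities": result.report.get("tail_probabilities", {}),
            "config_hash": chash,
        }
        (out_dir / "null_summary.json").write_text(json.dumps(null_json, indent=2))
        grid = pd.DataFrame(ns.density,
                            index=0.5 * (ns.degree_edges[:-1] + ns.degree_edges[1:]),
                            columns=0.5 * (ns.bibc_edges[:-1] + ns.bibc_edges[1:]))
        grid.to_csv(out_dir / "null_density.tsv", sep="\t", index_label="degree")

    manifest = {
        "config": asdict(config),
        "config_hash": chash,
        "stage_seeds": config.stage_seeds(),
        "inputs": {
            "counts": _sha256(counts_path),
            "host": _sha256(host_path),
            "metadata": _sha256(metadata_path),
            "taxonomy": _sha256(taxonomy_path),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    config.to_yaml(out_dir / "config.yaml")
    return out_dir
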