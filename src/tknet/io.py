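"""Readers and writers for the pipeline's plain-text formats.

Counts are TSV with ASVs as rows and samples as columns (the common
amplicon export layout); orientation is auto-detected against the metadata
sample ids and can be overridden.  Host tables and metadata are CSV.
Networks are written as GraphML (Cytoscape-importable) plus flat
nodes/edges TSV files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import AsvCountTable, FeatureTable, validate_metadata

__all__ = [
    "read_counts",
    "read_taxonomy",
    "read_host",
    "read_metadata",
    "read_truth",
    "write_edges",
    "read_edges",
    "write_feature_table",
    "read_feature_table",
    "write_graphml",
    "write_network_tables",
]


def read_counts(
    path,
    taxonomy_path=None,
    metadata: pd.DataFrame | None = None,
    orientation: str = "auto",
) -> AsvCountTable:
    """Read a TSV count table into samples x ASVs form.

    ``orientation`` is 'features-rows' (default layout), 'samples-rows', or
    'auto' (match row/column labels against metadata sample ids).  Counts
    must be integers; a float entry is a hard error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "auto":
        if metadata is not None:
            in_cols = raw.columns.isin(metadata.index).mean()
            in_rows = raw.index.isin(metadata.index).mean()
            orientation = "samples-rows" if in_rows > in_cols else "features-rows"
        else:
            orientation = "features-rows"
    if orientation == "features-rows":
        raw = raw.T
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    bad = [c for c in raw.columns if not np.issubdtype(raw[c].dtype, np.integer)]
    if bad:
        raise ValueError(
            f"count table {path} has non-integer entries in column(s) {bad[:5]}")
    as_int = raw.astype(np.int64)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return AsvCountTable(as_int, taxonomy)


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"taxonomy file {path} needs an id column and a lineage column")
    return df.iloc[:, 0].astype(str)


def read_host(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in host table {path}")
    return df.astype(float)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype=str)
    validate_metadata(df)
    return df


def read_truth(path):
    from .synthetic import GroundTruth
    return GroundTruth.from_json(Path(path).read_text())


def write_edges(edges: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Audit-complete edge table (kept and removed rows) as TSV."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        edges.to_csv(fh, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_feature_table(table: FeatureTable, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        for key, val in table.provenance.items():
            fh.write(f"# provenance {key}: {val}\n")
        fh.write("# kinds: " + ",".join(f"{c}={table.kinds[c]}"
                                        for c in table.values.columns) + "\n")
        table.values.to_csv(fh, sep="\t", index_label="sample_id")


def read_feature_table(path) -> FeatureTable:
    kinds_line = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# kinds:"):
                kinds_line = line[len("# kinds:"):].strip()
            if not line.startswith("#"):
                break
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if kinds_line:
        pairs = dict(item.split("=") for item in kinds_line.split(","))
        kinds = pd.Series(pairs).reindex(values.columns)
    else:
        kinds = pd.Series("microbe", index=values.columns)
    return FeatureTable(values, kinds)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_network_tables(network: nx.Graph, scores: pd.DataFrame, out_dir) -> None:
    """Flat nodes.tsv / edges.tsv views of the network with topology scores."""
    out_dir = Path(out_dir)
    nodes = scores.copy()
    for attr in ("fold_change", "abundance"):
        nodes[attr] = [network.nodes[v].get(attr, np.nan) for v in nodes.index]
    nodes.to_csv(out_dir / "nodes.tsv", sep="\t", index_label="node")
    rows = [
        {"node_a": a, "node_b": b, **d} for a, b, d in network.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(out_dir / "network_edges.tsv", sep="\t", index=False)
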