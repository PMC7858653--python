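"""Transkingdom network assembly, degree, and bipartite betweenness
centrality (BiBC).

BiBC of a node v, for two disjoint node sets A and B, is

    BiBC(v) = sum over pairs (s in A, t in B), s != v != t, of
              sigma_st(v) / sigma_st

where sigma_st counts shortest s-t paths and sigma_st(v) those passing
through v.  Each unordered A-B pair is counted once, endpoints receive no
credit for their own pair, and disconnected pairs contribute zero.  Edges
are unweighted for path purposes: the correlation magnitude is an edge
attribute, not a distance.  The normalized score divides by |A| x |B|, the
number of pairs, so it lies in [0, 1].

The implementation is a single-pass Brandes-style dependency accumulation
run from each source in A with targets restricted to B, which is exact and
O(|A| (n + m)) on unweighted graphs.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "degree",
    "bibc",
    "normalize_bibc",
    "topology_scores",
    "rank_candidates",
]


def build_network(
    kept_edges: pd.DataFrame,
    fold_changes: pd.DataFrame,
    abundance: pd.Series | None = None,
    kinds: pd.Series | None = None,
) -> nx.Graph:
    """Assemble kept edges into an undirected simple graph.

    Nodes are exactly the endpoints of kept edges (isolated features never
    become nodes) and carry their type, average median fold change, and —
    for microbes — average relative abundance.  Edges carry the average of
    the per-group Spearman correlations and its sign.
    """
    G = nx.Graph()
    kept = kept_edges[kept_edges["kept"]] if "kept" in kept_edges else kept_edges
    for row in kept.itertuples(index=False):
        a, b = row.node_a, row.node_b
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        G.add_edge(a, b, average_rho=float(row.average_rho),
                   sign=int(np.sign(row.average_rho)))
    for v in G.nodes:
        if v not in fold_changes.index:
            raise ValueError(f"node {v!r} has no fold-change record")
        G.nodes[v]["fold_change"] = float(
            fold_changes.loc[v, "average_median_fold_change"])
        if kinds is not None:
            G.nodes[v]["node_type"] = str(kinds[v])
        if abundance is not None and v in abundance.index:
            G.nodes[v]["abundance"] = float(abundance[v])
    return G


def degree(network: nx.Graph) -> dict:
    """Incident-edge count per node."""
    return dict(network.degree())


def bibc(network: nx.Graph, set_a, set_b, allow_overlap: bool = False) -> dict:
    """Raw bipartite betweenness centrality for every node of the graph.

    ``set_a`` and ``set_b`` must be disjoint subsets of the node set unless
    ``allow_overlap`` is given, in which case each unordered pair is still
    counted exactly once (with A = B = all nodes this reproduces classical
    unnormalized betweenness).
    """
    A = [v for v in set_a if v in network]
    Bset = {v for v in set_b if v in network}
    if not allow_overlap and set(A) & Bset:
        raise ValueError("node groups must be disjoint")
    Aset = set(A)

    adj = {v: list(network.adj[v]) for v in network}
    score = dict.fromkeys(network, 0.0)

    for s in A:
        # BFS shortest-path counts
        sigma = {s: 1.0}
        dist = {s: 0}
        preds: dict = {s: []}
        order = [s]
        queue = deque([s])
        while queue:
            v = queue.popleft()
            dv = dist[v]
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    order.append(w)
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation restricted to targets in B; a pair seen
        # from both sides (overlap mode) is weighted 1/2 each time
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            if w in Bset and w is not s:
                weight = 0.5 if (s in Bset and w in Aset) else 1.0
                coeff = delta[w] + weight
            else:
                coeff = delta[w]
            sw = sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] / sw * coeff
        for w in order:
            if w is not s:
                score[w] += delta[w]
    return score


def normalize_bibc(scores: dict, n_a: int, n_b: int) -> dict:
    """Divide raw BiBC by |A| x |B| (the pair count); result in [0, 1]."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both node groups must be non-empty")
    denom = float(n_a) * float(n_b)
    return {v: s / denom for v, s in scores.items()}


def topology_scores(
    network: nx.Graph,
    set_a=None,
    set_b=None,
    type_attr: str = "node_type",
    type_a: str = "microbe",
    type_b: str = "host",
) -> pd.DataFrame:
    """Degree, raw BiBC and normalized BiBC per node.

    By default the two groups are read off the ``node_type`` attribute
    (microbes vs host parameters); explicit node sets override this.
    """
    if set_a is None or set_b is None:
        set_a = [v for v, d in network.nodes(data=True) if d.get(type_attr) == type_a]
        set_b = [v for v, d in network.nodes(data=True) if d.get(type_attr) == type_b]
    if not set_a or not set_b:
        raise ValueError("both node groups must be non-empty")
    raw = bibc(network, set_a, set_b)
    norm = normalize_bibc(raw, len(set_a), len(set_b))
    deg = degree(network)
    df = pd.DataFrame({
        "node": list(network.nodes),
        "node_type": [network.nodes[v].get(type_attr, "") for v in network.nodes],
        "degree": [deg[v] for v in network.nodes],
        "bibc_raw": [raw[v] for v in network.nodes],
        "bibc_normalized": [norm[v] for v in network.nodes],
    })
    return df.set_index("node")


def rank_candidates(scores: pd.DataFrame, top_k: int = 3) -> dict[str, list[str]]:
    """Top-k bottleneck candidates per node type.

    Deterministic order: normalized BiBC descending, then degree
    descending, then node id ascending.
    """
    table = scores.reset_index() if "node" not in scores.columns else scores
    ranked = table.sort_values(by=["bibc_normalized", "degree", "node"],
                               ascending=[False, False, True])
    out: dict[str, list[str]] = {}
    for node_type, sub in ranked.groupby("node_type", sort=True):
        out[str(node_type)] = list(sub["node"].head(top_k))
    return out
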