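"""Erdős–Rényi G(n, m) null calibration of (degree, BiBC) scores.

An ensemble of random graphs matched to the observed network's node and
edge counts is sampled; each graph's nodes are split into a uniformly
random disjoint partition with the observed group sizes, and every node's
degree and normalized BiBC are pooled.  The pooled sample yields a 2D
probability-density histogram and an empirical upper-tail probability: the
chance of a random-network node having at least the queried degree AND at
least the queried BiBC.  A query beyond every pooled sample is reported by
the convention "< 1 / pool size".

The study this pipeline reproduces calibrated its headline network with
10,000 graphs at n = 109 nodes and m = 221 edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "sample_gnm",
    "NullEnsembleSummary",
    "build_null_ensemble",
    "tail_probability",
    "plot_density",
]

from .netbuild import bibc

N_BIBC_BINS = 50


def sample_gnm(n: int, m: int, seed) -> nx.Graph:
    """Uniform simple graph with exactly n nodes and m edges.

    ``seed`` may be an int or a numpy Generator; sampling is deterministic
    given the seed.
    """
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"m must be in [0, {max_m}] for n={n}, got {m}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    G = nx.gnm_random_graph(n, m, seed=rng)
    assert G.number_of_edges() == m
    return G


@dataclass
class NullEnsembleSummary:
    """Pooled (degree, normalized BiBC) node samples from a G(n, m) ensemble."""

    n_networks: int
    n: int
    m: int
    n_a: int
    n_b: int
    degrees: np.ndarray          # pooled, one entry per node per network
    bibc_norm: np.ndarray        # pooled, aligned with degrees
    edge_counts: np.ndarray      # per-network edge counts (all equal m)
    density: np.ndarray          # 2D probability density over (degree, bibc)
    degree_edges: np.ndarray
    bibc_edges: np.ndarray
    seed: int
    mode: str = "all-nodes"

    @property
    def pool_size(self) -> int:
        return self.degrees.size


def _degrees_and_bibc(G: nx.Graph, rng: np.random.Generator,
                      n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.array(list(G.nodes))
    perm = rng.permutation(nodes.size)
    set_a = nodes[perm[:n_a]].tolist()
    set_b = nodes[perm[n_a:n_a + n_b]].tolist()
    raw = bibc(G, set_a, set_b)
    denom = float(n_a) * float(n_b)
    deg = dict(G.degree())
    d = np.array([deg[v] for v in nodes], dtype=float)
    b = np.array([raw[v] / denom for v in nodes], dtype=float)
    return d, b


def build_null_ensemble(
    n: int,
    m: int,
    n_a: int,
    n_b: int,
    n_networks: int = 10_000,
    seed: int = 0,
    mode: str = "all-nodes",
) -> NullEnsembleSummary:
    """Sample the G(n, m) ensemble and pool (degree, normalized BiBC).

    Each sampled graph gets a fresh uniformly random disjoint partition of
    sizes (n_a, n_b) — the real bipartition has no meaning on an unlabeled
    random graph.  ``mode='all-nodes'`` pools every node of every network;
    ``mode='top-node'`` pools only each network's most extreme node
    (highest BiBC, ties broken by degree).
    """
    if n_a + n_b != n:
        raise ValueError(f"partition sizes must sum to n: {n_a}+{n_b} != {n}")
    if mode not in ("all-nodes", "top-node"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    all_d, all_b, edge_counts = [], [], np.empty(n_networks, dtype=int)
    for k in range(n_networks):
        G = sample_gnm(n, m, rng)
        edge_counts[k] = G.number_of_edges()
        d, b = _degrees_and_bibc(G, rng, n_a, n_b)
        if mode == "top-node":
            i = np.lexsort((d, b))[-1]
            d, b = d[i:i + 1], b[i:i + 1]
        all_d.append(d)
        all_b.append(b)

    degrees = np.concatenate(all_d)
    bibc_norm = np.concatenate(all_b)

    # degree binned at integers; BiBC in equal-width bins over the pooled range
    deg_edges = np.arange(-0.5, degrees.max() + 1.5)
    b_max = bibc_norm.max()
    bibc_edges = np.linspace(0.0, b_max * 1.05 if b_max > 0 else 1e-6, N_BIBC_BINS + 1)
    density, _, _ = np.histogram2d(degrees, bibc_norm,
                                   bins=[deg_edges, bibc_edges], density=True)

    return NullEnsembleSummary(
        n_networks=n_networks, n=n, m=m, n_a=n_a, n_b=n_b,
        degrees=degrees, bibc_norm=bibc_norm, edge_counts=edge_counts,
        density=density, degree_edges=deg_edges, bibc_edges=bibc_edges,
        seed=seed, mode=mode,
    )


def tail_probability(summary: NullEnsembleSummary, degree: float, bibc_value: float) -> float:
    """Empirical P(random node has degree >= d AND BiBC >= b).

    When no pooled sample reaches the query, the result is reported as
    1 / pool size, to be read as an upper bound ("< 1/pool size").
    """
    count = int(np.sum((summary.degrees >= degree) & (summary.bibc_norm >= bibc_value)))
    if count == 0:
        return 1.0 / summary.pool_size
    return count / summary.pool_size


def plot_density(summary: NullEnsembleSummary, path, observed=None) -> None:
    """Contour plot of the null (degree, BiBC) density; optional observed
    nodes overlaid as points.  ``observed`` is an iterable of
    (label, degree, bibc) triples."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xc = 0.5 * (summary.degree_edges[:-1] + summary.degree_edges[1:])
    yc = 0.5 * (summary.bibc_edges[:-1] + summary.bibc_edges[1:])
    fig, ax = plt.subplots(figsize=(6, 5))
    with np.errstate(divide="ignore"):
        z = np.log10(summary.density.T + 1e-12)
    cs = ax.contourf(xc, yc, z, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="log10 probability density")
    if observed is not None:
        for label, d, b in observed:
            ax.plot(d, b, "r*", markersize=10)
            ax.annotate(label, (d, b), fontsize=7)
    ax.set_xlabel("degree")
    ax.set_ylabel("normalized BiBC")
    ax.set_title(f"G(n={summary.n}, m={summary.m}) null, {summary.n_networks} networks")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
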