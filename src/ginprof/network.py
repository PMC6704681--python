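"""Thresholded similarity networks.

A similarity matrix becomes a sparse undirected graph by keeping only the
top-k heaviest gene pairs as edges (default k = 20,000 at screen scale).
Small disconnected fragments are then discarded in favour of the giant
connected component before module detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "GeneNetwork",
    "build_top_k_network",
    "giant_component",
    "network_summary",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph.

    ``threshold_weight`` is the weight of the rank-k edge retained by
    :func:`build_top_k_network` (``None`` for graphs built another way).
    Isolated nodes are never present: every node is incident to an edge.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    threshold_weight: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _pair_key(gene_a: str, gene_b: str) -> tuple[str, str]:
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


def build_top_k_network(s: SimilarityMatrix, k: int = 20000) -> GeneNetwork:
    """Retain the k highest-weight defined gene pairs as edges.

    Edges are ranked by weight descending; ties at the rank-k boundary are
    broken by ascending lexicographic gene-pair order, so the result is
    deterministic.  Nodes are exactly the endpoints of retained edges.
    """
    if k < 1:
        raise ValueError("k must be positive")
    n = len(s.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = s.defined[iu, ju]
    iu, ju = iu[mask], ju[mask]
    w = s.values[iu, ju]
    if w.size < k:
        raise ValueError(f"only {w.size} candidate edges available, need k={k}")
    cut = np.partition(w, w.size - k)[w.size - k]
    hi = np.where(w > cut)[0]
    eq = np.where(w == cut)[0]
    need = k - hi.size
    genes = s.gene_ids
    eq_sorted = sorted(eq, key=lambda t: _pair_key(genes[iu[t]], genes[ju[t]]))
    chosen = list(hi) + eq_sorted[:need]
    graph = nx.Graph()
    for t in chosen:
        a, b = _pair_key(genes[iu[t]], genes[ju[t]])
        graph.add_edge(a, b, weight=float(w[t]))
    return GeneNetwork(graph, threshold_weight=float(cut))


def giant_component(net: GeneNetwork) -> GeneNetwork:
    """Subgraph induced by the largest connected component.

    Ties on size are broken by the smallest lexicographic node label.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network has no giant component")
    comps = list(nx.connected_components(net.graph))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return GeneNetwork(net.graph.subgraph(best).copy(), net.threshold_weight)


def network_summary(net: GeneNetwork, giant: GeneNetwork) -> dict:
    """Node/edge counts for the full network and its giant component."""
    if not set(giant.graph.nodes) <= set(net.graph.nodes):
        raise ValueError("giant component is not a subgraph of the network")
    return {
        "nodes": net.n_nodes,
        "edges": net.n_edges,
        "nodes_giant": giant.n_nodes,
        "edges_giant": giant.n_edges,
        "threshold_weight": net.threshold_weight,
    }


def write_edge_list(net: GeneNetwork, path) -> None:
    """Tab-separated ``geneA geneB weight`` rows in lexicographic pair order."""
    edges = sorted(_pair_key(u, v) + (d["weight"],) for u, v, d in net.graph.edges(data=True))
    with open(path, "w") as handle:
        if net.threshold_weight is not None:
            handle.write(f"# threshold_weight={net.threshold_weight!r}\n")
        for a, b, w in edges:
            handle.write(f"{a}\t{b}\t{w!r}\n")


def read_edge_list(path) -> GeneNetwork:
    graph = nx.Graph()
    threshold = None
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "threshold_weight=" in line:
                    threshold = float(line.split("=", 1)[1])
                continue
            a, b, w = line.split("\t")
            graph.add_edge(a, b, weight=float(w))
    return GeneNetwork(graph, threshold)
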