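"""Module detection by recursive edge-betweenness removal (Girvan-Newman).

The algorithm repeatedly deletes the edge carried by the most shortest
paths, fragmenting the network; every connected component whose size falls
in a target window (default 5-50 genes, the plausible size range of a
functional module) at any step is recorded.  The deduplicated union of the
recorded components is the *clustering solution*; because components are
recorded while they shrink, modules may be nested.

Betweenness uses Brandes-style shortest-path counting with fractional
splitting among tied shortest paths (delegated to igraph's C routine; the
test suite checks it against exhaustive path enumeration).  The graph is
treated as unweighted by default - after top-k thresholding the weights
are similarities, whose inversion into path lengths is a separate modelling
choice exposed via ``weighted=True`` (edge length = 1/weight).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import igraph as ig
import networkx as nx

from .network import GeneNetwork

__all__ = [
    "ClusteringSolution",
    "edge_betweenness",
    "girvan_newman_clustering",
    "write_clustering",
    "read_clustering",
]


@dataclass
class ClusteringSolution:
    """Deduplicated set of modules over a gene universe.

    Modules are frozen gene sets with sizes inside ``[min_size, max_size]``;
    nesting and overlap between modules are allowed.
    """

    modules: frozenset
    universe: frozenset
    min_size: int
    max_size: int

    def __post_init__(self) -> None:
        self.modules = frozenset(frozenset(m) for m in self.modules)
        self.universe = frozenset(self.universe)
        for m in self.modules:
            if not self.min_size <= len(m) <= self.max_size:
                raise ValueError(f"module of size {len(m)} outside [{self.min_size}, {self.max_size}]")
            if not m <= self.universe:
                raise ValueError("module contains genes outside the universe")

    def genes(self) -> frozenset:
        """Distinct genes appearing in at least one module."""
        out: set = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def _to_igraph(graph: nx.Graph) -> ig.Graph:
    names = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(names)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    g = ig.Graph(n=len(names), edges=edges)
    g.vs["name"] = names
    g.es["weight"] = [graph.edges[u, v].get("weight", 1.0) for u, v in graph.edges]
    return g


def _edge_key(g: ig.Graph, edge: ig.Edge) -> tuple[str, str]:
    a = g.vs[edge.source]["name"]
    b = g.vs[edge.target]["name"]
    return (a, b) if a <= b else (b, a)


def _betweenness(g: ig.Graph, weighted: bool) -> list[float]:
    weights = [1.0 / w for w in g.es["weight"]] if weighted else None
    return g.edge_betweenness(weights=weights)


def edge_betweenness(net: GeneNetwork, weighted: bool = False) -> dict:
    """Betweenness score of every edge, keyed by sorted gene pair.

    The score of an edge is the number of shortest paths between unordered
    node pairs that traverse it, with pairs connected by several equally
    short paths contributing fractionally to each.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    g = _to_igraph(net.graph)
    scores = _betweenness(g, weighted)
    return {_edge_key(g, e): float(scores[e.index]) for e in g.es}


def _max_betweenness_edge(g: ig.Graph, weighted: bool) -> int:
    scores = _betweenness(g, weighted)
    best = max(scores)
    tied = [i for i, s in enumerate(scores) if s == best]
    return min(tied, key=lambda i: _edge_key(g, g.es[i]))


def girvan_newman_clustering(
    net: GeneNetwork,
    min_size: int = 5,
    max_size: int = 50,
    weighted: bool = False,
) -> ClusteringSolution:
    """Record every 5-50-gene component seen during recursive edge removal.

    The initial components count as a recording step.  At each step the
    highest-betweenness edge is removed (ties broken by lexicographic edge
    order); components that fall below ``min_size`` can never re-enter the
    window and are pruned from further processing, which leaves the output
    unchanged but avoids fragmenting them edge by edge.  Components are
    processed independently, which is equivalent to the single global
    removal sequence: deleting an edge never alters betweenness outside its
    own component, and recorded components are deduplicated.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if min_size < 1 or max_size < min_size:
        raise ValueError("invalid module size window")
    full = _to_igraph(net.graph)
    modules: set = set()
    stack = [full.subgraph(c) for c in full.connected_components()]
    while stack:
        g = stack.pop()
        n = g.vcount()
        if n < min_size:
            continue
        if n <= max_size:
            modules.add(frozenset(g.vs["name"]))
        if g.ecount() == 0:
            continue
        # remove edges until this component splits, then recurse on parts
        while True:
            g.delete_edges(_max_betweenness_edge(g, weighted))
            comps = g.connected_components()
            if len(comps) > 1:
                stack.extend(comps.subgraphs())
                break
            if g.ecount() == 0:
                break
    return ClusteringSolution(
        frozenset(modules), frozenset(net.graph.nodes), min_size, max_size
    )


def module_id(module) -> str:
    """Stable identifier for a module: hash of its sorted member list."""
    text = "|".join(sorted(module))
    return hashlib.sha1(text.encode()).hexdigest()[:10]


def write_clustering(solution: ClusteringSolution, path) -> None:
    """Write ``module_id <TAB> gene`` membership rows (deterministic order)."""
    ordered = sorted(solution.modules, key=lambda m: (sorted(m), len(m)))
    with open(path, "w") as handle:
        for m in ordered:
            mid = module_id(m)
            for gene in sorted(m):
                handle.write(f"{mid}\t{gene}\n")


def read_clustering(path, universe=None, min_size: int = 1, max_size: int | None = None) -> ClusteringSolution:
    """Read a membership table back into a :class:`ClusteringSolution`.

    The size window defaults to whatever the file contains; pass explicit
    bounds to enforce one.
    """
    groups: dict = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            mid, gene = line.split("\t")
            groups.setdefault(mid, set()).add(gene)
    modules = frozenset(frozenset(g) for g in groups.values())
    if max_size is None:
        max_size = max((len(m) for m in modules), default=1)
    if universe is None:
        universe = frozenset().union(*modules) if modules else frozenset()
    return ClusteringSolution(modules, frozenset(universe), min_size, max_size)
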