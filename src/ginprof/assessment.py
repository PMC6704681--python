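"""Comparing and evaluating clustering solutions.

Provides the Clustering Error index (optimal one-to-one module matching via
the Hungarian algorithm), the Biological Homogeneity Index against a flat
gene -> functional-term annotation table, hypergeometric (one-sided
Fisher's exact) enrichment of uncharacterized genes, shared-gene overlap
between solutions, and the 80/80-or-50 module-consistency rule against a
reference clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .community import ClusteringSolution

__all__ = [
    "read_annotations",
    "write_annotations",
    "confusion_matrix",
    "max_assignment",
    "clustering_error",
    "bhi_cluster",
    "bhi_solution",
    "hypergeom_upper_tail",
    "uncharacterized_enrichment",
    "shared_gene_overlap",
    "module_consistency",
    "module_type",
]


def read_annotations(path) -> dict:
    """Read a two-column ``gene <TAB> term`` table into a gene -> term-set map.

    Genes absent from the file are uncharacterized: look them up with
    ``ann.get(gene, set())``.
    """
    ann: dict = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            gene, term = line.split("\t")
            ann.setdefault(gene, set()).add(term)
    return ann


def write_annotations(ann: dict, path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                handle.write(f"{gene}\t{term}\n")


def _ordered_modules(solution: ClusteringSolution) -> list[frozenset]:
    return sorted(solution.modules, key=lambda m: (sorted(m), len(m)))


def confusion_matrix(a: ClusteringSolution, b: ClusteringSolution):
    """Shared-gene counts for every module pair.

    Returns ``(matrix, modules_a, modules_b)`` with modules in a
    deterministic order.
    """
    if not a.modules or not b.modules:
        raise ValueError("confusion matrix requires two non-empty solutions")
    mods_a = _ordered_modules(a)
    mods_b = _ordered_modules(b)
    m = np.zeros((len(mods_a), len(mods_b)), dtype=int)
    for i, sa in enumerate(mods_a):
        for j, sb in enumerate(mods_b):
            m[i, j] = len(sa & sb)
    return m, mods_a, mods_b


def max_assignment(m: np.ndarray) -> int:
    """Maximum total shared-gene count over one-to-one module matchings.

    Rectangular matrices are allowed; unmatched modules contribute zero.
    """
    m = np.asarray(m)
    if m.size == 0:
        raise ValueError("empty confusion matrix")
    rows, cols = linear_sum_assignment(m, maximize=True)
    return int(m[rows, cols].sum())


def clustering_error(a: ClusteringSolution, b: ClusteringSolution) -> float:
    """Clustering Error index ``(|U| - D) / |U|``.

    ``U`` is the set of distinct genes appearing in any module of either
    solution and ``D`` the optimal-assignment total of the confusion
    matrix; 0 means identical solutions, 1 no overlap under any matching.
    For solutions with overlapping or nested modules the matched total can
    exceed the distinct-gene count (a gene may be counted in several
    matched module pairs), so the index is floored at 0; for partitions the
    floor is never active.
    """
    universe = a.genes() | b.genes()
    if not universe:
        raise ValueError("both solutions cover no genes")
    m, _, _ = confusion_matrix(a, b)
    d = max_assignment(m)
    return max(0, len(universe) - d) / len(universe)


def bhi_cluster(cluster, ann: dict) -> float | None:
    """Biological Homogeneity Index of one cluster.

    The probability that two annotated genes of the cluster share at least
    one functional term; ``None`` (undefined) when fewer than two genes are
    annotated.
    """
    annotated = [g for g in cluster if ann.get(g)]
    n = len(annotated)
    if n < 2:
        return None
    linked = 0
    for i in range(n):
        terms_i = ann[annotated[i]]
        for j in range(i + 1, n):
            if terms_i & ann[annotated[j]]:
                linked += 1
    # ordered-pair sum / n(n-1) reduces to unordered count / C(n, 2)
    return linked / (n * (n - 1) / 2)


def bhi_solution(solution: ClusteringSolution, ann: dict) -> float:
    """Unweighted mean of defined per-cluster BHI values."""
    scores = [bhi_cluster(m, ann) for m in solution.modules]
    defined = [s for s in scores if s is not None]
    if not defined:
        raise ValueError("no cluster has a defined BHI")
    return float(np.mean(defined))


def hypergeom_upper_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) for a hypergeometric draw of n from N with K successes.

    Equivalent to a one-sided Fisher's exact test for overrepresentation in
    a 2x2 table.
    """
    if not (0 <= k <= min(big_k, n) <= big_n) or n > big_n or big_k > big_n:
        raise ValueError(f"inconsistent counts k={k} K={big_k} n={n} N={big_n}")
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


@dataclass
class EnrichmentResult:
    proportion: float
    direction: str
    p: float
    n_modules_with_uncharacterized: int


def uncharacterized_enrichment(
    solution: ClusteringSolution, ann: dict, universe, two_sided: bool = False
) -> EnrichmentResult:
    """Enrichment of annotation-less genes among the genes of a solution.

    One-sided in the direction of the observed deviation from the universe
    rate (``direction`` is ``"over"`` or ``"under"``); ``two_sided=True``
    doubles the one-sided tail (capped at 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = solution.genes()
    if not genes <= universe:
        raise ValueError("solution contains genes outside the universe")
    x = sum(1 for g in genes if not ann.get(g))
    n = len(genes)
    big_k = sum(1 for g in universe if not ann.get(g))
    big_n = len(universe)
    proportion = x / n if n else 0.0
    if n == 0:
        return EnrichmentResult(0.0, "over", 1.0, 0)
    if proportion >= big_k / big_n:
        direction = "over"
        p = hypergeom_upper_tail(x, big_k, n, big_n)
    else:
        direction = "under"
        p = float(hypergeom.cdf(x, big_n, big_k, n))
    if two_sided:
        p = min(1.0, 2.0 * p)
    with_unchar = sum(1 for m in solution.modules if any(not ann.get(g) for g in m))
    return EnrichmentResult(proportion, direction, p, with_unchar)


@dataclass
class OverlapResult:
    count: int
    p: float


def shared_gene_overlap(
    a: ClusteringSolution, b: ClusteringSolution, universe
) -> OverlapResult:
    """Genes shared by the coverage of two solutions, with a hypergeometric
    upper-tail p-value given the two coverage sizes and the universe."""
    universe = set(universe)
    ga, gb = a.genes(), b.genes()
    if not (ga <= universe and gb <= universe):
        raise ValueError("solution genes must lie inside the universe")
    count = len(ga & gb)
    p = hypergeom_upper_tail(count, len(ga), len(gb), len(universe))
    return OverlapResult(count, p)


def _max_term_share(module, ann: dict) -> float:
    """Largest fraction of the module's genes carrying one common term."""
    counts: dict = {}
    for g in module:
        for term in ann.get(g, ()):
            counts[term] = counts.get(term, 0) + 1
    if not counts:
        return 0.0
    return max(counts.values()) / len(module)


def module_consistency(module, reference: ClusteringSolution, ann: dict) -> bool:
    """80/80-or-50 consistency of a module against a reference clustering.

    True iff (i) at least 80% of the module's genes fall into a single
    reference cluster and (ii) the largest fraction of its genes sharing
    one annotation term is >= 0.8 for modules of 10+ genes, >= 0.5 for
    smaller modules.
    """
    module = set(module)
    if not module:
        raise ValueError("empty module")
    best_ref = max((len(module & r) for r in reference.modules), default=0)
    if best_ref / len(module) < 0.8:
        return False
    needed = 0.8 if len(module) >= 10 else 0.5
    return _max_term_share(module, ann) >= needed


def module_type(module, ann: dict) -> int:
    """Annotation-share proxy for module characterization.

    Type 1: more than half of the module's genes share one annotation term
    (already-known functional link); Type 2 otherwise.
    """
    return 1 if _max_term_share(module, ann) > 0.5 else 2
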