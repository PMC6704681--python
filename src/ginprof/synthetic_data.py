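"""Synthetic SGA-like screens with planted functional modules.

The generator emulates the shape of a real quantitative interaction screen:
a sparse, signed query x array score matrix over a few hundred to a few
thousand genes, in which the genes of a planted module share a designated
set of interaction partners (scores above the 0.5 binarization threshold)
against a low-magnitude noise background.  A matched annotation map assigns
one synthetic functional term per planted module, with a tunable fraction
of module genes left unannotated, so every downstream stage - similarity,
thresholded network, module detection, assessment - can be exercised and
scored without external data.

Module genes interact with their partner set rather than with each other:
network edges in this pipeline encode *profile similarity* (inferred
interaction), so what makes a module recoverable is shared partners, not
direct within-module hits.  Partners are drawn per module from the
background pool, independently across modules, so partner sets may overlap
and weak cross-module similarities arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import ClusteringSolution
from .sga_data import InteractionMatrix

__all__ = ["SyntheticConfig", "SyntheticScreen", "RecoveryReport", "simulate_screen", "recovery_report"]


@dataclass
class SyntheticConfig:
    """Parameters of a planted-module screen.

    Defaults describe the canonical benchmark condition used throughout the
    test suite: 8 modules of 6-10 genes, 15 shared partners per module, 200
    background genes, near-certain within-module interactions (0.95) over a
    0.005 spurious-interaction floor, every gene in both the query and the
    array set, hit scores in (0.6, 1.0) (always above the 0.5 threshold)
    and signed noise scores in (-0.2, 0.2) (always below it).
    """

    n_modules: int = 8
    module_size_range: tuple = (6, 10)
    partners_per_module: int = 15
    n_background_genes: int = 200
    query_fraction: float = 1.0
    array_fraction: float = 1.0
    p_within: float = 0.95
    p_background: float = 0.005
    hit_score_range: tuple = (0.6, 1.0)
    noise_score_range: tuple = (-0.2, 0.2)
    frac_unannotated: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if not (1 <= lo <= hi):
            raise ValueError("module_size_range must be ordered and positive")
        for p in (self.query_fraction, self.array_fraction):
            if not 0 < p <= 1:
                raise ValueError("query/array fractions must be in (0, 1]")
        for p in (self.p_within, self.p_background, self.frac_unannotated):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        h_lo, h_hi = self.hit_score_range
        n_lo, n_hi = self.noise_score_range
        if not (0.5 < h_lo <= h_hi):
            raise ValueError("hit scores must be ordered and exceed the 0.5 threshold")
        if not (-0.5 < n_lo <= n_hi < 0.5):
            raise ValueError("noise scores must be ordered and stay below the 0.5 threshold")
        if self.partners_per_module > self.n_background_genes:
            raise ValueError("not enough background genes to draw a partner set")


@dataclass
class SyntheticScreen:
    """A generated screen plus its ground truth."""

    matrix: InteractionMatrix
    truth_modules: list
    partner_sets: list
    annotations: dict
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def n_planted_pairs(self) -> int:
        """Number of planted module-partner gene pairs."""
        return sum(len(m) * len(p) for m, p in zip(self.truth_modules, self.partner_sets))

    @property
    def n_within_module_pairs(self) -> int:
        """Number of gene pairs lying inside one planted module."""
        return sum(len(m) * (len(m) - 1) // 2 for m in self.truth_modules)

    def benchmark_edge_budget(self, factor: int = 5) -> int:
        """Canonical top-k budget for recovery benchmarks:
        ``factor`` x the number of within-module gene pairs."""
        return factor * self.n_within_module_pairs

    def truth_solution(self) -> ClusteringSolution:
        """The planted modules as a :class:`ClusteringSolution`."""
        sizes = [len(m) for m in self.truth_modules]
        universe = set(self.matrix.query_ids) | set(self.matrix.array_ids)
        return ClusteringSolution(
            frozenset(frozenset(m) for m in self.truth_modules),
            frozenset(universe),
            min(sizes),
            max(sizes),
        )


def simulate_screen(cfg: SyntheticConfig) -> SyntheticScreen:
    """Generate a screen; deterministic for a given configuration and seed.

    Gene labels are zero-padded (``G0001``) so lexicographic order equals
    generation order: planted-module genes first, background genes after.
    Each gene enters the query (array) set independently with the
    configured fraction, with at least one member guaranteed per set; every
    tested off-diagonal pair receives a score (hit or noise), self-crosses
    are never produced.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    n_module_genes = int(sizes.sum())
    n_total = n_module_genes + cfg.n_background_genes
    width = max(4, len(str(n_total)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_total)]
    modules: list = []
    start = 0
    for s in sizes:
        modules.append(frozenset(genes[start : start + int(s)]))
        start += int(s)
    background = genes[n_module_genes:]
    partner_sets = [
        frozenset(rng.choice(background, size=cfg.partners_per_module, replace=False))
        for _ in range(cfg.n_modules)
    ]

    index = {g: i for i, g in enumerate(genes)}
    prob = np.full((n_total, n_total), cfg.p_background)
    for mod, partners in zip(modules, partner_sets):
        mi = [index[g] for g in sorted(mod)]
        pi = [index[g] for g in sorted(partners)]
        prob[np.ix_(mi, pi)] = cfg.p_within
        prob[np.ix_(pi, mi)] = cfg.p_within
    # one interaction decision per unordered gene pair
    draw = rng.random((n_total, n_total))
    upper = np.triu(np.ones((n_total, n_total), dtype=bool), k=1)
    interact = (draw < prob) & upper
    interact = interact | interact.T

    hits = rng.uniform(*cfg.hit_score_range, size=(n_total, n_total))
    noise = rng.uniform(*cfg.noise_score_range, size=(n_total, n_total))
    full_scores = np.where(interact, hits, noise)

    in_query = rng.random(n_total) < cfg.query_fraction
    in_array = rng.random(n_total) < cfg.array_fraction
    if not in_query.any():
        in_query[rng.integers(n_total)] = True
    if not in_array.any():
        in_array[rng.integers(n_total)] = True
    q_idx = np.where(in_query)[0]
    a_idx = np.where(in_array)[0]
    scores = full_scores[np.ix_(q_idx, a_idx)].copy()
    # self-crosses are never measured
    same = q_idx[:, None] == a_idx[None, :]
    scores[same] = np.nan
    matrix = InteractionMatrix([genes[i] for i in q_idx], [genes[i] for i in a_idx], scores)

    annotations: dict = {}
    for k, mod in enumerate(modules):
        members = sorted(mod)
        n_unannotated = int(np.floor(cfg.frac_unannotated * len(members)))
        skip = set(rng.choice(members, size=n_unannotated, replace=False)) if n_unannotated else set()
        for g in members:
            if g not in skip:
                annotations[g] = {f"MOD{k:03d}"}
    return SyntheticScreen(matrix, modules, partner_sets, annotations, cfg)


@dataclass
class RecoveryReport:
    best_jaccard: list
    recovered: list
    fraction_recovered: float


def _jaccard_sets(a, b) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def recovery_report(detected: ClusteringSolution, truth, j_min: float = 0.8) -> RecoveryReport:
    """Best-Jaccard match of each planted module among detected modules.

    A truth module counts as recovered when its best Jaccard index against
    any detected module reaches ``j_min``.
    """
    truth = [frozenset(t) for t in truth]
    if not truth:
        raise ValueError("empty truth module list")
    best = [
        max((_jaccard_sets(t, d) for d in detected.modules), default=0.0) for t in truth
    ]
    recovered = [b >= j_min for b in best]
    return RecoveryReport(best, recovered, sum(recovered) / len(truth))
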