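"""Reading, writing and reshaping quantitative genetic-interaction screens.

A synthetic genetic array (SGA) screen crosses a set of *query* gene
deletions against an *array* of deletion mutants and scores the fitness of
each double mutant, yielding a rectangular query x array matrix of signed
interaction scores.  This module holds that matrix (:class:`InteractionMatrix`),
folds it into a symmetric gene x gene score supermatrix over the union of
query and array genes (the "one-square" transformation,
:func:`build_one_square`), and thresholds scores into binary interaction
profiles (:func:`binarize`).

Conventions
-----------
* Matrices travel as tab-separated text: first row = array gene labels,
  first column = query gene labels, empty cell = not measured.
* A gene assayed under several conditions must arrive with distinct labels
  (e.g. ``GENE__27C``); the reader never merges labels.
* The gene universe is the lexicographically sorted union of query and
  array labels; every symmetric matrix is emitted in that canonical order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionMatrix",
    "ScoreSupermatrix",
    "BinarySupermatrix",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_gene_list",
    "write_gene_list",
    "gene_universe",
    "build_one_square",
    "binarize",
]


def _check_unique(labels: list[str], axis: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


@dataclass
class InteractionMatrix:
    """Rectangular query x array matrix of real-valued interaction scores.

    Parameters
    ----------
    query_ids : list of str
        Row labels (query genes), unique.
    array_ids : list of str
        Column labels (array genes), unique.
    scores : ndarray of float, shape (n_query, n_array)
        Interaction scores; ``NaN`` marks a pair that was not measured.
    """

    query_ids: list[str]
    array_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.query_ids), len(self.array_ids)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.query_ids)} query x {len(self.array_ids)} array labels"
            )
        _check_unique(self.query_ids, "query")
        _check_unique(self.array_ids, "array")

    @property
    def measured(self) -> np.ndarray:
        """Boolean mask of measured cells."""
        return ~np.isnan(self.scores)

    @property
    def n_measured(self) -> int:
        return int(self.measured.sum())


@dataclass
class ScoreSupermatrix:
    """Symmetric gene x gene matrix of raw interaction scores.

    ``values[i, j]`` holds the (possibly reciprocal-averaged) score for the
    gene pair; unmeasured pairs hold 0 with ``measured`` false.  The
    diagonal is never measured: the screen does not produce self-pairs.
    """

    gene_ids: list[str]
    values: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)
        if self.values.shape != (n, n) or self.measured.shape != (n, n):
            raise ValueError("supermatrix shape does not match gene_ids")


@dataclass
class BinarySupermatrix:
    """Symmetric 0/1 gene x gene matrix of thresholded interactions."""

    gene_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        n = len(self.gene_ids)
        if self.bits.shape != (n, n):
            raise ValueError("bits shape does not match gene_ids")


def read_interaction_matrix(path, unmeasured: str = "empty") -> InteractionMatrix:
    """Read a tab-separated query x array score matrix.

    Parameters
    ----------
    path : path-like
        File whose first row holds array labels (after a corner cell) and
        whose first column holds query labels.
    unmeasured : {"empty", "zero"}
        Convention for unmeasured pairs.  ``"empty"`` treats only empty
        cells as unmeasured; ``"zero"`` additionally treats exact-zero
        scores as unmeasured (some deposited matrices use 0 as the filler).

    Raises
    ------
    ValueError
        On duplicate labels (naming the label) or ragged rows (naming the
        row index).
    """
    if unmeasured not in ("empty", "zero"):
        raise ValueError(f"unknown unmeasured convention: {unmeasured!r}")
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    array_ids = [cell.strip() for cell in rows[0][1:]]
    n_array = len(array_ids)
    query_ids: list[str] = []
    data = np.full((len(rows) - 1, n_array), np.nan)
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != n_array + 1:
            raise ValueError(
                f"{path}: ragged row {r}: {len(row)} fields, expected {n_array + 1}"
            )
        query_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell:
                data[r - 1, c] = float(cell)
    if unmeasured == "zero":
        data[data == 0.0] = np.nan
    return InteractionMatrix(query_ids, array_ids, data)


def write_interaction_matrix(m: InteractionMatrix, path) -> None:
    """Write an :class:`InteractionMatrix` in the tab-separated dialect.

    Unmeasured cells are written empty.  ``repr``-precision floats are used
    so a write/read round trip is bit-exact.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + list(m.array_ids))
        for i, q in enumerate(m.query_ids):
            row: list[str] = [q]
            for x in m.scores[i]:
                row.append("" if np.isnan(x) else repr(float(x)))
            writer.writerow(row)


def read_gene_list(path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            handle.write(f"{g}\n")


def gene_universe(m: InteractionMatrix) -> list[str]:
    """Sorted union of query and array labels (no duplicates)."""
    return sorted(set(m.query_ids) | set(m.array_ids))


def build_one_square(m: InteractionMatrix) -> ScoreSupermatrix:
    """Fold a rectangular screen into a symmetric score supermatrix.

    Every measured cell ``X[q, a]`` is placed at the supermatrix position of
    the unordered gene pair ``{q, a}``.  If both the query-array and the
    reciprocal array-query cross were measured, the two scores are averaged;
    pairs never measured are stored as 0 with ``measured`` false.  The
    diagonal is always unmeasured.
    """
    genes = gene_universe(m)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    qi = np.fromiter((index[g] for g in m.query_ids), dtype=int, count=len(m.query_ids))
    ai = np.fromiter((index[g] for g in m.array_ids), dtype=int, count=len(m.array_ids))
    meas = m.measured
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    acc[np.ix_(qi, ai)] = np.where(meas, m.scores, 0.0)
    cnt[np.ix_(qi, ai)] = meas
    total = acc + acc.T
    count = cnt + cnt.T
    np.fill_diagonal(total, 0.0)
    np.fill_diagonal(count, 0.0)
    values = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return ScoreSupermatrix(genes, values, count > 0)


def binarize(s: ScoreSupermatrix, threshold: float = 0.5) -> BinarySupermatrix:
    """Threshold a score supermatrix into binary interaction profiles.

    A bit is 1 iff the score is strictly greater than *threshold* (default
    0.5, the conventional cutoff for these screens); scores equal to the
    threshold, and unmeasured pairs, map to 0.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    bits = (s.values > threshold) & s.measured
    return BinarySupermatrix(s.gene_ids, bits.astype(np.uint8))
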