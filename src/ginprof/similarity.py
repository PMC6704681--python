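"""Profile-similarity measures between genetic interaction vectors.

Two genes are considered functionally related when their genome-wide
interaction profiles are similar.  For binary (thresholded) profiles ``x``
and ``y`` with ``a`` shared 1s and support sizes ``|x|``, ``|y|``:

* Maryland bridge   ``Mb = (a/|x| + a/|y|) / 2``
* Dice              ``D  = 2a / (|x| + |y|)``   (harmonic mean of the two
  Braun-Blanquet coefficients)
* Ochiai            ``O  = a / sqrt(|x| |y|)``  (their geometric mean)
* Braun-Blanquet    ``BBmax = a / max(|x|, |y|)``, ``BBmin = a / min(|x|, |y|)``
* Jaccard           ``J  = a / (|x| + |y| - a)``

For raw (signed, real-valued) profiles the Pearson product-moment
correlation is used directly.  Whenever a denominator vanishes (empty
support, constant vector) the similarity is defined as 0 so that matrices
stay total; Pearson's degenerate pairs are additionally flagged in the
``defined`` mask.

All-pairs similarity matrices are built either from the rows of the
one-square score supermatrix (:func:`similarity_one_square`) or by scoring
query rows and array columns separately and merging the two square blocks
(:func:`similarity_two_squares`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sga_data import (
    BinarySupermatrix,
    InteractionMatrix,
    ScoreSupermatrix,
    binarize,
    gene_universe,
)

__all__ = [
    "BINARY_MEASURES",
    "MEASURES",
    "SimilarityMatrix",
    "SimilaritySummary",
    "maryland_bridge",
    "ochiai",
    "braun_blanquet",
    "dice",
    "jaccard",
    "pearson",
    "similarity_one_square",
    "similarity_two_squares",
    "summarize",
    "write_similarity_matrix",
    "read_similarity_matrix",
]

BINARY_MEASURES = (
    "maryland_bridge",
    "ochiai",
    "braun_blanquet_max",
    "braun_blanquet_min",
    "dice",
    "jaccard",
)
MEASURES = BINARY_MEASURES + ("pearson",)


def _binary_counts(x, y) -> tuple[float, float, float]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    xb = x != 0
    yb = y != 0
    return float(np.sum(xb & yb)), float(xb.sum()), float(yb.sum())


def maryland_bridge(x, y) -> float:
    """Maryland bridge coefficient; 0 if either support is empty."""
    a, nx, ny = _binary_counts(x, y)
    if nx == 0 or ny == 0:
        return 0.0
    return 0.5 * (a / nx + a / ny)


def ochiai(x, y) -> float:
    """Ochiai (cosine) coefficient; 0 if either support is empty."""
    a, nx, ny = _binary_counts(x, y)
    if nx == 0 or ny == 0:
        return 0.0
    return a / np.sqrt(nx * ny)


def braun_blanquet(x, y, variant: str = "max") -> float:
    """Braun-Blanquet coefficient, shared 1s over the larger ("max") or
    smaller ("min") support; 0 if the relevant denominator is 0."""
    a, nx, ny = _binary_counts(x, y)
    if variant == "max":
        denom = max(nx, ny)
    elif variant == "min":
        denom = min(nx, ny)
    else:
        raise ValueError(f"unknown Braun-Blanquet variant: {variant!r}")
    return a / denom if denom > 0 else 0.0


def dice(x, y) -> float:
    """Sorensen-Dice coefficient; 0 if both supports are empty."""
    a, nx, ny = _binary_counts(x, y)
    return 2.0 * a / (nx + ny) if nx + ny > 0 else 0.0


def jaccard(x, y) -> float:
    """Jaccard coefficient; 0 if the union of supports is empty."""
    a, nx, ny = _binary_counts(x, y)
    union = nx + ny - a
    return a / union if union > 0 else 0.0


def pearson(x, y) -> float:
    """Pearson product-moment correlation; 0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("pearson requires vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float((xc @ yc) / denom)


_SCALAR = {
    "maryland_bridge": maryland_bridge,
    "ochiai": ochiai,
    "braun_blanquet_max": lambda x, y: braun_blanquet(x, y, "max"),
    "braun_blanquet_min": lambda x, y: braun_blanquet(x, y, "min"),
    "dice": dice,
    "jaccard": jaccard,
    "pearson": pearson,
}


def pairwise_similarity(vectors: np.ndarray, measure: str) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs similarity between the rows of ``vectors``.

    Returns ``(values, defined)``; for binary measures rows are thresholded
    at 0.5 first (NaN counts as no interaction).  Vectorized equivalent of
    looping the scalar measures over every row pair.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown similarity measure: {measure!r}")
    v = np.asarray(vectors, dtype=float)
    n = v.shape[0]
    if measure == "pearson":
        filled = np.nan_to_num(v, nan=0.0)
        centered = filled - filled.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
        cov = centered @ centered.T
        denom = np.outer(norms, norms)
        values = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
        np.clip(values, -1.0, 1.0, out=values)
        ok = norms > 0
        defined = np.outer(ok, ok)
        return values, defined
    b = (np.nan_to_num(v, nan=0.0) > 0.5).astype(float)
    a = b @ b.T
    s = b.sum(axis=1)
    if measure == "maryland_bridge":
        t1 = np.divide(a, s[:, None], out=np.zeros_like(a), where=s[:, None] > 0)
        t2 = np.divide(a, s[None, :], out=np.zeros_like(a), where=s[None, :] > 0)
        empty = (s[:, None] == 0) | (s[None, :] == 0)
        values = np.where(empty, 0.0, 0.5 * (t1 + t2))
    elif measure == "ochiai":
        denom = np.sqrt(np.outer(s, s))
        values = np.divide(a, denom, out=np.zeros_like(a), where=denom > 0)
    elif measure == "braun_blanquet_max":
        denom = np.maximum.outer(s, s)
        values = np.divide(a, denom, out=np.zeros_like(a), where=denom > 0)
    elif measure == "braun_blanquet_min":
        denom = np.minimum.outer(s, s)
        values = np.divide(a, denom, out=np.zeros_like(a), where=denom > 0)
    elif measure == "dice":
        denom = np.add.outer(s, s)
        values = np.divide(2.0 * a, denom, out=np.zeros_like(a), where=denom > 0)
    else:  # jaccard
        denom = np.add.outer(s, s) - a
        values = np.divide(a, denom, out=np.zeros_like(a), where=denom > 0)
    return values, np.ones((n, n), dtype=bool)


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene profile-similarity matrix.

    ``defined`` marks entries that carry a meaningful similarity; the
    diagonal is always flagged undefined so that self-similarities never
    enter summaries or networks.
    """

    gene_ids: list[str]
    values: np.ndarray
    defined: np.ndarray
    measure: str
    transformation: str

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene_ids")


@dataclass
class SimilaritySummary:
    mean: float
    variance: float
    median: float
    minimum: float
    maximum: float


def similarity_one_square(r: ScoreSupermatrix, measure: str) -> SimilarityMatrix:
    """Score every pair of rows of the one-square supermatrix.

    Binary measures act on the thresholded profiles (cutoff 0.5); Pearson
    acts on the raw score rows directly (unmeasured entries count as 0, the
    supermatrix fill value).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown similarity measure: {measure!r}")
    if measure == "pearson":
        values, defined = pairwise_similarity(r.values, measure)
    else:
        bits = binarize(r).bits.astype(float)
        values, defined = pairwise_similarity(bits, measure)
    defined = defined.copy()
    np.fill_diagonal(defined, False)
    return SimilarityMatrix(list(r.gene_ids), values, defined, measure, "one_square")


def similarity_two_squares(m: InteractionMatrix, measure: str) -> SimilarityMatrix:
    """Score query rows and array columns separately, then merge.

    The query x query block Q and array x array block A are each mapped
    into the gene-universe frame; a pair present in both blocks is
    averaged, a pair present in neither (one gene query-only and the other
    array-only) stays undefined.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown similarity measure: {measure!r}")
    genes = gene_universe(m)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    qi = np.fromiter((index[g] for g in m.query_ids), dtype=int, count=len(m.query_ids))
    ai = np.fromiter((index[g] for g in m.array_ids), dtype=int, count=len(m.array_ids))
    q_vals, q_def = pairwise_similarity(m.scores, measure)
    a_vals, a_def = pairwise_similarity(m.scores.T, measure)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    acc[np.ix_(qi, qi)] += np.where(q_def, q_vals, 0.0)
    cnt[np.ix_(qi, qi)] += q_def
    acc[np.ix_(ai, ai)] += np.where(a_def, a_vals, 0.0)
    cnt[np.ix_(ai, ai)] += a_def
    values = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    defined = cnt > 0
    np.fill_diagonal(defined, False)
    return SimilarityMatrix(genes, values, defined, measure, "two_squares")


def summarize(s: SimilarityMatrix) -> SimilaritySummary:
    """Summary statistics over defined, off-diagonal, upper-triangle entries.

    Variance is the population variance (``ddof=0``).
    """
    iu, ju = np.triu_indices(len(s.gene_ids), k=1)
    mask = s.defined[iu, ju]
    vals = s.values[iu, ju][mask]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal similarity entries")
    return SimilaritySummary(
        mean=float(vals.mean()),
        variance=float(vals.var(ddof=0)),
        median=float(np.median(vals)),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
    )


def write_similarity_matrix(s: SimilarityMatrix, path) -> None:
    """Write a gene x gene similarity table plus a ``.meta`` sidecar.

    Undefined entries are written empty; the sidecar records the measure
    and transformation so the matrix is self-describing on re-read.
    """
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + list(s.gene_ids))
        for i, g in enumerate(s.gene_ids):
            row = [g]
            for j in range(len(s.gene_ids)):
                row.append(repr(float(s.values[i, j])) if s.defined[i, j] else "")
            writer.writerow(row)
    with open(str(path) + ".meta", "w") as handle:
        handle.write(f"measure={s.measure}\ntransformation={s.transformation}\n")


def read_similarity_matrix(path) -> SimilarityMatrix:
    import csv

    with open(path, newline="") as handle:
        rows = list(csv.reader(handle, delimiter="\t"))
    genes = [c.strip() for c in rows[0][1:]]
    n = len(genes)
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell:
                values[i, j] = float(cell)
                defined[i, j] = True
    meta = {"measure": "unknown", "transformation": "unknown"}
    try:
        with open(str(path) + ".meta") as handle:
            for line in handle:
                if "=" in line:
                    key, val = line.strip().split("=", 1)
                    meta[key] = val
    except FileNotFoundError:
        pass
    return SimilarityMatrix(genes, values, defined, meta["measure"], meta["transformation"])
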