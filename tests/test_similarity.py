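"""Scalar similarity coefficients, all-pairs matrices and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ginprof.sga_data import InteractionMatrix, build_one_square
from ginprof.similarity import (
    BINARY_MEASURES,
    MEASURES,
    braun_blanquet,
    dice,
    jaccard,
    maryland_bridge,
    ochiai,
    pearson,
    read_similarity_matrix,
    similarity_one_square,
    similarity_two_squares,
    summarize,
    write_similarity_matrix,
)

HALF_X = [1, 1, 0, 0]
HALF_Y = [1, 0, 1, 0]


class TestScalarCoefficients:
    @pytest.mark.parametrize(
        "fn,x,y,expected",
        [
            (maryland_bridge, HALF_X, HALF_Y, 0.5),
            (maryland_bridge, [1, 0, 1], [1, 0, 1], 1.0),
            (maryland_bridge, [1, 1, 1, 0], [1, 0, 0, 0], 2 / 3),
            (ochiai, [1, 0, 1], [1, 0, 1], 1.0),
            (ochiai, [1, 0, 0], [0, 1, 1], 0.0),
            (ochiai, [1, 1, 1, 0], [1, 0, 0, 0], 1 / np.sqrt(3)),
            (dice, HALF_X, HALF_Y, 0.5),
            (dice, [1, 1, 1, 0], [1, 0, 0, 0], 0.5),
            (dice, [0, 1, 1], [0, 1, 1], 1.0),
            (jaccard, HALF_X, HALF_Y, 1 / 3),
            (jaccard, [1, 1, 0], [1, 1, 0], 1.0),
            (jaccard, [1, 0, 0], [0, 1, 0], 0.0),
        ],
    )
    def test_known_values(self, fn, x, y, expected):
        assert fn(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "variant,expected", [("max", 1 / 3), ("min", 1.0)]
    )
    def test_braun_blanquet_variants(self, variant, expected):
        assert braun_blanquet([1, 1, 1, 0], [1, 0, 0, 0], variant) == pytest.approx(expected)
        assert braun_blanquet([1, 0, 1], [1, 0, 1], variant) == 1.0
        assert braun_blanquet([1, 0, 0], [0, 1, 1], variant) == 0.0

    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 0, 1, 0], [1, 1, 0, 0], 0.0),
        ],
    )
    def test_pearson(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_vector_is_zero(self):
        assert pearson([2, 2, 2], [1, 2, 3]) == 0.0

    def test_length_mismatch_raises(self):
        for fn in (maryland_bridge, ochiai, dice, jaccard, pearson):
            with pytest.raises(ValueError, match="mismatch"):
                fn([1, 0], [1, 0, 1])

    def test_empty_support_is_zero(self):
        zero = [0, 0, 0]
        one = [1, 0, 1]
        assert maryland_bridge(zero, one) == 0.0
        assert ochiai(zero, one) == 0.0
        assert braun_blanquet(zero, zero, "min") == 0.0
        assert dice(zero, zero) == 0.0
        assert jaccard(zero, zero) == 0.0


@given(
    st.lists(st.booleans(), min_size=1, max_size=30),
    st.data(),
)
def test_binary_measure_relations(bits_x, data):
    """Ordering chain, geometric/harmonic-mean identities, symmetry, range."""
    x = np.array(bits_x, dtype=int)
    y = np.array(data.draw(st.lists(st.booleans(), min_size=len(x), max_size=len(x))), dtype=int)
    bb_max = braun_blanquet(x, y, "max")
    bb_min = braun_blanquet(x, y, "min")
    d = dice(x, y)
    o = ochiai(x, y)
    mb = maryland_bridge(x, y)
    j = jaccard(x, y)
    eps = 1e-12
    for val in (bb_max, bb_min, d, o, mb, j):
        assert -eps <= val <= 1 + eps
    if x.sum() and y.sum():
        assert bb_max <= d + eps <= o + 2 * eps <= mb + 3 * eps <= bb_min + 4 * eps
    assert o * o == pytest.approx(bb_max * bb_min, abs=1e-12)
    if bb_max + bb_min > 0:
        assert d == pytest.approx(2 * bb_max * bb_min / (bb_max + bb_min), abs=1e-12)
    # symmetry in arguments
    assert maryland_bridge(y, x) == pytest.approx(mb, abs=1e-15)
    assert braun_blanquet(y, x, "max") == pytest.approx(bb_max, abs=1e-15)
    # pearson on binary vectors equals the phi coefficient
    if len(x) >= 2:
        n11 = int(np.sum((x == 1) & (y == 1)))
        n10 = int(np.sum((x == 1) & (y == 0)))
        n01 = int(np.sum((x == 0) & (y == 1)))
        n00 = int(np.sum((x == 0) & (y == 0)))
        denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        phi = (n11 * n00 - n10 * n01) / np.sqrt(denom) if denom > 0 else 0.0
        assert pearson(x, y) == pytest.approx(phi, abs=1e-12)


class TestOneSquareMatrix:
    def test_identical_rows_score_one(self):
        from ginprof.sga_data import ScoreSupermatrix

        vals = np.array(
            [[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]]
        )
        meas = ~np.eye(3, dtype=bool)
        r = ScoreSupermatrix(["A", "B", "C"], vals, meas)
        for measure in BINARY_MEASURES:
            s = similarity_one_square(r, measure)
            assert s.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("measure", MEASURES)
    def test_matches_scalar_loop_oracle(self, measure, rng, make_supermatrix):
        from ginprof.sga_data import binarize
        from ginprof.similarity import _SCALAR

        r = make_supermatrix(rng, n=20, density=0.5)
        s = similarity_one_square(r, measure)
        rows = r.values if measure == "pearson" else binarize(r).bits
        for i in range(20):
            for j in range(20):
                expected = _SCALAR[measure](rows[i], rows[j])
                assert s.values[i, j] == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(s.values, s.values.T, atol=0)
        assert not s.defined.diagonal().any()

    def test_unknown_measure(self, rng, make_supermatrix):
        with pytest.raises(ValueError, match="unknown"):
            similarity_one_square(make_supermatrix(rng, n=4), "euclid")


class TestTwoSquares:
    def test_symmetric_square_equals_one_block(self, rng):
        n = 6
        genes = [f"G{i}" for i in range(n)]
        x = rng.normal(size=(n, n))
        x = (x + x.T) / 2
        m = InteractionMatrix(genes, list(genes), x)
        s = similarity_two_squares(m, "pearson")
        from ginprof.similarity import pairwise_similarity

        q_vals, _ = pairwise_similarity(x, "pearson")
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(s.values[off], q_vals[off], atol=1e-12)

    def test_disjoint_sets_mapping_rule(self):
        x = np.array([[0.6, 0.7], [0.8, 0.9]])
        m = InteractionMatrix(["A", "B"], ["C", "D"], x)
        s = similarity_two_squares(m, "ochiai")
        idx = {g: i for i, g in enumerate(s.gene_ids)}
        for pair in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert not s.defined[idx[pair[0]], idx[pair[1]]]
        assert s.defined[idx["A"], idx["B"]]  # from Q only
        assert s.defined[idx["C"], idx["D"]]  # from A only

    def test_pearson_oracle_6x8(self, rng):
        nq, na = 6, 8
        query = [f"Q{i}" for i in range(nq - 2)] + ["S0", "S1"]
        array = [f"A{j}" for j in range(na - 2)] + ["S0", "S1"]
        x = rng.normal(size=(nq, na))
        m = InteractionMatrix(query, array, x)
        s = similarity_two_squares(m, "pearson")
        idx = {g: i for i, g in enumerate(s.gene_ids)}
        # brute-force: Q from rows, A from columns, then average where both
        for gi, g in enumerate(s.gene_ids):
            for hi_, h in enumerate(s.gene_ids):
                if g == h:
                    continue
                parts = []
                if g in query and h in query:
                    parts.append(pearson(x[query.index(g)], x[query.index(h)]))
                if g in array and h in array:
                    parts.append(pearson(x[:, array.index(g)], x[:, array.index(h)]))
                if parts:
                    assert s.defined[idx[g], idx[h]]
                    assert s.values[idx[g], idx[h]] == pytest.approx(np.mean(parts), abs=1e-10)
                else:
                    assert not s.defined[idx[g], idx[h]]


class TestSummaries:
    def test_two_value_summary(self):
        from ginprof.similarity import SimilarityMatrix

        vals = np.array([[0, 0.2, 0.4], [0.2, 0, 0.0], [0.4, 0.0, 0]])
        defined = np.array(
            [[False, True, True], [True, False, False], [True, False, False]]
        )
        s = SimilarityMatrix(["A", "B", "C"], vals, defined, "ochiai", "one_square")
        summary = summarize(s)
        assert summary.mean == pytest.approx(0.3)
        assert summary.minimum == 0.2
        assert summary.maximum == 0.4
        assert summary.median == pytest.approx(0.3)
        assert summary.variance == pytest.approx(0.01)

    def test_constant_entries_zero_variance(self):
        from ginprof.similarity import SimilarityMatrix

        vals = np.full((3, 3), 0.1)
        defined = ~np.eye(3, dtype=bool)
        s = SimilarityMatrix(["A", "B", "C"], vals, defined, "dice", "one_square")
        assert summarize(s).variance == pytest.approx(0.0, abs=1e-30)

    def test_agrees_with_flattened_reference(self, rng, make_supermatrix):
        r = make_supermatrix(rng, n=30, density=0.5)
        s = similarity_one_square(r, "maryland_bridge")
        summary = summarize(s)
        flat = [
            s.values[i, j]
            for i in range(30)
            for j in range(i + 1, 30)
            if s.defined[i, j]
        ]
        assert summary.mean == pytest.approx(np.mean(flat))
        assert summary.variance == pytest.approx(np.var(flat))
        assert summary.median == pytest.approx(np.median(flat))

    def test_no_defined_entries_raises(self):
        from ginprof.similarity import SimilarityMatrix

        s = SimilarityMatrix(
            ["A", "B"], np.zeros((2, 2)), np.zeros((2, 2), bool), "dice", "one_square"
        )
        with pytest.raises(ValueError):
            summarize(s)


def test_similarity_matrix_round_trip(tmp_path, rng, make_supermatrix):
    r = make_supermatrix(rng, n=10, density=0.5)
    s = similarity_one_square(r, "ochiai")
    path = tmp_path / "sim.tsv"
    write_similarity_matrix(s, path)
    back = read_similarity_matrix(path)
    assert back.gene_ids == s.gene_ids
    assert back.measure == "ochiai"
    assert back.transformation == "one_square"
    np.testing.assert_array_equal(back.defined, s.defined)
    np.testing.assert_array_equal(back.values[back.defined], s.values[s.defined])
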