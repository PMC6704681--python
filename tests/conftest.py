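import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_matrix():
    """2-query x 3-array screen with all cells measured."""
    from ginprof.sga_data import InteractionMatrix

    return InteractionMatrix(
        ["QA", "QB"],
        ["AA", "AB", "AC"],
        np.array([[0.1, 0.6, -0.2], [0.7, 0.0, 0.9]]),
    )


@pytest.fixture
def make_supermatrix():
    """Factory for random symmetric fully-measured score supermatrices."""

    def build(rng, n=20, density=0.4, lo=-1.0, hi=1.5):
        from ginprof.sga_data import ScoreSupermatrix

        raw = rng.uniform(lo, hi, size=(n, n))
        raw = np.where(rng.random((n, n)) < density, raw, 0.0)
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0.0)
        measured = np.ones((n, n), dtype=bool)
        np.fill_diagonal(measured, False)
        genes = [f"G{i:03d}" for i in range(n)]
        return ScoreSupermatrix(genes, sym, measured)

    return build
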