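"""Adjacency transform, topological overlap and its brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comethnet import (
    AdjacencyMatrix,
    correlation_adjacency,
    tom_dissimilarity,
    tom_similarity,
)

from .conftest import make_matrix


def tom_brute_force(A: np.ndarray) -> np.ndarray:
    """Independent triple-loop evaluation of the overlap formula."""
    n = A.shape[0]
    k = [sum(A[i, v] for v in range(n) if v != i) for i in range(n)]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, v] * A[j, v] for v in range(n) if v not in (i, j))
            t[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) - A[i, j] + 1.0)
    return t


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    return a


def pooled_matrix(values, genes):
    samples = [f"s{i}" for i in range(np.asarray(values).shape[1])]
    groups = {s: "5mC" for s in samples}
    return make_matrix(values, genes, samples, groups)


class TestCorrelationAdjacency:
    def test_duplicated_profiles_give_unit_weight(self):
        m = pooled_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [2, 1, 4, 3]], ["a", "b", "c"])
        for transform in ("abs", "signed_half", "clamp_zero"):
            a = correlation_adjacency(m, ["a", "b", "c"], transform=transform)
            assert a.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_by_transform(self):
        m = pooled_matrix([[1, 2, 3, 4], [4, 3, 2, 1], [1, 3, 2, 4]], ["a", "b", "c"])
        assert correlation_adjacency(m, ["a", "b"], "abs").values[0, 1] == pytest.approx(1.0)
        assert correlation_adjacency(m, ["a", "b"], "signed_half").values[0, 1] == pytest.approx(0.0)
        assert correlation_adjacency(m, ["a", "b"], "clamp_zero").values[0, 1] == pytest.approx(0.0)

    def test_hand_computed_correlations(self):
        m = pooled_matrix(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]], ["g1", "g2", "g3"]
        )
        a = correlation_adjacency(m, ["g1", "g2", "g3"], "abs")
        off = a.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_soft_power(self):
        m = pooled_matrix(np.random.default_rng(0).normal(size=(3, 8)), ["a", "b", "c"])
        a1 = correlation_adjacency(m, ["a", "b", "c"], "abs", power=1.0)
        a2 = correlation_adjacency(m, ["a", "b", "c"], "abs", power=2.0)
        assert np.allclose(a2.values, a1.values ** 2)

    def test_errors(self):
        m = pooled_matrix([[1, 1, 1, 1], [1, 2, 3, 4]], ["flat", "ok"])
        with pytest.raises(ValueError, match="zero-variance.*flat"):
            correlation_adjacency(m, ["flat", "ok"])
        with pytest.raises(ValueError, match="absent"):
            correlation_adjacency(m, ["ok", "ghost"])
        with pytest.raises(ValueError, match="at least 2"):
            correlation_adjacency(m, ["ok"])


class TestTOM:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        a = AdjacencyMatrix(gene_ids=list("abcd"), values=random_adjacency(rng, 4))
        assert np.all(np.diag(tom_similarity(a).values) == 1.0)

    def test_isolated_pair_is_zero(self):
        a = AdjacencyMatrix(gene_ids=list("ab"), values=np.zeros((2, 2)))
        assert tom_similarity(a).values[0, 1] == 0.0

    def test_three_node_hand_value(self):
        # all off-diagonal weights 0.5: overlap (0.25 + 0.5) / (1 - 0.5 + 1)
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0)
        a = AdjacencyMatrix(gene_ids=list("abc"), values=vals)
        t = tom_similarity(a)
        assert t.values[0, 1] == pytest.approx(0.5)
        d = tom_dissimilarity(t)
        assert d.values[0, 1] == pytest.approx(0.5)
        assert np.all(np.diag(d.values) == 0.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 16))
            vals = random_adjacency(rng, n)
            a = AdjacencyMatrix(gene_ids=[f"g{i}" for i in range(n)], values=vals)
            t = tom_similarity(a).values
            expected = tom_brute_force(vals)
            assert np.abs(t - expected).max() < 1e-10
            assert t.min() >= 0.0 and t.max() <= 1.0

    def test_binary_identical_rows_reach_maximal_overlap(self):
        # with 0/1 weights, duplicated neighbourhoods and a direct link give 1
        vals = np.array(
            [
                [0, 1, 1, 1],
                [1, 0, 1, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
        a = AdjacencyMatrix(gene_ids=list("abcd"), values=vals)
        assert tom_similarity(a).values[0, 1] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_permutation_equivariance_and_bounds(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = random_adjacency(rng, n)
        genes = [f"g{i}" for i in range(n)]
        t = tom_similarity(AdjacencyMatrix(gene_ids=genes, values=vals)).values
        assert t.min() >= 0.0 and t.max() <= 1.0
        perm = rng.permutation(n)
        vals_p = vals[np.ix_(perm, perm)]
        t_p = tom_similarity(
            AdjacencyMatrix(gene_ids=[genes[i] for i in perm], values=vals_p)
        ).values
        assert np.allclose(t_p, t[np.ix_(perm, perm)], atol=1e-12)

    def test_rejects_invalid_input(self):
        bad = np.array([[0.0, 0.4], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyMatrix(gene_ids=list("ab"), values=bad)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            AdjacencyMatrix(gene_ids=list("ab"), values=np.array([[0.0, 1.4], [1.4, 0.0]]))
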