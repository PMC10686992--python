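import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mixkit import (
    adjust,
    build_partition,
    count_edges,
    mixing_matrix,
)
from mixkit.mixing import EdgeCounts, MixingMatrix, _make_mixing

GITHUB = dict(E00=7432, E01=149069, E11=1381069, E=1537570)


def counts_to_mixing(E00, E01, E11):
    counts = EdgeCounts(np.array([[E00, E01], [0, E11]]), directed=False)
    return mixing_matrix(counts)


class TestBuildPartition:
    def test_minority_first_two_groups(self):
        labels = {i: ("F" if i < 2 else "M") for i in range(10)}
        part = build_partition(labels)
        assert part.categories == ("F", "M")
        np.testing.assert_allclose(part.fractions, [0.2, 0.8])
        assert all(part.labels[i] == 0 for i in range(2))

    def test_single_group(self):
        part = build_partition({i: "A" for i in range(6)})
        assert part.n_groups == 1
        np.testing.assert_allclose(part.fractions, [1.0])

    def test_three_equal_groups_tie_broken_lexicographically(self):
        part = build_partition({"a": "X", "b": "Y", "c": "Z"})
        assert part.categories == ("X", "Y", "Z")
        np.testing.assert_allclose(part.fractions, [1 / 3] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty partition"):
            build_partition({})


class TestCountEdges:
    def test_single_intra_edge_lands_on_minority_diagonal(self):
        part = build_partition({"u": "a", "v": "a", "w": "b", "x": "b", "y": "b"})
        counts = count_edges([("u", "v")], part)
        assert counts.total == 1
        assert counts.counts[0, 0] == 1

    def test_mixed_undirected(self, path_network):
        edges, labels = path_network
        part = build_partition(labels)
        counts = count_edges(edges + [("u0", "x1")], part)
        assert counts.counts[0, 0] == 1
        assert counts.counts[0, 1] == 2
        assert counts.counts[1, 1] == 1
        assert counts.total == 4

    def test_directed_keeps_orientation(self):
        part = build_partition({"u": "a", "v": "a", "w": "b", "x": "b", "y": "b"})
        counts = count_edges([("u", "w"), ("v", "x")], part, directed=True)
        assert counts.counts[0, 1] == 2
        assert counts.counts[1, 0] == 0

    def test_duplicate_undirected_edges_collapse(self):
        part = build_partition({"u": "a", "v": "a", "w": "b"})
        counts = count_edges([("u", "v"), ("v", "u")], part)
        assert counts.total == 1
        multi = count_edges([("u", "v"), ("v", "u")], part, multigraph=True)
        assert multi.total == 2

    def test_self_loop_rejected(self):
        part = build_partition({"u": "a", "v": "b"})
        with pytest.raises(ValueError, match="self-loop"):
            count_edges([("u", "u")], part)

    def test_unlabeled_endpoint_named_in_error(self):
        part = build_partition({"u": "a", "v": "b"})
        with pytest.raises(ValueError, match="ghost"):
            count_edges([("u", "ghost")], part)


class TestMixingMatrix:
    def test_github_fractions(self):
        m = counts_to_mixing(GITHUB["E00"], GITHUB["E01"], GITHUB["E11"])
        assert m.e[0, 0] == pytest.approx(0.0048336, abs=5e-7)
        assert m.e[0, 1] == pytest.approx(0.0484755, abs=5e-7)
        assert m.e[1, 0] == m.e[0, 1]
        assert m.e[1, 1] == pytest.approx(0.8982154, abs=5e-7)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 0, 1), [[0.5, 0.0], [0.0, 0.5]]),
            ((0, 2, 0), [[0.0, 0.5], [0.5, 0.0]]),
        ],
    )
    def test_small_cases(self, counts, expected):
        m = counts_to_mixing(*counts)
        np.testing.assert_allclose(m.e, expected)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            counts_to_mixing(0, 0, 0)

    def test_marginals_match_sums(self):
        m = counts_to_mixing(3, 5, 7)
        np.testing.assert_array_equal(m.a, m.e.sum(axis=1))
        np.testing.assert_array_equal(m.b, m.e.sum(axis=0))
        assert abs(m.e.sum() - 1.0) < 1e-12


class TestAdjust:
    def test_github_adjusted_entries(self):
        m = counts_to_mixing(GITHUB["E00"], GITHUB["E01"], GITHUB["E11"])
        adj = adjust(m, [0.06, 0.94])
        assert adj.adjusted
        assert adj.e[0, 0] == pytest.approx(0.329230, abs=5e-6)
        assert adj.e[0, 1] == pytest.approx(0.210754, abs=5e-6)
        assert adj.e[1, 1] == pytest.approx(0.249262, abs=5e-6)
        assert abs(adj.e.sum() - 1.0) < 1e-12

    def test_equal_fractions_is_identity(self):
        m = counts_to_mixing(3, 5, 7)
        adj = adjust(m, [0.5, 0.5])
        np.testing.assert_allclose(adj.e, m.e, atol=1e-12)

    def test_hand_arithmetic_diagonal_case(self):
        m = _make_mixing(np.diag([0.5, 0.5]))
        adj = adjust(m, [0.2, 0.8])
        # raw quotients (12.5, 0.78125); normalized by 13.28125
        np.testing.assert_allclose(
            np.diag(adj.e), [12.5 / 13.28125, 0.78125 / 13.28125], atol=1e-12)

    def test_raw_quotients_exposed(self):
        m = _make_mixing(np.diag([0.5, 0.5]))
        raw = adjust(m, [0.2, 0.8], normalize=False)
        np.testing.assert_allclose(np.diag(raw), [12.5, 0.78125])

    def test_zero_fraction_rejected(self):
        m = counts_to_mixing(1, 1, 1)
        with pytest.raises(ValueError, match="degenerate group"):
            adjust(m, [0.0, 1.0])

    def test_double_adjustment_rejected(self):
        m = counts_to_mixing(1, 1, 1)
        with pytest.raises(ValueError, match="already adjusted"):
            adjust(adjust(m, [0.4, 0.6]), [0.4, 0.6])

    def test_symmetry_preserved(self):
        m = counts_to_mixing(3, 5, 7)
        adj = adjust(m, [0.25, 0.75])
        np.testing.assert_allclose(adj.e, adj.e.T, atol=1e-15)


count_matrices = arrays(
    np.int64, (3, 3), elements=st.integers(min_value=0, max_value=50)
).filter(lambda c: np.triu(c).sum() > 0)


@given(counts=count_matrices, perm_seed=st.integers(0, 1000))
def test_permutation_equivariance(counts, perm_seed):
    """Relabeling groups permutes every derived matrix consistently."""
    upper = np.triu(counts)
    perm = np.random.default_rng(perm_seed).permutation(3)
    m = mixing_matrix(EdgeCounts(upper, directed=False))
    # permute the full symmetric count matrix, then refold to upper triangle
    full = upper + upper.T - np.diag(np.diag(upper))
    refolded = np.triu(full[np.ix_(perm, perm)])
    m_perm = mixing_matrix(EdgeCounts(refolded, directed=False))
    np.testing.assert_allclose(m.e[np.ix_(perm, perm)], m_perm.e, atol=1e-12)
    f = np.array([0.2, 0.3, 0.5])
    adj = adjust(m, f)
    adj_perm = adjust(m_perm, f[perm])
    np.testing.assert_allclose(adj.e[np.ix_(perm, perm)], adj_perm.e, atol=1e-12)
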