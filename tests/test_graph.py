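"""Nearest-neighbor graph construction, normalization, splitting, sub-sampling."""

import numpy as np
import pytest
import scipy.sparse as sp

from graphgwp import (
    DataSplit,
    MarkerMatrix,
    augment_adjacency,
    knn_graph,
    normalize_adjacency,
    sample_subgraphs,
    split_vertices,
    zero_cross_partition_edges,
)
from graphgwp.graph import degree_summary, export_edge_list, induced_subgraph

from conftest import random_marker_matrix


def brute_force_knn_edges(X, K):
    """Independent edge-set oracle: full pairwise distances, union symmetrization."""
    n = X.shape[0]
    edges = set()
    for i in range(n):
        d = [(np.linalg.norm(X[i] - X[j]), j) for j in range(n) if j != i]
        d.sort()
        for _, j in d[:K]:
            edges.add((min(i, j), max(i, j)))
    return edges


def edge_set(graph):
    A = sp.triu(graph.adjacency, k=1).tocoo()
    return set(zip(A.row.tolist(), A.col.tolist()))


class TestKnnGraph:
    def test_k_max_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        m = random_marker_matrix(rng, 6, 4)
        g = knn_graph(m, K=5)
        dense = g.adjacency.toarray()
        assert np.all(dense + np.eye(6) == 1)

    def test_hand_derived_two_pairs(self):
        # rows (0,0),(0,1),(2,2),(2,1); all 6 pairwise distances enumerated by
        # hand give nearest pairs (0,1) and (2,3)
        X = np.array([[0, 0], [0, 1], [2, 2], [2, 1]], dtype=float)
        g = knn_graph(X, K=1)
        assert edge_set(g) == {(0, 1), (2, 3)}

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_edge_sets_match_brute_force_oracle(self, K):
        rng = np.random.default_rng(101)
        for _ in range(50):
            m = random_marker_matrix(rng, 20, 6)
            g = knn_graph(m, K=K)
            assert edge_set(g) == brute_force_knn_edges(
                np.asarray(m.dosages, dtype=float), K
            )

    def test_k_out_of_range(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            knn_graph(X, K=4)

    def test_duplicate_rows_do_not_raise(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        g = knn_graph(X, K=1)
        assert g.n_vertices == 4  # ties broken deterministically, no exception

    def test_row_permutation_invariance_up_to_relabeling(self):
        # continuous coordinates: distances are tie-free, so the edge set is
        # a function of geometry alone and must commute with relabeling
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 5))
        g = knn_graph(X, K=3)
        perm = rng.permutation(15)
        g2 = knn_graph(X[perm], K=3)
        mapped = {(min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in edge_set(g2)}
        assert mapped == edge_set(g)

    def test_neighbor_lists_nest_with_k(self):
        # pre-symmetrization neighbor sets for K' < K are prefixes of those for K
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        for K_small, K_big in [(1, 3), (2, 4)]:
            d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            order = np.lexsort((np.broadcast_to(np.arange(12), (12, 12)), d2), axis=1)
            for v in range(12):
                assert set(order[v, :K_small]) <= set(order[v, :K_big])

    def test_distances_stored_on_edges(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0], [30.0, 40.0]])
        g = knn_graph(X, K=1)
        assert g.distances[0, 1] == pytest.approx(5.0)

    def test_missing_dosages_rejected(self):
        m = MarkerMatrix(["a", "b"], ["m"], np.array([[np.nan], [1.0]]))
        with pytest.raises(ValueError, match="missing"):
            knn_graph(m, K=1)


class TestAugmentNormalize:
    def test_edgeless_graph_augments_to_identity(self):
        from graphgwp import NeighborGraph

        g = augment_adjacency(NeighborGraph(adjacency=sp.csr_matrix((3, 3))))
        assert np.all(g.augmented.toarray() == np.eye(3))

    def test_single_edge_augmentation(self):
        from graphgwp import NeighborGraph

        g = NeighborGraph(adjacency=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert np.all(g.augmented.toarray() == 1.0)
        np.testing.assert_array_equal(g.degrees, [2.0, 2.0])

    def test_augmented_diagonal_always_one(self):
        rng = np.random.default_rng(3)
        g = knn_graph(random_marker_matrix(rng, 10, 4), K=2)
        assert np.all(g.augmented.diagonal() == 1.0)

    def test_single_vertex_normalizes_to_one(self):
        from graphgwp import NeighborGraph

        g = NeighborGraph(adjacency=sp.csr_matrix((1, 1)))
        np.testing.assert_allclose(normalize_adjacency(g).toarray(), [[1.0]])

    def test_two_vertex_complete_graph_all_half(self):
        from graphgwp import NeighborGraph

        g = NeighborGraph(adjacency=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
        np.testing.assert_allclose(normalize_adjacency(g).toarray(), 0.5)

    def test_entrywise_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = knn_graph(random_marker_matrix(rng, 12, 5), K=2)
            P = normalize_adjacency(g).toarray()
            At = g.augmented.toarray()
            d = g.degrees
            expected = At / np.sqrt(np.outer(d, d))
            np.testing.assert_allclose(P, expected, atol=1e-12)
            assert np.all((P >= 0) & (P <= 1))
            assert np.allclose(P, P.T)

    def test_spectral_radius_at_most_one(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = knn_graph(random_marker_matrix(rng, 10, 4), K=2)
            eigs = np.linalg.eigvalsh(normalize_adjacency(g).toarray())
            assert np.max(np.abs(eigs)) <= 1.0 + 1e-10


class TestSplitVertices:
    def test_paper_protocol_sizes(self):
        s = split_vertices(1100, test_n=100, train_fraction=0.8, seed=0)
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (800, 200, 100)

    def test_same_seed_identical(self):
        a = split_vertices(50, test_n=10, seed=4)
        b = split_vertices(50, test_n=10, seed=4)
        for x, y in zip((a.train_idx, a.val_idx, a.test_idx), (b.train_idx, b.val_idx, b.test_idx)):
            np.testing.assert_array_equal(x, y)

    def test_disjoint_union_over_many_seeds(self):
        for seed in range(1000):
            s = split_vertices(23, test_n=5, train_fraction=0.7, seed=seed)
            allv = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
            assert len(np.unique(allv)) == len(allv) == 23

    def test_test_n_too_large(self):
        with pytest.raises(ValueError):
            split_vertices(10, test_n=10)


class TestZeroCrossPartitionEdges:
    def _graph_and_split(self, seed=0):
        rng = np.random.default_rng(seed)
        g = knn_graph(random_marker_matrix(rng, 30, 5), K=3)
        s = split_vertices(30, test_n=6, seed=seed)
        return g, s

    def test_single_cross_edge_removed(self):
        from graphgwp import NeighborGraph

        A = np.zeros((4, 4))
        A[0, 3] = A[3, 0] = 1.0  # train vertex 0 -- test vertex 3
        g = NeighborGraph(adjacency=sp.csr_matrix(A))
        s = DataSplit(train_idx=[0, 1], val_idx=[2], test_idx=[3])
        assert zero_cross_partition_edges(g, s).adjacency.nnz == 0

    def test_result_is_block_diagonal_over_partitions(self):
        g, s = self._graph_and_split(7)
        zg = zero_cross_partition_edges(g, s)
        lab = s.labels(30)
        A = zg.adjacency.tocoo()
        assert all(lab[i] == lab[j] for i, j in zip(A.row, A.col))

    def test_within_train_edges_unchanged(self):
        g, s = self._graph_and_split(2)
        zg = zero_cross_partition_edges(g, s)
        tr = s.train_idx
        before = g.adjacency[np.ix_(tr, tr)].toarray()
        after = zg.adjacency[np.ix_(tr, tr)].toarray()
        np.testing.assert_array_equal(before, after)

    def test_idempotent(self):
        g, s = self._graph_and_split(5)
        once = zero_cross_partition_edges(g, s)
        twice = zero_cross_partition_edges(once, s)
        assert (once.adjacency != twice.adjacency).nnz == 0


class TestSampleSubgraphs:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        g = knn_graph(random_marker_matrix(rng, n, 5), K=3)
        s = split_vertices(n, test_n=8, seed=seed)
        return g, s

    def test_single_subgraph_equals_induced_training_graph(self):
        g, s = self._setup(1)
        batch = sample_subgraphs(g, s, n_subgraphs=1, seed=3)
        assert batch.n_subgraphs == 1
        np.testing.assert_array_equal(batch.subgraphs[0].vertex_indices, s.train_idx)
        expected = induced_subgraph(g, s.train_idx)
        assert (batch.subgraphs[0].graph.adjacency != expected.adjacency).nnz == 0

    def test_disjoint_partition_covers_train_exactly(self):
        g, s = self._setup(4)
        batch = sample_subgraphs(g, s, n_subgraphs=5, seed=9)
        concat = np.sort(np.concatenate([sg.vertex_indices for sg in batch.subgraphs]))
        np.testing.assert_array_equal(concat, np.sort(s.train_idx))
        sizes = [len(sg.vertex_indices) for sg in batch.subgraphs]
        assert max(sizes) - min(sizes) <= 1

    def test_subgraph_edges_internal_only(self):
        g, s = self._setup(6)
        batch = sample_subgraphs(g, s, n_subgraphs=4, seed=2)
        for sg in batch.subgraphs:
            assert sg.graph.n_vertices == len(sg.vertex_indices)
            assert set(sg.vertex_indices) <= set(s.train_idx.tolist())

    def test_too_many_subgraphs(self):
        g, s = self._setup(0, n=20)
        with pytest.raises(ValueError):
            sample_subgraphs(g, s, n_subgraphs=len(s.train_idx) + 1)


class TestExports:
    def test_edge_list_and_degree_summary(self, tmp_path):
        rng = np.random.default_rng(0)
        g = knn_graph(random_marker_matrix(rng, 10, 4), K=2)
        out = tmp_path / "edges.tsv"
        export_edge_list(g, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "source_id\ttarget_id\tdistance"
        assert len(lines) - 1 == g.n_edges
        summ = degree_summary(g)
        assert summ["n_vertices"] == 10
        assert summ["n_edges"] == g.n_edges
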