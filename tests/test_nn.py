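"""Graph-convolution layer semantics, aggregators, forward pass and gradients."""

import numpy as np
import pytest
import scipy.sparse as sp

from graphgwp import (
    LayerWeights,
    NeighborGraph,
    gcn_layer_forward,
    knn_graph,
    mean_aggregate_forward,
    mse_loss,
    normalize_adjacency,
    sample_aggregate_forward,
)
from graphgwp.nn import (
    backward_full,
    forward,
    forward_full,
    init_gcn_model,
    load_model,
    propagation_operator,
    row_normalized_adjacency,
    save_model,
)

from conftest import random_marker_matrix


def message_passing_oracle(A_norm, H, W):
    """Entrywise per-vertex oracle for the normalized convolution."""
    A = np.asarray(A_norm.todense() if sp.issparse(A_norm) else A_norm)
    n, d_out = H.shape[0], W.shape[1]
    out = np.zeros((n, d_out))
    for v in range(n):
        msg = np.zeros(H.shape[1])
        for u in range(n):
            msg += A[v, u] * H[u]
        out[v] = msg @ W
    return out


class TestGcnLayerForward:
    def test_identity_propagation(self):
        H = np.arange(6, dtype=float).reshape(3, 2)
        layer = LayerWeights(W=np.eye(2), activation="identity")
        np.testing.assert_array_equal(gcn_layer_forward(H, np.eye(3), layer), H)

    def test_hand_two_vertex_average(self):
        A = np.full((2, 2), 0.5)
        H = np.array([[2.0], [4.0]])
        layer = LayerWeights(W=np.array([[1.0]]), activation="identity")
        np.testing.assert_allclose(gcn_layer_forward(H, A, layer), [[3.0], [3.0]])

    def test_relu_clamps_negatives_to_zero(self):
        H = np.array([[-5.0], [1.0]])
        layer = LayerWeights(W=np.array([[1.0]]), activation="relu")
        out = gcn_layer_forward(H, np.eye(2), layer)
        np.testing.assert_array_equal(out, [[0.0], [1.0]])

    def test_shape_mismatch_names_both_shapes(self):
        layer = LayerWeights(W=np.ones((3, 2)))
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 2\)|shape"):
            gcn_layer_forward(np.ones((2, 2)), np.eye(2), layer)

    def test_matches_entrywise_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 16)
            m = random_marker_matrix(rng, n, 4)
            g = knn_graph(m, K=min(2, n - 1))
            P = normalize_adjacency(g)
            H = rng.normal(size=(n, 3))
            W = rng.normal(size=(3, 2))
            layer = LayerWeights(W=W, activation="identity")
            np.testing.assert_allclose(
                gcn_layer_forward(H, P, layer),
                message_passing_oracle(P, H, W),
                atol=1e-10,
            )


class TestMeanAggregateForward:
    def test_single_neighbor_copies_embedding(self):
        H = np.array([[1.0], [5.0]])
        layer = LayerWeights(W=np.array([[1.0]]), activation="identity")
        out = mean_aggregate_forward(H, [[1], [0]], layer)
        np.testing.assert_allclose(out, [[5.0], [1.0]])

    def test_hand_arithmetic_with_self_weight(self):
        # neighbors carry 1 and 3 (mean 2), W=2, B=1, own embedding 5 => 9
        H = np.array([[5.0], [1.0], [3.0]])
        layer = LayerWeights(W=np.array([[2.0]]), B=np.array([[1.0]]), activation="identity")
        out = mean_aggregate_forward(H, [[1, 2], [0], [0]], layer)
        assert out[0, 0] == pytest.approx(9.0)

    def test_empty_neighborhood_errors(self):
        layer = LayerWeights(W=np.eye(1))
        with pytest.raises(ValueError, match="empty neighborhood"):
            mean_aggregate_forward(np.ones((2, 1)), [[1], []], layer)

    def test_matrix_form_oracle_on_regular_graph(self):
        # on a k-regular graph with B=0, the mean aggregator equals
        # row-normalized-adjacency propagation
        rng = np.random.default_rng(2)
        n = 6
        A = np.zeros((n, n))  # 6-cycle: 2-regular
        for i in range(n):
            A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
        g = NeighborGraph(adjacency=sp.csr_matrix(A))
        H = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 2))
        layer = LayerWeights(W=W, activation="identity")
        nbrs = [np.flatnonzero(A[v]) for v in range(n)]
        M = row_normalized_adjacency(g)
        np.testing.assert_allclose(
            mean_aggregate_forward(H, nbrs, layer), (M @ H) @ W, atol=1e-12
        )

    def test_fixed_point_when_neighbors_share_embedding(self):
        # B = W, identity activation, all neighbors equal to self => (W+B) h
        h = np.array([2.0, -1.0])
        H = np.tile(h, (3, 1))
        W = np.array([[0.5, 0.1], [0.2, 0.3]])
        layer = LayerWeights(W=W, B=W, activation="identity")
        out = mean_aggregate_forward(H, [[1, 2], [0, 2], [0, 1]], layer)
        np.testing.assert_allclose(out[0], h @ (W + W), atol=1e-12)


class TestSampleAggregateForward:
    def test_singleton_sample_mean_equals_max(self):
        H = np.array([[1.0, 2.0], [3.0, -1.0]])
        layer = LayerWeights(W=np.ones((4, 2)), activation="identity")
        a = sample_aggregate_forward(H, [[1], [0]], layer, agg="mean")
        b = sample_aggregate_forward(H, [[1], [0]], layer, agg="max")
        np.testing.assert_array_equal(a, b)

    def test_hand_mean_and_max_slots(self):
        # neighbors with scalar embeddings -1, 2, 7: mean 8/3, max 7
        H = np.array([[0.0], [-1.0], [2.0], [7.0]])
        W = np.array([[1.0], [0.0]])  # reads out the AGG slot only
        layer = LayerWeights(W=W, activation="identity")
        nbrs = [[1, 2, 3], [0], [0], [0]]
        assert sample_aggregate_forward(H, nbrs, layer, "mean")[0, 0] == pytest.approx(8 / 3)
        assert sample_aggregate_forward(H, nbrs, layer, "max")[0, 0] == pytest.approx(7.0)

    def test_full_sampling_mean_reproduces_mean_aggregator_term(self):
        rng = np.random.default_rng(4)
        n, d, d_out = 7, 3, 2
        H = rng.normal(size=(n, d))
        nbrs = [list(set(rng.integers(0, n, 3).tolist()) - {v}) or [(v + 1) % n] for v in range(n)]
        W_agg = rng.normal(size=(d, d_out))
        concat_W = np.vstack([W_agg, np.zeros((d, d_out))])
        got = sample_aggregate_forward(H, nbrs, LayerWeights(W=concat_W, activation="identity"))
        want = mean_aggregate_forward(
            H, nbrs, LayerWeights(W=W_agg, B=np.zeros((d, d_out)), activation="identity")
        )
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_empty_sample_falls_back_to_self(self):
        H = np.array([[3.0], [1.0]])
        W = np.array([[1.0], [0.0]])
        out = sample_aggregate_forward(H, [[], [0]], LayerWeights(W=W, activation="identity"))
        assert out[0, 0] == pytest.approx(3.0)


class TestMseLoss:
    @pytest.mark.parametrize(
        "pred, truth, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([1.0, 2.0], [3.0, 2.0], 2.0),
        ],
    )
    def test_values(self, pred, truth, expected):
        assert mse_loss(np.array(pred), np.array(truth)) == pytest.approx(expected)

    def test_constant_predictor_gives_population_variance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        assert mse_loss(np.full_like(y, y.mean()), y) == pytest.approx(np.var(y))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.ones(3), np.ones(4))


class TestForwardPass:
    def _graph(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return knn_graph(random_marker_matrix(rng, n, 5), K=2), rng

    def test_dropout_zero_makes_train_equal_eval(self):
        g, rng = self._graph()
        X = rng.normal(size=(8, 5))
        model = init_gcn_model(5, (4, 3), dropout_p=0.0, rng=1)
        train = forward(model, g, X, train_mode=True, seed=9)
        ev = forward(model, g, X, train_mode=False)
        np.testing.assert_array_equal(train.values, ev.values)

    def test_all_zero_weights_predict_head_bias(self):
        g, rng = self._graph()
        X = rng.normal(size=(8, 5))
        model = init_gcn_model(5, (4, 3), rng=1)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        model.params["head_b"] = np.array([2.5])
        out = forward(model, g, X)
        np.testing.assert_allclose(out.values, 2.5)

    def test_manual_single_vertex_composition(self):
        # 1-vertex graph: P = [1]; hand-set 1x1 weights through all stages:
        # conv1: relu(3*2+0)=6 ; conv2: 6*(-1)= -6 ; head: -6*0.5+1 = -2
        g = NeighborGraph(adjacency=sp.csr_matrix((1, 1)))
        model = init_gcn_model(1, (1, 1), dropout_p=0.0, rng=0)
        model.params["W1"] = np.array([[2.0]])
        model.params["W2"] = np.array([[-1.0]])
        model.params["b1"] = np.zeros(1)
        model.params["b2"] = np.zeros(1)
        model.params["head_w"] = np.array([[0.5]])
        model.params["head_b"] = np.array([1.0])
        out = forward(model, g, np.array([[3.0]]))
        assert out.values[0] == pytest.approx(-2.0)

    def test_linear_in_features_with_identity_activations(self):
        g, rng = self._graph(10, 3)
        model = init_gcn_model(4, (3, 2), dropout_p=0.0, rng=2)
        model.activations = ("identity", "identity")
        for k in ("b1", "b2", "head_b"):
            model.params[k] = np.zeros_like(model.params[k])
        P = propagation_operator(g, model.propagation_mode)
        X1, X2 = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        f = lambda X: forward_full(model, P, X)[0]
        np.testing.assert_allclose(
            f(2.0 * X1 - 3.0 * X2), 2.0 * f(X1) - 3.0 * f(X2), atol=1e-10
        )

    def test_propagation_commutes_with_graph_isomorphism(self):
        g, rng = self._graph(9, 7)
        X = rng.normal(size=(9, 5))
        model = init_gcn_model(5, (4, 2), dropout_p=0.0, rng=3)
        perm = rng.permutation(9)
        A_perm = g.adjacency.toarray()[np.ix_(perm, perm)]
        g_perm = NeighborGraph(adjacency=sp.csr_matrix(A_perm))
        out = forward(model, g, X).values
        out_perm = forward(model, g_perm, X[perm]).values
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_all_propagation_modes_agree_on_single_selfloop_vertex(self):
        # on a single self-loop vertex all aggregation slots reduce to the
        # vertex itself; with equivalent weights (no self-path duplication)
        # the three modes must produce the identical composition:
        # conv1 relu(2+1)=3 -> conv2 3+1=4 -> head 4+1=5
        g = NeighborGraph(adjacency=sp.csr_matrix((1, 1)))
        X = np.array([[2.0]])
        outs = []
        for mode in ("normalized_gcn", "mean_aggregator", "sample_aggregate"):
            model = init_gcn_model(1, (1, 1), propagation_mode=mode, dropout_p=0.0, rng=0)
            for k in list(model.params):
                model.params[k] = np.ones_like(model.params[k])
            for k in ("B1", "B2"):
                if k in model.params:
                    model.params[k] = np.zeros_like(model.params[k])
            if mode == "sample_aggregate":  # zero the concatenated self slot
                model.params["W1"][1] = 0.0
                model.params["W2"][1] = 0.0
            outs.append(forward(model, g, X).values[0])
        assert outs[0] == outs[1] == outs[2] == pytest.approx(5.0)

    def test_nan_weights_raise_numeric_error(self):
        g, rng = self._graph()
        model = init_gcn_model(5, (3, 2), rng=0)
        model.params["W1"][0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="conv1"):
            forward(model, g, rng.normal(size=(8, 5)))


class TestGradients:
    @pytest.mark.parametrize("mode", ["normalized_gcn", "mean_aggregator", "sample_aggregate"])
    def test_backward_matches_finite_differences(self, mode):
        rng = np.random.default_rng(12)
        g = knn_graph(random_marker_matrix(rng, 7, 4), K=2)
        P = propagation_operator(g, mode)
        X = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        model = init_gcn_model(4, (3, 2), propagation_mode=mode, dropout_p=0.0, rng=5)

        def loss():
            pred, _ = forward_full(model, P, X)
            return 0.5 * np.sum((pred - y) ** 2)

        pred, caches = forward_full(model, P, X)
        grads = backward_full(model, caches, pred - y)
        eps = 1e-6
        for key in model.params:
            flat = model.params[key].ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                np.testing.assert_allclose(
                    grads[key].ravel()[idx], num, rtol=1e-4, atol=1e-6,
                    err_msg=f"{mode}/{key}[{idx}]",
                )


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = init_gcn_model(6, (4, 3), propagation_mode="mean_aggregator", rng=8)
        model.x_center = np.arange(6.0)
        model.x_scale = np.ones(6)
        model.y_center, model.y_scale = 1.5, 2.0
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.propagation_mode == "mean_aggregator"
        assert back.y_center == 1.5
        for k in model.params:
            np.testing.assert_array_equal(back.params[k], model.params[k])
        np.testing.assert_array_equal(back.x_center, model.x_center)
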