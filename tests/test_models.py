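"""Forward-pass correctness of the MLP, GNN variants and label embedder."""

import numpy as np
import pytest

from gopredict.containers import InteractionTable
from gopredict.errors import ValidationError
from gopredict.graphs import EgoGraph, attach_features, build_ego_graph
from gopredict.embeddings import EmbeddingStore
from gopredict.models import (
    GnnConfig,
    LabelEmbedderConfig,
    MlpHeadConfig,
    embed_labels,
    gnn_forward,
    init_gnn_params,
    init_label_embedder_params,
    init_mlp_params,
    mlp_forward,
)
from gopredict.nn.autograd import Tensor


def silu(x):
    return x / (1.0 + np.exp(-x))


class TestMlpForward:
    def test_eval_mode_deterministic(self):
        cfg = MlpHeadConfig(input_dim=4, output_dim=3, hidden_dims=[5], dropout_rate=0.5)
        params = init_mlp_params(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(6, 4))
        a = mlp_forward(cfg, params, x, train=False).data
        b = mlp_forward(cfg, params, x, train=False).data
        np.testing.assert_array_equal(a, b)

    def test_zero_weights_yield_bias(self):
        cfg = MlpHeadConfig(input_dim=2, output_dim=2, hidden_dims=[3], dropout_rate=0.0)
        params = init_mlp_params(cfg, np.random.default_rng(0))
        for k in params:
            params[k].data[:] = 0.0
        params["b1"].data[:] = [0.5, -1.5]
        out = mlp_forward(cfg, params, np.ones((4, 2))).data
        np.testing.assert_allclose(out, np.tile([0.5, -1.5], (4, 1)))

    def test_matches_manual_affine_silu_chain(self):
        cfg = MlpHeadConfig(input_dim=3, output_dim=2, hidden_dims=[2], dropout_rate=0.0)
        params = init_mlp_params(cfg, np.random.default_rng(0))
        W0 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]])
        b0 = np.array([0.1, -0.2])
        W1 = np.array([[2.0, 0.0], [1.0, 1.0]])
        b1 = np.array([0.0, 0.5])
        params["W0"].data, params["b0"].data = W0, b0
        params["W1"].data, params["b1"].data = W1, b1
        x = np.array([[1.0, 2.0, 3.0], [-1.0, 0.5, 0.0]])
        expected = silu(x @ W0 + b0) @ W1 + b1
        np.testing.assert_allclose(mlp_forward(cfg, params, x).data, expected)

    def test_shape_mismatch_rejected(self):
        cfg = MlpHeadConfig(input_dim=3, output_dim=2)
        params = init_mlp_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            mlp_forward(cfg, params, np.zeros((2, 4)))


class TestEmbedLabels:
    def test_identical_labels_identical_embeddings(self):
        cfg = LabelEmbedderConfig(num_labels=4, output_dim=3)
        params = init_label_embedder_params(cfg, np.random.default_rng(0))
        y = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 0]], dtype=float)
        m = embed_labels(cfg, params, y).data
        np.testing.assert_array_equal(m[0], m[1])
        assert not np.allclose(m[0], m[2])

    def test_zero_labels_zero_biases_zero_embedding(self):
        cfg = LabelEmbedderConfig(num_labels=3, output_dim=2)
        params = init_label_embedder_params(cfg, np.random.default_rng(0))
        params["b0"].data[:] = 0.0
        params["b1"].data[:] = 0.0
        m = embed_labels(cfg, params, np.zeros((1, 3))).data
        np.testing.assert_allclose(m, np.zeros((1, 2)), atol=1e-12)

    def test_matches_manual_two_layer_chain(self):
        cfg = LabelEmbedderConfig(num_labels=3, output_dim=2, hidden_dim=2)
        params = init_label_embedder_params(cfg, np.random.default_rng(0))
        W0 = np.array([[1.0, -1.0], [0.5, 0.5], [0.0, 2.0]])
        b0 = np.array([0.1, 0.2])
        W1 = np.array([[1.0, 1.0], [-1.0, 0.5]])
        b1 = np.array([0.0, -0.1])
        params["W0"].data, params["b0"].data = W0, b0
        params["W1"].data, params["b1"].data = W1, b1
        y = np.array([[1.0, 0.0, 1.0]])
        expected = silu(y @ W0 + b0) @ W1 + b1
        np.testing.assert_allclose(embed_labels(cfg, params, y).data, expected)

    def test_non_binary_labels_rejected(self):
        cfg = LabelEmbedderConfig(num_labels=2, output_dim=2)
        params = init_label_embedder_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            embed_labels(cfg, params, np.array([[0.5, 1.0]]))


def single_node_graph(feature):
    return EgoGraph(
        center="Q", nodes=["Q"], edges=[(0, 0, 1.0)],
        features=np.asarray([feature], dtype=np.float32),
    )


def featured_graphs(rng, n_graphs=4, n_prot=12, dim=5):
    table = InteractionTable.from_rows(
        [
            (f"P{int(i)}", f"P{int(j)}", float(rng.random()))
            for i, j in (
                rng.choice(n_prot, size=2, replace=False) for _ in range(30)
            )
        ]
    )
    store = EmbeddingStore(
        dim=dim,
        vectors={f"P{i}": rng.normal(size=dim).astype(np.float32)
                 for i in range(n_prot)},
    )
    queries = sorted(table.proteins())[:n_graphs]
    return [
        attach_features(build_ego_graph(table, q, k=5), store) for q in queries
    ]


class TestGnnForward:
    def test_single_node_gcn_closed_form(self):
        cfg = GnnConfig(input_dim=3, output_dim=2, architecture="GCN",
                        num_layers=1, hidden_dim=3, dropout_rate=0.0)
        params = init_gnn_params(cfg, np.random.default_rng(0))
        x = np.array([0.5, -1.0, 2.0])
        out = gnn_forward(cfg, params, [single_node_graph(x)]).data
        # one node with a self-loop: normalized adjacency is the identity
        h = silu(x @ params["L0_W"].data + params["L0_b"].data)
        expected = h @ params["Wout"].data + params["bout"].data
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    @pytest.mark.parametrize("arch", ["GAT", "GCN", "GIN"])
    def test_neighbor_order_invariance(self, arch):
        rng = np.random.default_rng(2)
        cfg = GnnConfig(input_dim=4, output_dim=3, architecture=arch,
                        num_layers=2, hidden_dim=8, attention_heads=2,
                        dropout_rate=0.0)
        params = init_gnn_params(cfg, rng)
        feats = rng.normal(size=(4, 4)).astype(np.float32)
        g = EgoGraph(
            center="Q", nodes=["Q", "A", "B", "C"],
            edges=[(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0), (3, 3, 1.0),
                   (0, 1, 0.9), (0, 2, 0.8), (1, 2, 0.7), (0, 3, 0.5)],
            features=feats,
        )
        perm = [0, 3, 1, 2]  # center stays first
        inv = {old: new for new, old in enumerate(perm)}
        g2 = EgoGraph(
            center="Q", nodes=[g.nodes[i] for i in perm],
            edges=[(min(inv[i], inv[j]), max(inv[i], inv[j]), c) if i != j
                   else (inv[i], inv[j], c)
                   for i, j, c in g.edges],
            features=feats[perm],
        )
        out1 = gnn_forward(cfg, params, [g]).data
        out2 = gnn_forward(cfg, params, [g2]).data
        np.testing.assert_allclose(out1[0], out2[0], atol=1e-6)

    @pytest.mark.parametrize("arch", ["GAT", "GCN", "GIN"])
    def test_batching_matches_single_calls(self, arch):
        rng = np.random.default_rng(3)
        graphs = featured_graphs(rng)
        cfg = GnnConfig(input_dim=5, output_dim=2, architecture=arch,
                        num_layers=2, hidden_dim=4, attention_heads=2,
                        dropout_rate=0.0)
        params = init_gnn_params(cfg, rng)
        batch = gnn_forward(cfg, params, graphs).data
        for i, g in enumerate(graphs):
            single = gnn_forward(cfg, params, [g]).data
            np.testing.assert_allclose(batch[i], single[0], atol=1e-8)

    def test_unfeatured_graph_rejected(self):
        cfg = GnnConfig(input_dim=3, output_dim=2)
        params = init_gnn_params(cfg, np.random.default_rng(0))
        bare = EgoGraph(center="Q", nodes=["Q"], edges=[(0, 0, 1.0)])
        with pytest.raises(ValidationError):
            gnn_forward(cfg, params, [bare])

    def test_gat_heads_must_divide_hidden(self):
        with pytest.raises(ValidationError):
            GnnConfig(input_dim=3, output_dim=2, hidden_dim=10, attention_heads=4)
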