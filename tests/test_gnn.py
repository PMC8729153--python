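import numpy as np
import pytest

from lncgat.gnn import (
    Adam,
    GraphBatch,
    ModelConfig,
    gat_attention,
    gat_forward,
    gcn_forward,
    classify,
    init_model,
    loss,
    parameter_count,
    readout,
)
from lncgat.pipeline import train

from conftest import random_attributed_graph


def dense_gcn_oracle(x, edges, W):
    """D^{-1/2} (A + I) D^{-1/2} X W as dense matrix algebra."""
    n = x.shape[0]
    A = np.eye(n)
    for u, v in edges:
        A[u, v] = A[v, u] = 1.0
    d = A.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(d))
    return Dinv @ A @ Dinv @ x @ W


class TestGcnLayer:
    def test_isolated_node_is_linear_map(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 5))
        W = rng.normal(size=(5, 3))
        assert np.allclose(gcn_forward(x, [], W), x @ W)

    def test_two_connected_nodes_average(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4))
        W = rng.normal(size=(4, 3))
        out = gcn_forward(x, [(0, 1)], W)
        expect = (x[0] + x[1]) @ W / 2.0
        assert np.allclose(out[0], expect) and np.allclose(out[1], expect)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(3, 20))
            x = rng.normal(size=(n, 6))
            W = rng.normal(size=(6, 4))
            edges = [
                (u, v)
                for u in range(n)
                for v in range(u + 1, n)
                if rng.random() < 0.3
            ]
            assert np.abs(
                gcn_forward(x, edges, W) - dense_gcn_oracle(x, edges, W)
            ).max() <= 1e-6


class TestGatAttention:
    def params(self, rng, d_in=5, d_out=4):
        return (
            rng.normal(size=(d_in, d_out)),
            rng.normal(size=d_out),
            rng.normal(size=d_out),
        )

    def test_single_neighbour_attention_is_one(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(1, 5))
        W, ad, asrc = self.params(rng)
        att = gat_attention(h, [], W, ad, asrc)
        assert att["alpha"] == pytest.approx([1.0])

    def test_equal_scores_give_uniform_attention(self):
        rng = np.random.default_rng(4)
        h = np.tile(rng.normal(size=(1, 5)), (4, 1))  # identical nodes
        W, ad, asrc = self.params(rng)
        att = gat_attention(h, [(0, 1), (0, 2), (0, 3)], W, ad, asrc)
        mask = att["dst"] == 0
        assert np.allclose(att["alpha"][mask], 0.25)

    def test_rows_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            h = rng.normal(size=(n, 5))
            W, ad, asrc = self.params(rng)
            edges = [
                (u, v) for u in range(n) for v in range(u + 1, n) if rng.random() < 0.4
            ]
            att = gat_attention(h, edges, W, ad, asrc)
            sums = np.zeros(n)
            np.add.at(sums, att["dst"], att["alpha"])
            assert np.abs(sums - 1.0).max() <= 1e-6

    def test_removing_edge_keeps_non_incident_rows(self):
        rng = np.random.default_rng(6)
        h = rng.normal(size=(6, 5))
        W, ad, asrc = self.params(rng)
        edges = [(0, 1), (1, 2), (3, 4), (4, 5)]
        full = gat_attention(h, edges, W, ad, asrc)
        pruned = gat_attention(h, edges[1:], W, ad, asrc)

        def rows(att, node):
            m = att["dst"] == node
            return sorted(zip(att["src"][m].tolist(), att["alpha"][m].tolist()))

        for node in (3, 4, 5):
            assert rows(full, node) == pytest.approx(rows(pruned, node))


class TestGatForward:
    def test_zero_weights_give_zero_output(self):
        rng = np.random.default_rng(7)
        h = rng.normal(size=(4, 5))
        out = gat_forward(h, [(0, 1)], np.zeros((5, 3)), np.zeros(3), np.zeros(3))
        assert np.all(out == 0.0)

    def test_evaluation_forward_is_deterministic(self):
        rng = np.random.default_rng(8)
        graphs = [random_attributed_graph(rng, 6, 9, y=i % 2) for i in range(4)]
        model = init_model(ModelConfig(input_dim=9, seed=5))
        batch = GraphBatch(graphs)
        p1, _ = model.forward(batch, training=False)
        p2, _ = model.forward(batch, training=False)
        assert np.array_equal(p1, p2)


class TestReadoutAndHead:
    def test_readout_concatenates_targets(self):
        rng = np.random.default_rng(9)
        h = rng.normal(size=(7, 4))
        g = readout(h, (2, 5))
        assert g.shape == (8,)
        assert np.array_equal(g, np.concatenate([h[2], h[5]]))

    def test_readout_missing_target_rejected(self):
        with pytest.raises(IndexError):
            readout(np.zeros((3, 4)), (0, 5))

    def test_equal_logits_give_half(self):
        W = np.zeros((4, 2))
        p = classify(np.ones(4), W, np.zeros(2))
        assert p == pytest.approx([0.5, 0.5])

    def test_log_three_logit_gap(self):
        W = np.zeros((2, 2))
        p = classify(np.zeros(2), W, np.array([0.0, np.log(3.0)]))
        assert p == pytest.approx([0.25, 0.75])

    def test_loss_closed_forms(self):
        assert loss(np.array([[0.0, 1.0]]), [1]) == pytest.approx(0.0, abs=1e-9)
        assert loss(np.array([[0.5, 0.5]]), [1]) == pytest.approx(np.log(2))
        rng = np.random.default_rng(10)
        p1 = rng.random(8)
        probs = np.c_[1 - p1, p1]
        assert loss(probs, rng.integers(0, 2, size=8)) >= 0.0

    def test_loss_mean_reduction(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert loss(probs, [0, 1], reduction="mean") == pytest.approx(np.log(2))


class TestInitAndSerialization:
    def test_same_seed_identical_parameters(self):
        cfg = ModelConfig(input_dim=10, seed=3)
        m1, m2 = init_model(cfg), init_model(cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_different_seeds_differ(self):
        cfg = ModelConfig(input_dim=10)
        m1 = init_model(cfg, seed=1)
        m2 = init_model(cfg, seed=2)
        assert not np.array_equal(m1.params["W_gcn"], m2.params["W_gcn"])

    def test_parameter_count_matches_hand_formula(self):
        cfg = ModelConfig(input_dim=10, gcn_dim=8, gat_layers=2, gat_dim=6)
        # 10*8 + (8*6 + 2*6) + (6*6 + 2*6) + 12*2 + 2
        assert parameter_count(cfg) == 80 + 60 + 48 + 26
        model = init_model(cfg)
        assert sum(v.size for v in model.params.values()) == parameter_count(cfg)

    def test_save_load_round_trip_bit_exact(self, tmp_path):
        model = init_model(ModelConfig(input_dim=6, seed=9))
        model.loss_history = [1.0, 0.5]
        path = tmp_path / "model.npz"
        model.save(path)
        from lncgat.gnn import TrainedModel

        back = TrainedModel.load(path)
        assert back.config == model.config
        assert back.loss_history == model.loss_history
        for k in model.params:
            assert np.array_equal(back.params[k], model.params[k])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(input_dim=4, dropout=1.0)


class TestGradientsAndTraining:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(input_dim=6, gcn_dim=4, gat_layers=2, gat_dim=3,
                          dropout=0.0, seed=1)
        model = init_model(cfg)
        graphs = [random_attributed_graph(rng, int(rng.integers(3, 6)), 6, y=i % 2)
                  for i in range(4)]
        batch = GraphBatch(graphs)
        _, grads = model.loss_and_grads(batch)
        eps = 1e-6
        for key in ("W_gcn", "W_gat0", "a_dst1", "W_out", "b_out"):
            v = model.params[key]
            flat = v.reshape(-1)
            for idx in (0, flat.size // 2):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss(model.forward(batch)[0], batch.y)
                flat[idx] = old - eps
                lm = loss(model.forward(batch)[0], batch.y)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)

    def test_forward_is_permutation_equivariant(self):
        rng = np.random.default_rng(12)
        g = random_attributed_graph(rng, 8, 7, y=1)
        model = init_model(ModelConfig(input_dim=7, seed=2))
        p0, _ = model.forward(GraphBatch([g]))

        perm = rng.permutation(8)
        inv = np.argsort(perm)
        from lncgat.features import AttributedSubgraph
        from lncgat.subgraph import EnclosingSubgraph

        nodes = [g.sub.nodes[perm[i]] for i in range(8)]
        edges = [(int(inv[u]), int(inv[v])) for u, v in g.sub.edges]
        tpos = (int(inv[g.sub.target_positions[0]]), int(inv[g.sub.target_positions[1]]))
        g2 = AttributedSubgraph(
            EnclosingSubgraph(g.sub.target_pair, 1, nodes, edges, tpos, g.sub.y),
            g.x[perm],
        )
        p1, _ = model.forward(GraphBatch([g2]))
        assert np.abs(p0 - p1).max() <= 1e-6

    def test_capacity_overfits_random_labels(self):
        """20 random-label subgraphs reach near-zero training loss."""
        rng = np.random.default_rng(13)
        graphs = [
            random_attributed_graph(rng, int(rng.integers(4, 8)), 12, y=int(rng.integers(2)))
            for _ in range(20)
        ]
        cfg = ModelConfig(input_dim=12, dropout=0.0, epochs=200, batch_size=20, seed=4)
        model = train(graphs, cfg)
        assert model.loss_history[-1] < 0.05

    def test_adam_reduces_simple_quadratic(self):
        params = {"w": np.array([5.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(200):
            opt.step({"w": 2 * params["w"]})
        assert abs(params["w"][0]) < 1e-2
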