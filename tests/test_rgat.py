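"""Relational graph attention: dense-oracle equivalence, normalization,
equivariance, determinism."""

import numpy as np
import pytest

from herbgat._autodiff import Tensor
from herbgat.rgat import (
    SELF_RELATION,
    GraphTensors,
    RgatConfig,
    RgatModel,
    scaled_dot_attention,
)


# ---------------------------------------------------------------------------
# Dense brute-force oracle: materializes full attention matrices per node,
# reading the same parameters as the edge-list implementation.
# ---------------------------------------------------------------------------


def dense_layer_oracle(layer, H, src, dst, rel, n_nodes):
    """Per-node loops over the in-neighborhood; full softmax per head."""
    K, M = layer.K, layer.M
    dh, drh = layer.d_head, layer.d_rhead
    h_att = np.zeros((n_nodes, layer.hidden))
    h_rel = np.zeros((n_nodes, layer.hidden))
    rel_emb = layer.rel_emb.data
    for i in range(n_nodes):
        nbr = np.flatnonzero(dst == i)
        if len(nbr) == 0:
            continue
        js = src[nbr]
        for k in range(K):
            Wq = layer.q.W.data[:, k * dh:(k + 1) * dh]
            Wk = layer.k.W.data[:, k * dh:(k + 1) * dh]
            Wv = layer.v.W.data[:, k * dh:(k + 1) * dh]
            scores = np.array([(H[i] @ Wq) @ (H[j] @ Wk) for j in js]) / np.sqrt(dh)
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            h_att[i, k * dh:(k + 1) * dh] = sum(
                a * (H[j] @ Wv) for a, j in zip(alpha, js))
        for m in range(M):
            W1, b1 = layer.rel_w1[m].W.data, layer.rel_w1[m].b.data
            W2, b2 = layer.rel_w2[m].W.data, layer.rel_w2[m].b.data
            g = []
            for e_idx in nbr:
                r = rel_emb[rel[e_idx]]
                inner = np.maximum(r @ W1 + b1, 0.0)
                g.append(1.0 / (1.0 + np.exp(-(inner @ W2 + b2)[0])))
            g = np.array(g)
            ex = np.exp(g - g.max())
            beta = ex / ex.sum()
            Wv = layer.rel_v.W.data[:, m * drh:(m + 1) * drh]
            h_rel[i, m * drh:(m + 1) * drh] = sum(
                b * (H[j] @ Wv) for b, j in zip(beta, js))
    x = np.hstack([h_att, h_rel])
    return np.maximum(x @ layer.out.W.data + layer.out.b.data, 0.0)


def random_graph_tensors(rng, n_nodes, n_rel_types, feat_dim=5, p_edge=0.5):
    """Small single-type graph with random typed edges plus self-loops."""
    src, dst, rel = [], [], []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p_edge:
                src.append(j)
                dst.append(i)
                rel.append(rng.integers(n_rel_types))
    for i in range(n_nodes):
        src.append(i)
        dst.append(i)
        rel.append(n_rel_types)  # self relation id
    names = [f"rel{r}" for r in range(n_rel_types)] + [SELF_RELATION]
    return GraphTensors(
        node_types=["n"],
        type_of=np.zeros(n_nodes, dtype=np.intp),
        type_slices={"n": slice(0, n_nodes)},
        features={"n": rng.standard_normal((n_nodes, feat_dim))},
        src=np.array(src, dtype=np.intp),
        dst=np.array(dst, dtype=np.intp),
        rel=np.array(rel, dtype=np.intp),
        relation_names=names,
    )


def small_config(seed, layers=1):
    return RgatConfig(num_layers=layers, hidden_dim=8, attention_heads=2,
                      relation_heads=2, relation_dim=4, seed=seed)


class TestDenseOracleEquivalence:
    @pytest.mark.parametrize("n_nodes", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("n_rel", [1, 2])
    def test_layer_outputs_match_dense_oracle(self, n_nodes, n_rel):
        """Every graph size up to 6 nodes and up to 2 relation types,
        several random draws each, tolerance 1e-5."""
        for draw in range(4):
            rng = np.random.default_rng(1000 * n_nodes + 100 * n_rel + draw)
            gt = random_graph_tensors(rng, n_nodes, n_rel)
            model = RgatModel(small_config(draw, layers=2),
                              {"n": 5}, gt.relation_names)
            H_out, _ = model.forward(gt)
            H = gt.features["n"] @ model.proj["n"].W.data
            for layer in model.layers:
                H = dense_layer_oracle(layer, H, gt.src, gt.dst, gt.rel, n_nodes)
            assert np.abs(H_out.data - H).max() < 1e-5


class TestAttentionNormalization:
    def test_alpha_and_beta_sum_to_one_per_node_head_layer(self):
        rng = np.random.default_rng(42)
        gt = random_graph_tensors(rng, 12, 2, p_edge=0.3)
        model = RgatModel(small_config(0, layers=2), {"n": 5}, gt.relation_names)
        _, trace = model.forward(gt)
        for layer_alpha, layer_beta in zip(trace.alpha, trace.beta):
            for W in (layer_alpha, layer_beta):
                sums = np.zeros((12, W.shape[1]))
                np.add.at(sums, gt.dst, W)
                assert np.abs(sums - 1.0).max() < 1e-6

    def test_weights_lie_in_unit_interval(self):
        rng = np.random.default_rng(7)
        gt = random_graph_tensors(rng, 8, 2)
        model = RgatModel(small_config(1), {"n": 5}, gt.relation_names)
        _, trace = model.forward(gt)
        for W in trace.alpha + trace.beta:
            assert W.min() >= 0 and W.max() <= 1


class TestScaledDotAttention:
    def test_single_key_returns_value_row(self, rng):
        Q = rng.standard_normal((4, 3))
        K = rng.standard_normal((1, 3))
        V = np.array([[2.0, 5.0]])
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V, (4, 1)))

    def test_identical_keys_give_column_mean(self, rng):
        Q = rng.standard_normal((2, 3))
        K = np.tile(rng.standard_normal(3), (5, 1))
        V = rng.standard_normal((5, 2))
        assert np.allclose(scaled_dot_attention(Q, K, V),
                           np.tile(V.mean(axis=0), (2, 1)))

    def test_hand_arithmetic_value(self):
        out = scaled_dot_attention(np.array([[1.0, 0.0]]),
                                   np.array([[1.0, 0.0], [0.0, 1.0]]),
                                   np.array([[1.0], [0.0]]))
        # weight = softmax(1/sqrt(2), 0) = e^0.70711 / (e^0.70711 + 1)
        expected = np.exp(1 / np.sqrt(2)) / (np.exp(1 / np.sqrt(2)) + 1)
        assert out[0, 0] == pytest.approx(expected, abs=1e-9)
        assert out[0, 0] == pytest.approx(0.66976, abs=1e-5)

    def test_zero_key_dim_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((1, 0)), np.zeros((2, 0)),
                                 np.zeros((2, 1)))


class TestLayerBehaviors:
    def test_single_neighbor_output_is_transformed_neighbor(self):
        """With one in-neighbor the attention weight is 1, so each head
        returns that neighbor's value transform exactly."""
        rng = np.random.default_rng(3)
        # node 1 receives only from node 0 (no self-loop on node 1)
        gt = GraphTensors(
            node_types=["n"], type_of=np.zeros(2, dtype=np.intp),
            type_slices={"n": slice(0, 2)},
            features={"n": rng.standard_normal((2, 5))},
            src=np.array([0, 0], dtype=np.intp),
            dst=np.array([0, 1], dtype=np.intp),
            rel=np.array([1, 0], dtype=np.intp),
            relation_names=["rel0", SELF_RELATION],
        )
        model = RgatModel(small_config(0), {"n": 5}, gt.relation_names)
        H0 = gt.features["n"] @ model.proj["n"].W.data
        layer = model.layers[0]
        h_att, alphas = layer.node_attention(
            Tensor(H0, requires_grad=False), gt.src, gt.dst, 2)
        assert np.allclose(alphas, 1.0)
        assert np.allclose(h_att.data[1], H0[0] @ layer.v.W.data, atol=1e-12)

    def test_uniform_beta_when_single_relation_type(self):
        rng = np.random.default_rng(5)
        gt = random_graph_tensors(rng, 6, 1, p_edge=1.0)
        # overwrite: make every edge the same relation (including loops)
        gt.rel[:] = 0
        model = RgatModel(small_config(2), {"n": 5}, gt.relation_names)
        _, trace = model.forward(gt)
        deg = np.bincount(gt.dst, minlength=6)
        expected = 1.0 / deg[gt.dst]
        assert np.allclose(trace.beta[0], expected[:, None], atol=1e-12)

    def test_output_dimension_is_hidden_for_all_nodes(self, small_assembled):
        gt = GraphTensors.from_graph(small_assembled.graph)
        cfg = RgatConfig(num_layers=2, hidden_dim=16, attention_heads=2,
                         relation_heads=2, relation_dim=4, seed=0)
        model = RgatModel(cfg, {t: gt.features[t].shape[1]
                                for t in gt.node_types}, gt.relation_names)
        H, _ = model.forward(gt)
        assert H.data.shape == (gt.num_nodes, 16)

    def test_two_stacked_layers_equal_manual_composition(self):
        rng = np.random.default_rng(9)
        gt = random_graph_tensors(rng, 6, 2)
        model = RgatModel(small_config(4, layers=2), {"n": 5}, gt.relation_names)
        H_full, _ = model.forward(gt)
        H = Tensor(gt.features["n"] @ model.proj["n"].W.data, requires_grad=False)
        for layer in model.layers:
            H, _, _ = layer(H, gt.src, gt.dst, gt.rel, gt.num_nodes)
        assert np.allclose(H_full.data, H.data, atol=1e-12)


class TestForwardContracts:
    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(11)
        gt = random_graph_tensors(rng, 10, 2)
        outs = []
        for _ in range(2):
            model = RgatModel(small_config(6, layers=2), {"n": 5},
                              gt.relation_names)
            H, _ = model.forward(gt)
            outs.append(H.data)
        assert np.array_equal(outs[0], outs[1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        gt = random_graph_tensors(rng, 7, 2)
        model = RgatModel(small_config(7, layers=2), {"n": 5}, gt.relation_names)
        H1, _ = model.forward(gt)
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        gt2 = GraphTensors(
            node_types=["n"], type_of=gt.type_of,
            type_slices=gt.type_slices,
            features={"n": gt.features["n"][perm]},
            src=inv[gt.src], dst=inv[gt.dst], rel=gt.rel,
            relation_names=gt.relation_names,
        )
        H2, _ = model.forward(gt2)
        assert np.allclose(H1.data[perm], H2.data, atol=1e-10)

    def test_self_loop_only_node_depends_solely_on_own_feature(self):
        """Ablate-the-rest: perturbing every other node's feature leaves an
        isolated (self-loop-only) node's representation unchanged."""
        rng = np.random.default_rng(17)
        gt = random_graph_tensors(rng, 6, 2, p_edge=0.6)
        keep = (gt.src == gt.dst) | (gt.dst != 0)  # node 0: self-loop only
        gt = GraphTensors(
            node_types=["n"], type_of=gt.type_of, type_slices=gt.type_slices,
            features=gt.features, src=gt.src[keep], dst=gt.dst[keep],
            rel=gt.rel[keep], relation_names=gt.relation_names)
        model = RgatModel(small_config(8, layers=1), {"n": 5}, gt.relation_names)
        H1, _ = model.forward(gt)
        feats2 = gt.features["n"].copy()
        feats2[1:] += rng.standard_normal(feats2[1:].shape)
        gt2 = GraphTensors(
            node_types=["n"], type_of=gt.type_of, type_slices=gt.type_slices,
            features={"n": feats2}, src=gt.src, dst=gt.dst, rel=gt.rel,
            relation_names=gt.relation_names)
        H2, _ = model.forward(gt2)
        assert np.allclose(H1.data[0], H2.data[0], atol=1e-12)


class TestConfigAndPersistence:
    def test_hidden_must_divide_heads(self):
        with pytest.raises(ValueError):
            RgatConfig(hidden_dim=10, attention_heads=4)

    def test_default_depth_is_two_layers(self):
        assert RgatConfig().num_layers == 2

    def test_checkpoint_roundtrip(self, tmp_path):
        rng = np.random.default_rng(19)
        gt = random_graph_tensors(rng, 5, 2)
        model = RgatModel(small_config(9, layers=2), {"n": 5}, gt.relation_names)
        H1, _ = model.forward(gt)
        model.save(tmp_path / "ckpt.npz")
        model2 = RgatModel.load(tmp_path / "ckpt.npz")
        H2, _ = model2.forward(gt)
        assert np.array_equal(H1.data, H2.data)

    def test_unknown_node_type_rejected(self):
        rng = np.random.default_rng(21)
        gt = random_graph_tensors(rng, 4, 1)
        model = RgatModel(small_config(1), {"other": 5}, gt.relation_names)
        with pytest.raises(KeyError):
            model.project_inputs(gt)
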