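"""Network core: GAT vs a brute-force oracle, attention algebra, fusion,
variant builders, masking equivalence."""

import numpy as np
import pytest

from eegfuse.autodiff import Tensor
from eegfuse.graph import GraphSpec
from eegfuse.model import (ChannelAttention, EmotionNet, Fusion, GATLayer,
                           LSTMBranch, ModelConfig, build_variant,
                           gate_time_input, load_checkpoint, save_checkpoint)


def random_graph(n, rng, p=0.5):
    bias = rng.uniform(0.1, 1.0, size=(n, n))
    bias = (bias + bias.T) / 2
    np.fill_diagonal(bias, 1.0)
    edges = frozenset(
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    )
    return GraphSpec(bias=bias, tau=1.0, edges=edges, self_loops=True)


def elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1.0)


def gat_oracle(x, layer: GATLayer, graph: GraphSpec):
    """Literal per-node, per-head enumeration of the attention update."""
    n, _ = x.shape
    H, dh = layer.heads, layer.d_head
    adj = graph.adjacency_mask()
    heads_out = np.zeros((n, H * dh))
    for h in range(H):
        Wq = layer.Wq.data[:, h * dh : (h + 1) * dh]
        Wk = layer.Wk.data[:, h * dh : (h + 1) * dh]
        Wv = layer.Wv.data[:, h * dh : (h + 1) * dh]
        for i in range(n):
            neigh = [j for j in range(n) if adj[i, j]]
            e = np.array(
                [
                    (x[i] @ Wq) @ (x[j] @ Wk) / np.sqrt(dh) + graph.bias[i, j]
                    for j in neigh
                ]
            )
            a = np.exp(e - e.max())
            a /= a.sum()
            heads_out[i, h * dh : (h + 1) * dh] = sum(
                a[k] * (x[j] @ Wv) for k, j in enumerate(neigh)
            )
    return elu(heads_out @ layer.Wo.data + layer.bo.data)


@pytest.mark.parametrize("heads", [1, 2])
def test_gat_matches_bruteforce_oracle(heads):
    rng = np.random.default_rng(42)
    for draw in range(10):
        n = int(rng.integers(1, 6))
        graph = random_graph(n, rng)
        layer = GATLayer(d_in=3, d_out=4, heads=heads, rng=rng)
        x = rng.standard_normal((n, 3))
        got = layer(Tensor(x), graph).data
        want = gat_oracle(x, layer, graph)
        np.testing.assert_allclose(got, want, atol=1e-10)


def test_gat_single_node_self_loop():
    rng = np.random.default_rng(0)
    graph = GraphSpec(bias=np.ones((1, 1)), tau=1.0, edges=frozenset())
    layer = GATLayer(2, 2, 1, rng)
    x = rng.standard_normal((1, 2))
    out = layer(Tensor(x), graph).data
    # softmax over a single logit is 1: output = elu(Wv x Wo + bo)
    want = elu((x @ layer.Wv.data) @ layer.Wo.data + layer.bo.data)
    np.testing.assert_allclose(out, want, atol=1e-12)


def test_gat_rejects_indivisible_heads():
    with pytest.raises(ValueError):
        GATLayer(3, 5, 2, np.random.default_rng(0))


def test_channel_attention_simplex_and_scaling():
    rng = np.random.default_rng(1)
    ca = ChannelAttention(6, rng)
    h = Tensor(rng.standard_normal((7, 9, 6)))
    att, att_scaled = ca(h)
    np.testing.assert_allclose(att.data.sum(axis=-1), 1.0)
    np.testing.assert_allclose(att_scaled.data.mean(axis=-1), 1.0)
    assert np.all(att.data > 0)
    # identical embeddings -> uniform weights
    same = Tensor(np.tile(rng.standard_normal(6), (2, 32, 1)))
    att_u, att_s = ca(same)
    np.testing.assert_allclose(att_u.data, 1.0 / 32)
    np.testing.assert_allclose(att_s.data, 1.0)
    # monotone: ordering of scaled weights equals ordering of raw scores
    s = (h.data @ ca.w.data).squeeze(-1)
    assert np.array_equal(
        np.argsort(s, axis=-1), np.argsort(att_scaled.data, axis=-1)
    )


def test_gate_time_input_limits():
    rng = np.random.default_rng(2)
    x = Tensor(rng.standard_normal((3, 10, 4)))
    att = Tensor(rng.uniform(0.5, 2.0, size=(3, 4)))
    # beta -> 0: identity
    out0 = gate_time_input(x, att, Tensor(np.zeros(())))
    np.testing.assert_allclose(out0.data, x.data)
    # beta = 1, att = 2 -> doubled
    out1 = gate_time_input(x, Tensor(np.full((3, 4), 2.0)), Tensor(np.ones(())))
    np.testing.assert_allclose(out1.data, 2.0 * x.data)
    # att all 1 -> identity for any beta
    out2 = gate_time_input(x, Tensor(np.ones((3, 4))), Tensor(np.full((), 0.37)))
    np.testing.assert_allclose(out2.data, x.data)


def test_lstm_branch_temporal_attention():
    rng = np.random.default_rng(3)
    br = LSTMBranch(4, 5, 6, 7, rng)
    x = Tensor(rng.standard_normal((2, 9, 4)))
    z, w = br(x)
    assert z.shape == (2, 7)
    np.testing.assert_allclose(w.data.sum(axis=-1), 1.0)
    assert np.all(w.data >= 0)
    # T = 1: weight is exactly 1
    _, w1 = br(Tensor(rng.standard_normal((2, 1, 4))))
    np.testing.assert_allclose(w1.data, 1.0)
    # order sensitivity: reversing time changes the output
    xr = Tensor(x.data[:, ::-1, :].copy())
    zr, _ = br(xr)
    assert np.max(np.abs(zr.data - z.data)) > 1e-8


def test_fusion_gate_limits_and_convexity():
    rng = np.random.default_rng(4)
    fu = Fusion(5, rng)
    za = Tensor(rng.standard_normal((6, 5)))
    zb = Tensor(rng.standard_normal((6, 5)))
    # w = 0, b = 0 -> midpoint
    fu.w.data[:] = 0.0
    fu.b.data[:] = 0.0
    mid, g = fu(za, zb)
    np.testing.assert_allclose(g.data, 0.5)
    np.testing.assert_allclose(mid.data, 0.5 * (za.data + zb.data))
    # bias -> -inf: gate 0 -> z_lstm passthrough
    fu.b.data[:] = -80.0
    out, g = fu(za, zb)
    np.testing.assert_allclose(g.data, 0.0, atol=1e-20)
    np.testing.assert_allclose(out.data, zb.data)
    # random gate: elementwise between inputs
    fu.w.data[:] = rng.standard_normal((10, 1))
    fu.b.data[:] = 0.3
    out, _ = fu(za, zb)
    lo = np.minimum(za.data, zb.data) - 1e-12
    hi = np.maximum(za.data, zb.data) + 1e-12
    assert np.all(out.data >= lo) and np.all(out.data <= hi)
    # equal inputs -> identity
    same, _ = fu(za, za)
    np.testing.assert_allclose(same.data, za.data)
    with pytest.raises(ValueError):
        fu(za, Tensor(rng.standard_normal((6, 4))))


def test_build_variants():
    m1 = build_variant(1)
    assert m1.use_lstm and not m1.use_gcn and not m1.fusion_active
    m2 = build_variant(2)
    assert m2.use_gcn and not m2.use_lstm
    m3 = build_variant(3)
    assert m3.fusion_active and not m3.use_ca
    m4 = build_variant(4)
    assert m4.use_ca and m4.attn_heads == 2
    assert (m4.lstm_units_1, m4.lstm_units_2, m4.lstm_dense_units) == (32, 64, 32)
    assert (m4.gcn_units_1, m4.gcn_units_2, m4.gcn_dense_units) == (32, 64, 32)
    with pytest.raises(ValueError):
        build_variant(7)
    with pytest.raises(ValueError):
        ModelConfig(use_lstm=False, use_gcn=False)
    with pytest.raises(ValueError):
        ModelConfig(use_lstm=True, use_gcn=False, use_ca=True)


SMALL = ModelConfig(
    lstm_units_1=4, lstm_units_2=4, lstm_dense_units=6,
    gcn_units_1=4, gcn_units_2=4, attn_heads=2, gcn_dense_units=6,
)


def test_forward_probabilities_and_determinism(tiny_graph):
    rng = np.random.default_rng(5)
    model = EmotionNet(SMALL, 4, 5, rng)
    de = rng.standard_normal((8, 4, 5))
    time = rng.standard_normal((8, 4, 10))
    p1 = model.forward(de, time, tiny_graph).data
    p2 = model.forward(de, time, tiny_graph).data
    np.testing.assert_allclose(p1.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(p1 > 0)
    np.testing.assert_array_equal(p1, p2)
    # identical inputs across the batch -> identical outputs
    same = model.forward(np.zeros((4, 4, 5)), np.zeros((4, 4, 10)), tiny_graph).data
    assert np.ptp(same, axis=0).max() == 0.0


def test_lstm_only_ignores_de(tiny_graph):
    rng = np.random.default_rng(6)
    cfg = ModelConfig(
        lstm_units_1=4, lstm_units_2=4, lstm_dense_units=6,
        gcn_units_1=4, gcn_units_2=4, attn_heads=2, gcn_dense_units=6,
        use_gcn=False, use_ca=False,
    )
    model = EmotionNet(cfg, 4, 5, rng)
    time = rng.standard_normal((3, 4, 10))
    p1 = model.forward(None, time, None).data
    p2 = model.forward(rng.standard_normal((3, 4, 5)), time, tiny_graph).data
    np.testing.assert_array_equal(p1, p2)


def test_masked_forward_keep_all_is_bit_identical(tiny_graph):
    rng = np.random.default_rng(7)
    cfg = ModelConfig(
        lstm_units_1=4, lstm_units_2=4, lstm_dense_units=6,
        gcn_units_1=4, gcn_units_2=4, attn_heads=2, gcn_dense_units=6,
        use_ca=True,
    )
    model = EmotionNet(cfg, 4, 5, rng)
    de = rng.standard_normal((5, 4, 5))
    time = rng.standard_normal((5, 4, 10))
    full = model.forward(de, time, tiny_graph).data
    masked = model.forward(de, time, tiny_graph,
                           node_mask=np.ones(4, dtype=bool)).data
    np.testing.assert_array_equal(full, masked)
    # dropping a channel changes the output
    part = model.forward(de, time, tiny_graph,
                         node_mask=np.array([True, True, True, False])).data
    assert np.max(np.abs(part - full)) > 1e-9


def test_checkpoint_roundtrip(tmp_path, tiny_graph):
    rng = np.random.default_rng(8)
    model = EmotionNet(SMALL, 4, 5, rng)
    de = rng.standard_normal((3, 4, 5))
    time = rng.standard_normal((3, 4, 10))
    before = model.forward(de, time, tiny_graph).data
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    after = loaded.forward(de, time, tiny_graph).data
    np.testing.assert_array_equal(before, after)
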