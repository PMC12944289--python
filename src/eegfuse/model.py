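"""Dual-pipeline emotion classifier.

Frequency branch: per-electrode differential-entropy vectors are node
features on the electrode graph; two multi-head graph-attention layers
(attention logits biased additively by the Gaussian distance kernel)
followed by mean pooling over nodes and a dense readout.

Channel attention: the second graph layer's node embeddings are projected
to scalar electrode scores, softmax-normalized, rescaled to mean 1, and
used to gate the time-domain input channel-wise.

Time branch: two stacked LSTM layers over the (gated) multichannel
waveform, additive temporal attention pooling, dense readout.

Fusion: a per-sample sigmoid gate convexly combines the two branch
outputs (the frequency branch is pre-projected to the time branch's
width); a dense softmax head yields 4-quadrant class probabilities
(HVHA, LVHA, LVLA, HVLA).

Single-branch ablation variants bypass the fusion gate and feed the
active branch directly to the classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .autodiff import Tensor, masked_softmax, softmax
from .graph import GraphSpec
from .nn import LSTM, Adam, Dense, Module, TemporalAttention, glorot

__all__ = [
    "ModelConfig",
    "GATLayer",
    "ChannelAttention",
    "gate_time_input",
    "LSTMBranch",
    "Fusion",
    "EmotionNet",
    "build_variant",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """All architectural hyperparameters (the architecture-search decision vector)."""

    lstm_units_1: int = 32
    lstm_units_2: int = 64
    lstm_dense_units: int = 32
    gcn_units_1: int = 32
    gcn_units_2: int = 64
    attn_heads: int = 2
    gcn_dense_units: int = 32
    use_lstm: bool = True
    use_gcn: bool = True
    use_ca: bool = True
    n_classes: int = 4

    def __post_init__(self):
        if not (self.use_lstm or self.use_gcn):
            raise ValueError("at least one branch must be active")
        if self.use_ca and not (self.use_lstm and self.use_gcn):
            raise ValueError("channel attention requires both branches")
        for f in ("lstm_units_1", "lstm_units_2", "lstm_dense_units",
                  "gcn_units_1", "gcn_units_2", "attn_heads", "gcn_dense_units"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def fusion_active(self) -> bool:
        return self.use_lstm and self.use_gcn


def build_variant(model_id: int) -> ModelConfig:
    """Ablation variants with fixed widths.

    1: time branch only; 2: frequency branch only; 3: both + fusion;
    4: both + channel attention + fusion.  Fixed sizes: LSTM layers 32/64,
    dense 32; GAT layers 32/64 with 2 heads, dense 32.
    """
    base = ModelConfig(
        lstm_units_1=32, lstm_units_2=64, lstm_dense_units=32,
        gcn_units_1=32, gcn_units_2=64, attn_heads=2, gcn_dense_units=32,
        use_lstm=True, use_gcn=True, use_ca=False,
    )
    if model_id == 1:
        return replace(base, use_gcn=False)
    if model_id == 2:
        return replace(base, use_lstm=False)
    if model_id == 3:
        return base
    if model_id == 4:
        return replace(base, use_ca=True)
    raise ValueError(f"unknown variant {model_id}; expected 1..4")


class GATLayer(Module):
    """Multi-head graph attention with an additive distance bias.

    Per head: e_ij = (W_q h_i)^T (W_k h_j) / sqrt(d_head) + beta_ij for j in
    the neighborhood (kept edges plus self-loop); attention is the softmax of
    e over the neighborhood; the new node state is the attention-weighted sum
    of W_v h_j.  Heads are concatenated and linearly projected to d_out, then
    passed through an ELU.
    """

    def __init__(self, d_in: int, d_out: int, heads: int, rng: np.random.Generator):
        if d_out % heads != 0:
            raise ValueError(f"d_out={d_out} not divisible by heads={heads}")
        self.heads = heads
        self.d_head = d_out // heads
        self.d_out = d_out
        self.Wq = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.Wk = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.Wv = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.Wo = Tensor(glorot(rng, d_out, d_out), requires_grad=True)
        self.bo = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(
        self,
        x: Tensor,
        graph: GraphSpec,
        node_mask: np.ndarray | None = None,
    ) -> Tensor:
        squeeze = False
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
            squeeze = True
        B, n, _ = x.shape
        H, dh = self.heads, self.d_head

        def split_heads(t):  # [B, n, H*dh] -> [B, H, n, dh]
            return t.reshape(B, n, H, dh).transpose(0, 2, 1, 3)

        q = split_heads(x @ self.Wq)
        k = split_heads(x @ self.Wk)
        v = split_heads(x @ self.Wv)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        logits = logits + Tensor(graph.bias[None, None])
        adj = graph.adjacency_mask()
        if node_mask is not None:
            node_mask = np.asarray(node_mask, dtype=bool)
            adj = adj & node_mask[None, :] & node_mask[:, None]
            # keep masked-out rows numerically valid (their output is zeroed)
            adj = adj | np.diag(~node_mask)
        alpha = masked_softmax(logits, adj[None, None], axis=-1)
        out = alpha @ v  # [B, H, n, dh]
        out = out.transpose(0, 2, 1, 3).reshape(B, n, H * dh)
        out = (out @ self.Wo + self.bo).elu()
        if node_mask is not None:
            out = out * Tensor(node_mask.astype(float)[None, :, None])
        if squeeze:
            out = out.reshape(n, self.d_out)
        return out


class ChannelAttention(Module):
    """Electrode-importance scores from graph-layer node embeddings.

    s_i = w^T h_i; att = softmax(s) over electrodes; att_scaled = n * att so
    the mean weight is exactly 1.  The mixing coefficient beta (stored as a
    raw scalar squashed by a sigmoid into (0,1)) controls how strongly the
    scaled weights gate the time-domain input.
    """

    def __init__(self, d_in: int, rng: np.random.Generator):
        self.w = Tensor(glorot(rng, d_in, 1), requires_grad=True)
        self.mixing_raw = Tensor(np.zeros(()), requires_grad=True)

    @property
    def mixing(self) -> Tensor:
        return self.mixing_raw.sigmoid()

    def __call__(
        self, h: Tensor, node_mask: np.ndarray | None = None
    ) -> tuple[Tensor, Tensor]:
        """h: [B, n, d] -> (att [B, n] on the simplex, att_scaled [B, n])."""
        B, n, _ = h.shape
        s = (h @ self.w).reshape(B, n)
        if node_mask is None:
            att = softmax(s, axis=-1)
            att_scaled = att * float(n)
        else:
            node_mask = np.asarray(node_mask, dtype=bool)
            att = masked_softmax(s, node_mask[None], axis=-1)
            att_scaled = att * float(node_mask.sum())
        return att, att_scaled


def gate_time_input(x_raw: Tensor, att_scaled: Tensor, mixing: Tensor) -> Tensor:
    """x_gated(t, i) = x_raw(t, i) * [(1 - beta) + beta * att_i].

    x_raw: [B, T, n]; att_scaled: [B, n]; mixing: scalar in (0, 1).
    """
    B, _, n = x_raw.shape
    gate = (1.0 - mixing) + mixing * att_scaled  # [B, n]
    return x_raw * gate.reshape(B, 1, n)


class LSTMBranch(Module):
    """Two stacked LSTM layers, temporal-attention pooling, dense readout."""

    def __init__(self, n_channels: int, units_1: int, units_2: int,
                 dense_units: int, rng: np.random.Generator):
        self.lstm1 = LSTM(n_channels, units_1, rng)
        self.lstm2 = LSTM(units_1, units_2, rng)
        self.attention = TemporalAttention(units_2, units_2, rng)
        self.dense = Dense(units_2, dense_units, rng, activation="relu")

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: [B, T, n_channels] -> (z [B, dense_units], temporal weights [B, T])."""
        if x.shape[1] < 1:
            raise ValueError("empty time axis")
        h = self.lstm2(self.lstm1(x))
        ctx, w = self.attention(h)
        return self.dense(ctx), w


class Fusion(Module):
    """Per-sample convex gate between the two branch outputs."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.w = Tensor(glorot(rng, 2 * width, 1), requires_grad=True)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, z_gcn: Tensor, z_lstm: Tensor) -> tuple[Tensor, Tensor]:
        if z_gcn.shape != z_lstm.shape:
            raise ValueError("branch widths differ; project before fusing")
        from .autodiff import concat

        g = (concat([z_gcn, z_lstm], axis=-1) @ self.w + self.b).sigmoid()  # [B, 1]
        fused = (1.0 - g) * z_lstm + g * z_gcn
        return fused, g.reshape(g.shape[0])


class EmotionNet(Module):
    """The full dual-pipeline classifier (any ablation variant).

    The frequency branch runs first so its second-layer embeddings can feed
    the channel-attention gate applied to the time branch's input; the
    branches are conceptually parallel but computed sequentially per sample.
    """

    def __init__(self, config: ModelConfig, n_channels: int, n_bands: int,
                 rng: np.random.Generator):
        self.config = config
        self.n_channels = n_channels
        self.n_bands = n_bands
        c = config
        if c.use_gcn:
            self.gat1 = GATLayer(n_bands, c.gcn_units_1, c.attn_heads, rng)
            self.gat2 = GATLayer(c.gcn_units_1, c.gcn_units_2, c.attn_heads, rng)
            self.gcn_dense = Dense(c.gcn_units_2, c.gcn_dense_units, rng,
                                   activation="relu")
        if c.use_ca:
            self.channel_attention = ChannelAttention(c.gcn_units_2, rng)
        if c.use_lstm:
            self.lstm_branch = LSTMBranch(
                n_channels, c.lstm_units_1, c.lstm_units_2, c.lstm_dense_units, rng
            )
        if c.fusion_active:
            # dimension-matching projection of the frequency branch
            self.gcn_project = Dense(c.gcn_dense_units, c.lstm_dense_units, rng)
            self.fusion = Fusion(c.lstm_dense_units, rng)
            head_width = c.lstm_dense_units
        elif c.use_lstm:
            head_width = c.lstm_dense_units
        else:
            head_width = c.gcn_dense_units
        self.classifier = Dense(head_width, c.n_classes, rng)

    def forward(
        self,
        de: np.ndarray | None,
        time: np.ndarray | None,
        graph: GraphSpec | None,
        node_mask: np.ndarray | None = None,
        return_extras: bool = False,
    ):
        """Class probabilities for a batch.

        de:   [B, n_channels, n_bands] standardized DE features
        time: [B, n_channels, n_time_steps] standardized waveforms
        node_mask: optional boolean [n_channels]; masked-out electrodes are
        removed from the graph (attention renormalized over the remaining
        neighborhood) and zeroed in the time input.
        """
        c = self.config
        extras: dict = {}
        z_gcn = h2 = None
        if c.use_gcn:
            if de is None or graph is None:
                raise ValueError("frequency branch active but de/graph missing")
            x = Tensor(np.asarray(de, dtype=np.float64))
            h1 = self.gat1(x, graph, node_mask)
            h2 = self.gat2(h1, graph, node_mask)
            if node_mask is None:
                pooled = h2.mean(axis=1)
            else:
                m = np.asarray(node_mask, dtype=float)
                pooled = (h2 * Tensor(m[None, :, None])).sum(axis=1) * (
                    1.0 / float(m.sum())
                )
            z_gcn = self.gcn_dense(pooled)
        z_lstm = None
        if c.use_lstm:
            if time is None:
                raise ValueError("time branch active but time input missing")
            xt = Tensor(np.asarray(time, dtype=np.float64)).swapaxes(1, 2)  # [B,T,n]
            if node_mask is not None:
                xt = xt * Tensor(
                    np.asarray(node_mask, dtype=float)[None, None, :]
                )
            if c.use_ca:
                att, att_scaled = self.channel_attention(h2, node_mask)
                extras["channel_attention"] = att
                extras["channel_attention_scaled"] = att_scaled
                xt = gate_time_input(xt, att_scaled, self.channel_attention.mixing)
            z_lstm, tw = self.lstm_branch(xt)
            extras["temporal_attention"] = tw
        if c.fusion_active:
            z, g = self.fusion(self.gcn_project(z_gcn), z_lstm)
            extras["fusion_gate"] = g
        elif c.use_lstm:
            z = z_lstm
        else:
            z = z_gcn
        probs = softmax(self.classifier(z), axis=-1)
        if return_extras:
            return probs, extras
        return probs

    __call__ = forward

    def predict(self, de, time, graph, node_mask=None, batch_size: int = 64) -> np.ndarray:
        """Hard class predictions, computed in batches without gradients."""
        n = (de if de is not None else time).shape[0]
        out = np.empty(n, dtype=np.intp)
        for s in range(0, n, batch_size):
            sl = slice(s, min(s + batch_size, n))
            probs = self.forward(
                None if de is None else de[sl],
                None if time is None else time[sl],
                graph,
                node_mask=node_mask,
            )
            out[sl] = probs.data.argmax(axis=-1)
        return out


# ----------------------------------------------------------- checkpointing
def save_checkpoint(model: EmotionNet, path) -> None:
    """Single-file archive: config as JSON plus all parameter arrays."""
    meta = json.dumps(
        {
            "config": asdict(model.config),
            "n_channels": model.n_channels,
            "n_bands": model.n_bands,
        }
    )
    arrays = {f"p{i}": a for i, a in enumerate(model.state())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_checkpoint(path) -> EmotionNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("p")])
        state = [z[f"p{i}"] for i in range(n)]
    model = EmotionNet(
        ModelConfig(**meta["config"]),
        meta["n_channels"],
        meta["n_bands"],
        np.random.default_rng(0),
    )
    model.load_state(state)
    return model
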