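"""Differentiable architecture search over the model's width/head space.

Every architectural decision (LSTM layer widths, dense widths, GAT layer
widths, attention head count) has a small candidate set.  A supernet
instantiates one sub-layer per candidate and mixes their outputs with
softmax(architecture parameters alpha) — heterogeneous widths are made
summable by a linear canonicalization map from each candidate's width to
the decision point's maximum width (the discretized network drops these
maps and uses the raw width).  Head-count candidates are separate
sub-layer instantiations, mixed the same way; the unit and head mixtures
of a graph layer factorize, so each (units, heads) sub-layer carries the
product of the two softmax weights.

Search alternates per epoch between updating network weights w on one
half of the pooled training+validation windows and updating alpha on the
other half (first-order), both with Adam at the same learning rate.
Discretization picks the argmax candidate per decision (ties broken
toward the smaller, cheaper candidate); the discrete architectures found
under different seeds are retrained from scratch on the standard 60/20/20
split and the one with the highest validation accuracy is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor, cross_entropy, softmax
from .features import FeaturePair
from .graph import GraphSpec
from .model import (ChannelAttention, Fusion, GATLayer, ModelConfig,
                    gate_time_input)
from .nn import LSTM, Adam, Dense, Module, TemporalAttention

__all__ = [
    "SearchSpace",
    "SearchResult",
    "SuperNet",
    "mixed_forward",
    "search",
    "discretize",
    "retrain_and_select",
    "run_search",
]


@dataclass(frozen=True)
class SearchSpace:
    """Candidate sets per decision point."""

    lstm_units_1: tuple = (32, 48, 64, 80, 96, 128, 160)
    lstm_units_2: tuple = (32, 48, 64, 80, 96, 128, 160)
    lstm_dense_units: tuple = (64, 96, 128, 160)
    gcn_units_1: tuple = (32, 48, 64, 80, 96, 112, 128, 160)
    gcn_units_2: tuple = (32, 48, 64, 80, 96, 112, 128, 160)
    attn_heads: tuple = (1, 2, 4, 8)
    gcn_dense_units: tuple = (64, 96, 128, 160)

    def __post_init__(self):
        for f in fields(self):
            cands = getattr(self, f.name)
            if len(cands) == 0:
                raise ValueError(f"{f.name}: empty candidate set")

    def decision_names(self) -> list[str]:
        return [f.name for f in fields(self)]


def mixed_forward(x, candidates, alpha: Tensor):
    """Softmax(alpha)-weighted sum of candidate operations applied to x.

    ``candidates`` are callables with outputs of one common shape;
    differentiable in alpha and in every candidate's own weights.
    """
    if len(candidates) != alpha.shape[0]:
        raise ValueError("alpha length != candidate count")
    w = softmax(alpha, axis=-1)
    out = None
    for i, op in enumerate(candidates):
        y = op(x)
        term = w[i : i + 1] * y if y.ndim == 1 else w[i] * y
        if out is not None and term.shape != out.shape:
            raise ValueError("candidate outputs disagree on shape")
        out = term if out is None else out + term
    return out


class _MixedLSTM(Module):
    """One LSTM per width candidate, each canonicalized to the max width."""

    def __init__(self, d_in: int, candidates, rng):
        self.width = max(candidates)
        self.subs = [LSTM(d_in, u, rng) for u in candidates]
        self.canon = [
            None if u == self.width else Dense(u, self.width, rng)
            for u in candidates
        ]

    def __call__(self, x: Tensor, alpha: Tensor) -> Tensor:
        def make_op(k):
            def op(inp):
                h = self.subs[k](inp)
                return h if self.canon[k] is None else self.canon[k](h)
            return op

        return mixed_forward(x, [make_op(k) for k in range(len(self.subs))], alpha)


class _MixedDense(Module):
    def __init__(self, d_in: int, candidates, rng, activation="relu"):
        self.width = max(candidates)
        self.subs = [Dense(d_in, u, rng, activation=activation) for u in candidates]
        self.canon = [
            None if u == self.width else Dense(u, self.width, rng)
            for u in candidates
        ]

    def __call__(self, x: Tensor, alpha: Tensor) -> Tensor:
        def make_op(k):
            def op(inp):
                h = self.subs[k](inp)
                return h if self.canon[k] is None else self.canon[k](h)
            return op

        return mixed_forward(x, [make_op(k) for k in range(len(self.subs))], alpha)


class _MixedGAT(Module):
    """Grid of (units, heads) GAT sub-layers; the two softmax mixtures factorize."""

    def __init__(self, d_in: int, unit_candidates, head_candidates, rng):
        self.width = max(unit_candidates)
        self.grid = []
        self.canon = []
        for u in unit_candidates:
            row, crow = [], []
            for h in head_candidates:
                if u % h != 0:
                    raise ValueError(f"units {u} not divisible by heads {h}")
                row.append(GATLayer(d_in, u, h, rng))
                crow.append(None if u == self.width else Dense(u, self.width, rng))
            self.grid.append(row)
            self.canon.append(crow)

    def __call__(self, x: Tensor, graph: GraphSpec,
                 alpha_units: Tensor, alpha_heads: Tensor) -> Tensor:
        wu = softmax(alpha_units, axis=-1)
        wh = softmax(alpha_heads, axis=-1)
        out = None
        for iu, row in enumerate(self.grid):
            for ih, gat in enumerate(row):
                y = gat(x, graph)
                if self.canon[iu][ih] is not None:
                    y = self.canon[iu][ih](y)
                term = (wu[iu] * wh[ih]) * y
                out = term if out is None else out + term
        return out


class SuperNet(Module):
    """The full dual-pipeline model with every decision point mixed."""

    def __init__(self, space: SearchSpace, n_channels: int, n_bands: int,
                 rng: np.random.Generator, alpha_init: float = 0.0):
        self.space = space
        self.alphas = {
            name: Tensor(
                np.full(len(getattr(space, name)), alpha_init), requires_grad=True
            )
            for name in space.decision_names()
        }
        self.lstm1 = _MixedLSTM(n_channels, space.lstm_units_1, rng)
        self.lstm2 = _MixedLSTM(self.lstm1.width, space.lstm_units_2, rng)
        self.temporal_attention = TemporalAttention(
            self.lstm2.width, self.lstm2.width, rng
        )
        self.lstm_dense = _MixedDense(self.lstm2.width, space.lstm_dense_units, rng)
        self.gat1 = _MixedGAT(n_bands, space.gcn_units_1, space.attn_heads, rng)
        self.gat2 = _MixedGAT(self.gat1.width, space.gcn_units_2, space.attn_heads, rng)
        self.channel_attention = ChannelAttention(self.gat2.width, rng)
        self.gcn_dense = _MixedDense(self.gat2.width, space.gcn_dense_units, rng)
        # fusion-input projection sized to the (canonical) LSTM dense width
        self.gcn_project = Dense(self.gcn_dense.width, self.lstm_dense.width, rng)
        self.fusion = Fusion(self.lstm_dense.width, rng)
        self.classifier = Dense(self.lstm_dense.width, 4, rng)

    def arch_parameters(self) -> list[Tensor]:
        return list(self.alphas.values())

    def weight_parameters(self) -> list[Tensor]:
        arch_ids = {id(a) for a in self.arch_parameters()}
        return [p for p in self.parameters() if id(p) not in arch_ids]

    def forward(self, de: np.ndarray, time: np.ndarray, graph: GraphSpec) -> Tensor:
        a = self.alphas
        x = Tensor(np.asarray(de, dtype=np.float64))
        h1 = self.gat1(x, graph, a["gcn_units_1"], a["attn_heads"])
        h2 = self.gat2(h1, graph, a["gcn_units_2"], a["attn_heads"])
        z_gcn = self.gcn_dense(h2.mean(axis=1), a["gcn_dense_units"])
        _, att_scaled = self.channel_attention(h2)
        xt = Tensor(np.asarray(time, dtype=np.float64)).swapaxes(1, 2)
        xt = gate_time_input(xt, att_scaled, self.channel_attention.mixing)
        h = self.lstm2(self.lstm1(xt, a["lstm_units_1"]), a["lstm_units_2"])
        ctx, _ = self.temporal_attention(h)
        z_lstm = self.lstm_dense(ctx, a["lstm_dense_units"])
        fused, _ = self.fusion(self.gcn_project(z_gcn), z_lstm)
        return softmax(self.classifier(fused), axis=-1)

    __call__ = forward


def search(
    features: FeaturePair,
    graph: GraphSpec,
    space: SearchSpace,
    epochs: int = 40,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> dict:
    """First-order alternating search; returns the final alpha per decision.

    The supplied windows (training+validation pooled) are split 50/50 with a
    seeded shuffle: network weights are updated on one half, architecture
    parameters on the other, alternating once per epoch.
    """
    n = features.n_windows
    if n < 4:
        raise ValueError("too few windows to split for search")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half_w, half_a = perm[: n // 2], perm[n // 2 :]
    net = SuperNet(space, features.n_channels, features.de.shape[2], rng)
    opt_w = Adam(net.weight_parameters(), lr=lr)
    opt_a = Adam(net.arch_parameters(), lr=lr)

    def run_half(idx, opt):
        order = rng.permutation(len(idx))
        for s in range(0, len(idx), batch_size):
            b = idx[order[s : s + batch_size]]
            probs = net(features.de[b], features.time[b], graph)
            loss = cross_entropy(probs, features.labels[b])
            net.zero_grad()
            loss.backward()
            opt.step()

    for _ in range(epochs):
        run_half(half_w, opt_w)
        run_half(half_a, opt_a)
    return {name: a.data.copy() for name, a in net.alphas.items()}


def discretize(alpha: dict, space: SearchSpace) -> ModelConfig:
    """Argmax per decision point; exact ties go to the smaller candidate."""
    chosen = {}
    for name in space.decision_names():
        cands = getattr(space, name)
        a = np.asarray(alpha[name])
        if len(a) != len(cands):
            raise ValueError(f"{name}: alpha length mismatch")
        best = a.max()
        tied = [cands[i] for i in range(len(cands)) if a[i] == best]
        chosen[name] = min(tied)
    return ModelConfig(use_lstm=True, use_gcn=True, use_ca=True, **chosen)


@dataclass
class SearchResult:
    per_seed: list  # of dicts: {seed, alpha, config, val_accuracy}
    selected_index: int
    selected_config: ModelConfig
    test_accuracy: float | None = None


def retrain_and_select(
    configs: list,
    features: FeaturePair,
    graph: GraphSpec,
    split,
    seeds=None,
    epochs: int = 150,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> SearchResult:
    """Retrain each discretized config from scratch on the 60/20/20 split and
    select the one with the highest validation accuracy; the test accuracy is
    reported only for the selected config."""
    from .evaluation import evaluate, train_model  # avoid circular import

    if not configs:
        raise ValueError("no configs to retrain")
    if seeds is None:
        seeds = list(range(len(configs)))
    records = []
    for cfg, sd in zip(configs, seeds):
        model, history = train_model(
            cfg, features, graph, split, epochs=epochs, lr=lr,
            batch_size=batch_size, seed=sd,
        )
        val_acc = max(h["val_accuracy"] for h in history)
        records.append({"seed": sd, "config": cfg, "model": model,
                        "val_accuracy": val_acc})
    best = int(np.argmax([r["val_accuracy"] for r in records]))
    sel = records[best]
    test_acc = evaluate(sel["model"], features, graph, split.test)
    return SearchResult(
        per_seed=records,
        selected_index=best,
        selected_config=sel["config"],
        test_accuracy=test_acc,
    )


def run_search(
    features: FeaturePair,
    graph: GraphSpec,
    space: SearchSpace,
    split,
    n_seeds: int = 5,
    search_epochs: int = 40,
    train_epochs: int = 150,
    base_seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> SearchResult:
    """Full protocol: repeat the search under ``n_seeds`` seeds on the pooled
    train+validation windows, discretize each result, retrain on the standard
    split, and select by validation accuracy."""
    pooled_idx = np.concatenate([split.train, split.val])
    pooled = features.subset(pooled_idx)
    alphas, configs, seeds = [], [], []
    for k in range(n_seeds):
        sd = base_seed + k
        a = search(pooled, graph, space, epochs=search_epochs, seed=sd,
                   lr=lr, batch_size=batch_size)
        alphas.append(a)
        configs.append(discretize(a, space))
        seeds.append(sd)
    result = retrain_and_select(
        configs, features, graph, split, seeds=seeds,
        epochs=train_epochs, lr=lr, batch_size=batch_size,
    )
    for rec, a in zip(result.per_seed, alphas):
        rec["alpha"] = a
    return result
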