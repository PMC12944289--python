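"""Experimental protocol: window-level splits, per-subject training,
accuracy, ablation runs, electrode ranking and reduction experiments.

All public functions take *raw* (unstandardized) features; the training
routine fits the standardization statistics on its training partition
only and attaches them to the returned model, so downstream evaluation
can never leak validation/test statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import cross_entropy
from .features import FeaturePair, apply_scaler, fit_scaler
from .graph import GraphSpec
from .model import EmotionNet, ModelConfig
from .nn import Adam

log = logging.getLogger(__name__)

__all__ = [
    "SplitIndex",
    "split_windows",
    "train_model",
    "evaluate",
    "rank_electrodes",
    "masked_evaluate",
    "reduction_curve",
    "retrain_with_k",
    "run_ablation",
]


@dataclass
class SplitIndex:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split partitions overlap")


def split_windows(n_windows: int, seed: int, ratios=(0.6, 0.2, 0.2)) -> SplitIndex:
    """Seeded shuffle, then a 6:2:2 partition of window indices.

    Train gets floor(r_train * n); the remainder is balanced between
    validation and test (sizes within one window of the exact proportions).
    """
    if n_windows < 10:
        raise ValueError(f"need at least 10 windows, got {n_windows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_windows)
    n_train = int(np.floor(ratios[0] * n_windows))
    rest = n_windows - n_train
    n_val = rest // 2
    return SplitIndex(
        train=perm[:n_train],
        val=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
    )


def _branch_inputs(config: ModelConfig, features: FeaturePair, idx):
    de = features.de[idx] if config.use_gcn else None
    time = features.time[idx] if config.use_lstm else None
    return de, time


def _accuracy(model: EmotionNet, config, features, graph, idx,
              node_mask=None) -> float:
    de, time = _branch_inputs(config, features, idx)
    pred = model.predict(de, time, graph, node_mask=node_mask)
    return float(np.mean(pred == features.labels[idx]))


def train_model(
    config: ModelConfig,
    features: FeaturePair,
    graph: GraphSpec | None,
    split: SplitIndex,
    epochs: int = 150,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[EmotionNet, list[dict]]:
    """Train one model on the split's training windows.

    Adam at the given learning rate, cross-entropy loss; per-epoch training
    and validation loss/accuracy are logged; the returned model carries the
    weights of the best-validation epoch and the scaler fit on the training
    partition.
    """
    rng = np.random.default_rng(seed)
    scaler = fit_scaler(features.subset(split.train))
    std = apply_scaler(features, scaler)
    model = EmotionNet(config, features.n_channels, features.de.shape[2], rng)
    opt = Adam(model.parameters(), lr=lr)
    history: list[dict] = []
    best_val, best_state = -1.0, None
    for epoch in range(epochs):
        order = rng.permutation(split.train)
        losses, hits, seen = [], 0, 0
        for s in range(0, len(order), batch_size):
            b = order[s : s + batch_size]
            de, time = _branch_inputs(config, std, b)
            probs = model.forward(de, time, graph)
            loss = cross_entropy(probs, std.labels[b])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: check inputs/learning rate"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(b))
            hits += int((probs.data.argmax(-1) == std.labels[b]).sum())
            seen += len(b)
        val_acc = _accuracy(model, config, std, graph, split.val)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.sum(losses) / seen),
                "train_accuracy": hits / seen,
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.state()
    if best_state is not None:
        model.load_state(best_state)
    model.scaler = scaler
    return model, history


def evaluate(model: EmotionNet, features: FeaturePair, graph, idx) -> float:
    """Fraction of correctly classified windows (features standardized with
    the model's own training-partition scaler)."""
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("empty evaluation set")
    std = apply_scaler(features, model.scaler)
    return _accuracy(model, model.config, std, graph, idx)


def rank_electrodes(
    model: EmotionNet, features: FeaturePair, graph, val_idx
) -> pd.DataFrame:
    """Mean scaled channel-attention weight per electrode over validation
    windows, sorted descending (ties broken by channel name)."""
    if not model.config.use_ca:
        raise ValueError("electrode ranking requires a model with channel attention")
    std = apply_scaler(features, model.scaler)
    val_idx = np.asarray(val_idx)
    total = np.zeros(features.n_channels)
    for s in range(0, len(val_idx), 64):
        b = val_idx[s : s + 64]
        _, extras = model.forward(std.de[b], std.time[b], graph, return_extras=True)
        total += extras["channel_attention_scaled"].data.sum(axis=0)
    scores = total / len(val_idx)
    names = features.channel_names or [f"ch{i}" for i in range(features.n_channels)]
    df = pd.DataFrame({"channel": names, "score": scores,
                       "index": np.arange(features.n_channels)})
    return df.sort_values(["score", "channel"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def _as_mask(keep, features: FeaturePair) -> np.ndarray:
    keep = list(keep)
    if len(keep) == 0:
        raise ValueError("keep set must be non-empty")
    mask = np.zeros(features.n_channels, dtype=bool)
    for k in keep:
        if isinstance(k, str):
            mask[features.channel_names.index(k)] = True
        else:
            mask[int(k)] = True
    return mask


def masked_evaluate(
    model: EmotionNet, features: FeaturePair, graph, idx, keep,
    mode: str = "drop",
) -> float:
    """Test accuracy with all channels outside ``keep`` disabled.

    ``mode="drop"`` (default): excluded electrodes are removed from the
    graph neighborhoods (attention renormalized over what remains) and
    zeroed in the time-domain input.  ``mode="zero"``: the graph is left
    intact and the excluded channels' DE and time inputs are zeroed
    instead.  Model weights are untouched in both modes.
    """
    mask = _as_mask(keep, features)
    std = apply_scaler(features, model.scaler)
    idx = np.asarray(idx)
    if mode == "drop":
        return _accuracy(model, model.config, std, graph, idx, node_mask=mask)
    if mode != "zero":
        raise ValueError("mode must be 'drop' or 'zero'")
    zeroed = FeaturePair(
        de=np.where(mask[None, :, None], std.de, 0.0),
        time=np.where(mask[None, :, None], std.time, 0.0),
        labels=std.labels,
        window_s=std.window_s,
        channel_names=list(std.channel_names),
    )
    return _accuracy(model, model.config, zeroed, graph, idx)


def reduction_curve(
    model: EmotionNet,
    features: FeaturePair,
    graph,
    idx,
    ranking: pd.DataFrame,
    ks=None,
    n_random: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Top-K / Bottom-K / Random-K masking accuracies across K.

    Random-K is replicated ``n_random`` times with a seeded generator and
    every replicate is reported (aggregate with a groupby mean).
    """
    n = features.n_channels
    ks = list(ks) if ks is not None else list(range(1, n + 1))
    order = ranking["index"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        rows.append(
            {"K": k, "strategy": "top", "replicate": 0,
             "accuracy": masked_evaluate(model, features, graph, idx, order[:k])}
        )
        rows.append(
            {"K": k, "strategy": "bottom", "replicate": 0,
             "accuracy": masked_evaluate(model, features, graph, idx, order[-k:])}
        )
        for r in range(n_random):
            keep = rng.choice(n, size=k, replace=False)
            rows.append(
                {"K": k, "strategy": "random", "replicate": r,
                 "accuracy": masked_evaluate(model, features, graph, idx, keep)}
            )
    return pd.DataFrame(rows)


def retrain_with_k(
    config: ModelConfig,
    features: FeaturePair,
    graph: GraphSpec,
    ranking: pd.DataFrame,
    k: int,
    split: SplitIndex,
    epochs: int = 150,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[float, EmotionNet]:
    """Retrain from scratch on the top-K electrodes (architecture frozen).

    The feature tensors are restricted to the K retained channels, the
    scaler is refit on the reduced training partition, and the graph is
    rebuilt as the induced subgraph on the retained electrodes (same tau and
    edge selection as the full montage).  Returns test accuracy and the
    retrained model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = np.sort(ranking["index"].to_numpy()[:k])
    reduced = features.restrict_channels(keep)
    sub = graph.subgraph(keep)
    model, _ = train_model(config, reduced, sub, split, epochs=epochs, lr=lr,
                           batch_size=batch_size, seed=seed)
    return evaluate(model, reduced, sub, split.test), model


def run_ablation(
    configs: dict,
    features: FeaturePair,
    graph,
    split: SplitIndex,
    epochs: int = 150,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate a set of named model variants on one split."""
    rows = []
    for name, cfg in configs.items():
        model, history = train_model(cfg, features, graph, split, epochs=epochs,
                                     lr=lr, batch_size=batch_size, seed=seed)
        rows.append(
            {
                "model": name,
                "val_accuracy": max(h["val_accuracy"] for h in history),
                "test_accuracy": evaluate(model, features, graph, split.test),
            }
        )
        log.info("ablation %s: %s", name, rows[-1])
    return pd.DataFrame(rows)
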