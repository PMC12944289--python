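"""Neural-network building blocks on top of the autodiff core.

Small, explicit layer classes; parameters are ``Tensor`` leaves with
``requires_grad=True``, collected recursively via ``Module.parameters()``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax, stack

__all__ = ["Module", "Dense", "LSTM", "TemporalAttention", "Adam", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {s.shape}")
            p.data = s.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    """Affine map with optional pointwise activation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "tanh":
            out = out.tanh()
        elif self.activation == "elu":
            out = out.elu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return out


class LSTM(Module):
    """Single LSTM layer returning the full hidden-state sequence.

    Input [B, T, d_in] -> output [B, T, units].  Forget-gate bias is
    initialized to 1 (standard trick for gradient flow on long windows).
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.W = Tensor(
            glorot(rng, d_in + units, 4 * units), requires_grad=True
        )
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget gate
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((B, u)))
        c = Tensor(np.zeros((B, u)))
        hs = []
        for t in range(T):
            xt = x[:, t, :]
            z = concat([xt, h], axis=-1) @ self.W + self.b
            i = z[:, :u].sigmoid()
            f = z[:, u : 2 * u].sigmoid()
            g = z[:, 2 * u : 3 * u].tanh()
            o = z[:, 3 * u :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return stack(hs, axis=1)


class TemporalAttention(Module):
    """Additive (tanh) attention pooling over the time axis.

    Scores a_t = v^T tanh(W h_t + b); softmax over t; context = sum a_t h_t.
    """

    def __init__(self, d_in: int, d_att: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, d_in, d_att), requires_grad=True)
        self.b = Tensor(np.zeros(d_att), requires_grad=True)
        self.v = Tensor(glorot(rng, d_att, 1), requires_grad=True)

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: [B, T, d] -> (context [B, d], weights [B, T])."""
        scores = ((h @ self.W + self.b).tanh() @ self.v)  # [B, T, 1]
        B, T, _ = scores.shape
        w = softmax(scores.reshape(B, T), axis=-1)  # [B, T]
        ctx = (h * w.reshape(B, T, 1)).sum(axis=1)  # [B, d]
        return ctx, w


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
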