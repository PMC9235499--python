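"""Minimal dense neural-network core: layers with explicit backprop and a
decoupled-weight-decay Adam optimizer with linear warmup.

Sized for desk-scale problems (a few thousand rows, feature widths in the
hundreds); everything is float64 numpy and fully deterministic given the
seed.  Batch normalization uses batch statistics in both training and
inference: all call sites run full batches, which keeps evaluation
deterministic without running-average state.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError


class Param:
    __slots__ = ("value", "grad", "m", "v", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)
        self.decay = decay  # weight matrices decay; biases/BN gains do not


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out), decay=False)
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm:
    """Batch-statistics normalization with learnable gain/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim), decay=False)
        self.beta = Param(np.zeros(dim), decay=False)
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0]
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        return (inv / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def mlp(d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator) -> Sequential:
    """Single hidden-layer perceptron."""
    return Sequential(Linear(d_in, d_hidden, rng), ReLU(), Linear(d_hidden, d_out, rng))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and d(loss)/d(logits) for integer labels."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class AdamW:
    """Adam with decoupled weight decay and linear learning-rate warmup."""

    def __init__(self, params: list[Param], lr: float = 1e-3, warmup_steps: int = 0,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.warmup = warmup_steps
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr = self.lr * min(1.0, self.t / self.warmup) if self.warmup else self.lr
        for p in self.params:
            if not np.all(np.isfinite(p.grad)):
                raise TrainingError("non-finite gradient encountered")
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            mhat = p.m / (1 - self.b1 ** self.t)
            vhat = p.v / (1 - self.b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.decay and self.wd:
                p.value -= lr * self.wd * p.value
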