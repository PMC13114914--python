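"""Neural building blocks (layers, LSTM cell, attention block, Adam).

Built on the package's autodiff core (:mod:`neurotwin._autodiff`).  Layers
follow the familiar module/parameter idiom: each layer exposes
``parameters()`` and a ``__call__`` that consumes and returns ``Tensor``s.
Initialisation is Glorot-uniform driven by an explicit ``numpy`` Generator,
so every model in the package is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "LSTM", "MultiHeadSelfAttention",
    "TransformerBlock", "Adam", "cross_entropy", "sinusoidal_positions",
]


class Module:
    """Base class: recursively collects ``Tensor`` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class LSTM(Module):
    """Single-direction LSTM layer processing a (B, T, D) batch.

    Gate order in the packed weight matrix is (input, forget, cell, output).
    The forget-gate bias starts at 1.0, the usual remedy against early
    gradient vanishing in short-sequence training.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.weight = Tensor(
            _glorot(rng, n_in + hidden, 4 * hidden, (n_in + hidden, 4 * hidden)),
            requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        """Run over a list of T tensors of shape (B, D); returns hidden states."""
        H = self.hidden
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor | None] = [None] * len(xs)
        for t in order:
            z = concat([xs[t], h], axis=1) @ self.weight + self.bias
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out[t] = h
        return out  # type: ignore[return-value]


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention over (B, N, D) token batches.

    The post-softmax attention array (B, H, N, N) of the most recent call is
    kept on ``last_attention`` so training-time regularisers and diagnostics
    can consume it.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(
                f"embedding dim {dim} not divisible by {heads} heads")
        self.dim, self.heads = dim, heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        H, Dh = self.heads, self.dim // self.heads
        qkv = self.qkv(x)                                  # (B, N, 3D)
        q = qkv[:, :, 0 * D:1 * D].reshape(B, N, H, Dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, 1 * D:2 * D].reshape(B, N, H, Dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * D:3 * D].reshape(B, N, H, Dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))
        attn = scores.softmax(axis=-1)                     # (B, H, N, N)
        self.last_attention = attn
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(ctx)


class TransformerBlock(Module):
    """Pre-norm encoder block: LN -> MHSA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())


class Adam:
    """Adam optimiser (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cross_entropy(probs: Tensor, labels: np.ndarray,
                  clamp: float = 1e-12) -> Tensor:
    """Mean categorical cross-entropy of predicted probabilities.

    ``probs`` has classes on the last axis; ``labels`` are integer class
    indices of matching leading shape.  Probabilities are clamped away from
    0/1 before the log, as exact endpoints would make the loss non-finite.
    """
    flat = probs.reshape(-1, probs.shape[-1])
    idx = (np.arange(flat.shape[0]), np.asarray(labels).reshape(-1))
    picked = flat[idx]
    clamped = picked * (1 - 2 * clamp) + clamp
    return -(clamped.log().mean())


def sinusoidal_positions(n: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional encodings (n, dim)."""
    pos = np.arange(n)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float64)
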