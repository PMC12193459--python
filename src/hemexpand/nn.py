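"""Neural-network building blocks on top of :mod:`hemexpand.autodiff`.

Layers follow the usual module pattern: parameters are :class:`Parameter`
tensors discovered by recursive traversal, and a ``training`` flag switches
dropout on and off.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, relu, softmax, sqrt, swapaxes, tmean


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = False

    def parameters(self):
        params = []
        for value in vars(self).items():
            params.extend(_collect(value[1]))
        return params

    def named_parameters(self, prefix=""):
        out = []
        for name, value in vars(self).items():
            out.extend(_collect_named(value, f"{prefix}{name}"))
        return out

    def set_training(self, mode: bool):
        self.training = bool(mode)
        for value in vars(self).values():
            for mod in _collect_modules(value):
                mod.set_training(mode)

    def modules(self):
        out = [self]
        for value in vars(self).values():
            for mod in _collect_modules(value):
                out.extend(mod.modules())
        return out

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.shape)


def _collect(value):
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, prefix):
    if isinstance(value, Parameter):
        return [(prefix, value)]
    if isinstance(value, Module):
        return value.named_parameters(prefix + ".")
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_named(v, f"{prefix}.{i}"))
        return out
    return []


def _collect_modules(value):
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    """Affine map ``x @ W + b`` applied to the trailing dimension."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(glorot(rng, in_dim, out_dim))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LayerNorm(Module):
    """Per-row normalization with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-8):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def normalized(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = tmean(centered * centered, axis=-1, keepdims=True)
        return centered / sqrt(var + self.eps)

    def __call__(self, x: Tensor) -> Tensor:
        return self.normalized(x) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with H parallel heads.

    Per head, ``A_h = softmax(Q_h K_h^T / sqrt(d_k)) V_h``; head outputs are
    concatenated and affinely mixed. The attention weights of the most recent
    forward pass are stashed on ``last_attention`` (shape B x H x T x T) for
    inspection.
    """

    def __init__(self, model_dim: int, n_heads: int, key_dim: int, rng):
        super().__init__()
        self.n_heads = n_heads
        self.key_dim = key_dim
        self.wq = Linear(model_dim, n_heads * key_dim, rng)
        self.wk = Linear(model_dim, n_heads * key_dim, rng)
        self.wv = Linear(model_dim, n_heads * key_dim, rng)
        self.wo = Linear(n_heads * key_dim, model_dim, rng)
        self.last_attention = None

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, H*dk) -> (B, H, T, dk)
        return swapaxes(x.reshape((B, T, self.n_heads, self.key_dim)), 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        scores = (q @ swapaxes(k, -1, -2)) * (1.0 / np.sqrt(self.key_dim))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (B, H, T, dk)
        out = swapaxes(out, 1, 2).reshape((B, T, self.n_heads * self.key_dim))
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, model_dim: int, hidden_dim: int, rng):
        super().__init__()
        self.fc1 = Linear(model_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, model_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class EncoderBlock(Module):
    """Attention -> feed-forward -> residual + layer norm: E = LN(F + A)."""

    def __init__(self, model_dim, n_heads, key_dim, ffn_dim, dropout, rng):
        super().__init__()
        self.attention = MultiHeadAttention(model_dim, n_heads, key_dim, rng)
        self.ffn = FeedForward(model_dim, ffn_dim, rng)
        self.norm = LayerNorm(model_dim)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # residual around attention keeps per-step identity: uniform softmax
        # weights at initialization would otherwise average the sequence away
        attended = x + self.dropout(self.attention(x))
        f = self.dropout(self.ffn(attended))
        return self.norm(f + attended)


def positional_encoding(seq_len: int, dim: int) -> np.ndarray:
    """Sinusoidal position code of shape (seq_len, dim)."""
    pos = np.arange(seq_len)[:, None].astype(float)
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Dropout",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderBlock",
    "positional_encoding",
    "glorot",
    "concat",
]
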