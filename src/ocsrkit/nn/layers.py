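"""Neural-network building blocks on the autodiff engine.

Initialization follows transformer conventions: truncated-normal-like
(std 0.02) weights for linear maps and embeddings, ones/zeros for norms.
Modules share a NumPy ``Generator`` so a model built from (config, seed) is
fully reproducible; dropout draws from the same stream and is disabled in
eval mode.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []

        def walk(key, value):
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    walk(f"{key}.{i}", item)

        for name, value in self.__dict__.items():
            walk(f"{prefix}{name}", value)
        return out

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def walk(value):
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    walk(item)

        for value in self.__dict__.values():
            walk(value)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m._training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m._training = False
        return self

    @property
    def training(self) -> bool:
        return getattr(self, "_training", True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take(np.asarray(ids), axis=0)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class MLP(Module):
    """Two-layer feed-forward block with GELU activation."""

    def __init__(self, dim: int, hidden: int, rng, dropout: float = 0.0):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.fc1(x).gelu()))


class MultiHeadAttention(Module):
    """Scaled dot-product attention over the last two axes.

    Inputs are ``(..., T, dim)``; an optional additive mask broadcastable to
    ``(..., heads, T_q, T_k)`` is applied to the attention logits before the
    softmax (use large negative values to forbid positions).
    """

    def __init__(self, dim: int, n_heads: int, rng, dropout: float = 0.0):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def _split(self, x: Tensor) -> Tensor:
        *batch, t, d = x.shape
        x = x.reshape(*batch, t, self.n_heads, self.head_dim)
        axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
        return x.transpose(axes)  # (..., heads, T, head_dim)

    def _merge(self, x: Tensor) -> Tensor:
        *batch, h, t, hd = x.shape
        axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
        return x.transpose(axes).reshape(*batch, t, h * hd)

    def __call__(self, query: Tensor, key_value: Tensor, mask=None) -> Tensor:
        q = self._split(self.q_proj(query))
        k = self._split(self.k_proj(key_value))
        v = self._split(self.v_proj(key_value))
        logits = q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)
        logits = logits * (1.0 / np.sqrt(self.head_dim))
        if mask is not None:
            logits = logits + Tensor(mask)
        attn = self.drop(logits.softmax(axis=-1))
        return self.out_proj(self._merge(attn @ v))


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding table, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(np.float32)
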