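"""Hierarchical window-attention image backbone.

A 4-stage pyramid: the image is cut into 4x4 patches and linearly embedded;
each stage alternates self-attention within fixed local windows (W-MSA) and
within windows shifted by half a window (SW-MSA), which mixes information
across window boundaries; between stages, 2x2 neighbouring patches are
merged and projected, halving the resolution and doubling the channels.
The final feature map is flattened spatially into the sequence ``S_b``
consumed by the text-side encoder: a 224x224 input with patch size 4 gives
56x56 patches, three merges reduce that to 7x7, so ``S_b`` has 49 positions
with ``8 x embed_dim`` channels.

Shifted windows use the cyclic-shift trick: the map is rolled by half a
window, attention is computed in regular windows, and an additive mask
forbids attention between patches that were not adjacent before the roll.
Window attention carries a learned relative-position bias per head.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor
from .layers import Dropout, LayerNorm, Linear, MLP, Module

_NEG = -1e9


def _window_partition(x: Tensor, window: int) -> Tensor:
    """(B, H, W, C) -> (B, nWh, nWw, window*window, C)."""
    b, h, w, c = x.shape
    x = x.reshape(b, h // window, window, w // window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h // window, w // window, window * window, c)


def _window_merge(x: Tensor, window: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`_window_partition`."""
    b = x.shape[0]
    c = x.shape[-1]
    x = x.reshape(b, h // window, w // window, window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


def _relative_position_index(window: int) -> np.ndarray:
    """Flat index into the (2w-1)^2 bias table for every patch pair."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :] + window - 1  # in [0, 2w-2]
    return (rel[0] * (2 * window - 1) + rel[1]).astype(np.int64)


def _shift_attention_mask(h: int, w: int, window: int, shift: int) -> np.ndarray:
    """Additive mask (nWh, nWw, 1, T, T) for cyclically shifted windows."""
    region = np.zeros((h, w), dtype=np.int64)
    idx = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            region[hs, ws] = idx
            idx += 1
    region = region.reshape(h // window, window, w // window, window)
    region = region.transpose(0, 2, 1, 3).reshape(
        h // window, w // window, window * window
    )
    different = region[:, :, :, None] != region[:, :, None, :]
    return np.where(different, _NEG, 0.0)[:, :, None, :, :].astype(np.float32)


class WindowAttention(Module):
    """Multi-head self-attention within one window, with relative bias."""

    def __init__(self, dim: int, n_heads: int, window: int, rng,
                 dropout: float = 0.0):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.window = window
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        self.rel_bias = Parameter(
            rng.normal(0.0, 0.02, size=((2 * window - 1) ** 2, n_heads))
        )
        self._rel_index = _relative_position_index(window).reshape(-1)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, nwh, nww, t, c = x.shape
        qkv = self.qkv(x).reshape(b, nwh, nww, t, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(4, 0, 1, 2, 5, 3, 6)  # (3, B, nWh, nWw, heads, T, hd)
        q = qkv.take(np.array([0]), axis=0).reshape(
            b, nwh, nww, self.n_heads, t, self.head_dim
        )
        k = qkv.take(np.array([1]), axis=0).reshape(
            b, nwh, nww, self.n_heads, t, self.head_dim
        )
        v = qkv.take(np.array([2]), axis=0).reshape(
            b, nwh, nww, self.n_heads, t, self.head_dim
        )
        logits = (q @ k.transpose(0, 1, 2, 3, 5, 4)) * (1.0 / np.sqrt(self.head_dim))
        bias = self.rel_bias.take(self._rel_index, axis=0)  # (T*T, heads)
        bias = bias.reshape(t, t, self.n_heads).transpose(2, 0, 1)  # (heads, T, T)
        logits = logits + bias
        if mask is not None:
            logits = logits + Tensor(mask)
        attn = self.drop(logits.softmax(axis=-1))
        out = (attn @ v).transpose(0, 1, 2, 4, 3, 5).reshape(b, nwh, nww, t, c)
        return self.out_proj(out)


class SwinBlock(Module):
    """One W-MSA or SW-MSA block: attention + MLP, pre-norm residuals."""

    def __init__(self, dim: int, n_heads: int, resolution: tuple[int, int],
                 window: int, shift: bool, mlp_ratio: float, rng,
                 dropout: float = 0.0):
        h, w = resolution
        if min(h, w) <= window:
            window = min(h, w)  # window covers the whole map: no shift needed
            shift = False
        if h % window or w % window:
            raise ValueError(
                f"window size {window} does not divide feature map {h}x{w}"
            )
        self.resolution = (h, w)
        self.window = window
        self.shift = window // 2 if shift else 0
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, window, rng, dropout)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng, dropout)
        self.drop = Dropout(dropout, rng)
        self._mask = (
            _shift_attention_mask(h, w, window, self.shift) if self.shift else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        h, w = self.resolution
        shortcut = x
        x = self.norm1(x)
        if self.shift:
            x = x.roll((-self.shift, -self.shift), (1, 2))
        x = _window_partition(x, self.window)
        x = self.attn(x, self._mask)
        x = _window_merge(x, self.window, h, w)
        if self.shift:
            x = x.roll((self.shift, self.shift), (1, 2))
        x = shortcut + self.drop(x)
        return x + self.drop(self.mlp(self.norm2(x)))


class PatchMerging(Module):
    """Concatenate 2x2 neighbouring patches and project 4C -> 2C."""

    def __init__(self, dim: int, rng):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.reduce(self.norm(x))


class PatchEmbed(Module):
    """Cut the image into patch_size^2 patches and embed linearly."""

    def __init__(self, patch_size: int, in_channels: int, dim: int, rng):
        self.patch_size = patch_size
        self.proj = Linear(patch_size * patch_size * in_channels, dim, rng)
        self.norm = LayerNorm(dim)

    def __call__(self, images: Tensor) -> Tensor:
        b, h, w, c = images.shape
        p = self.patch_size
        x = images.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // p, w // p, p * p * c)
        return self.norm(self.proj(x))


class SwinBackbone(Module):
    """4-stage window-attention pyramid producing the sequence ``S_b``."""

    def __init__(self, image_size: int, patch_size: int, embed_dim: int,
                 depths, heads, window: int, mlp_ratio: float, rng,
                 dropout: float = 0.0, in_channels: int = 3):
        if image_size % (patch_size * 2 ** (len(depths) - 1)):
            raise ValueError(
                f"image size {image_size} not divisible by "
                f"{patch_size * 2 ** (len(depths) - 1)}"
            )
        self.patch_embed = PatchEmbed(patch_size, in_channels, embed_dim, rng)
        self.pos_drop = Dropout(dropout, rng)
        self.stages: list[list[SwinBlock]] = []
        self.mergers: list[PatchMerging] = []
        side = image_size // patch_size
        dim = embed_dim
        for stage, (depth, n_heads) in enumerate(zip(depths, heads)):
            blocks = [
                SwinBlock(dim, n_heads, (side, side), window,
                          shift=(i % 2 == 1), mlp_ratio=mlp_ratio, rng=rng,
                          dropout=dropout)
                for i in range(depth)
            ]
            self.stages.append(blocks)
            if stage < len(depths) - 1:
                self.mergers.append(PatchMerging(dim, rng))
                dim *= 2
                side //= 2
        self.norm = LayerNorm(dim)
        self.out_dim = dim
        self.out_len = side * side

    def __call__(self, images: Tensor) -> Tensor:
        """(B, H, W, 3) float image -> S_b of shape (B, L, C_b)."""
        x = self.pos_drop(self.patch_embed(images))
        for stage, blocks in enumerate(self.stages):
            for block in blocks:
                x = block(x)
            if stage < len(self.stages) - 1:
                x = self.mergers[stage](x)
        b, h, w, c = x.shape
        return self.norm(x.reshape(b, h * w, c))
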