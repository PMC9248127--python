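"""Text-side transformer: feature encoder and autoregressive decoder.

The encoder adds a fixed sinusoidal positional encoding to the (projected)
backbone sequence and applies standard layers of self-attention + MLP, each
sublayer followed by a residual connection and layer normalization
(post-norm).  The decoder stacks masked self-attention, cross-attention
over the encoder output, and an MLP per layer, with the same residual/norm
arrangement, followed by a linear head over the vocabulary.  The causal
mask guarantees that logits at position *i* depend only on tokens at
positions < *i* of the shifted input.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import (
    Dropout, Embedding, LayerNorm, Linear, MLP, Module, MultiHeadAttention,
    sinusoidal_positions,
)

_NEG = -1e9


class EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, hidden: int, rng,
                 dropout: float = 0.0):
        self.attn = MultiHeadAttention(d_model, n_heads, rng, dropout)
        self.norm1 = LayerNorm(d_model)
        self.mlp = MLP(d_model, hidden, rng, dropout)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x)))
        return self.norm2(x + self.mlp(x))


class Encoder(Module):
    def __init__(self, d_model: int, n_layers: int, n_heads: int, hidden: int,
                 max_positions: int, rng, dropout: float = 0.0):
        self.layers = [
            EncoderLayer(d_model, n_heads, hidden, rng, dropout)
            for _ in range(n_layers)
        ]
        self.drop = Dropout(dropout, rng)
        self.positions = sinusoidal_positions(max_positions, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        t = x.shape[-2]
        x = self.drop(x + Tensor(self.positions[:t]))
        for layer in self.layers:
            x = layer(x)
        return x


class DecoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, hidden: int, rng,
                 dropout: float = 0.0):
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng, dropout)
        self.norm1 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng, dropout)
        self.norm2 = LayerNorm(d_model)
        self.mlp = MLP(d_model, hidden, rng, dropout)
        self.norm3 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, memory: Tensor, causal_mask) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x, causal_mask)))
        x = self.norm2(x + self.drop(self.cross_attn(x, memory)))
        return self.norm3(x + self.mlp(x))


class Decoder(Module):
    def __init__(self, vocab_size: int, d_model: int, n_layers: int,
                 n_heads: int, hidden: int, max_len: int, rng,
                 dropout: float = 0.0):
        self.embed = Embedding(vocab_size, d_model, rng)
        self.positions = sinusoidal_positions(max_len, d_model)
        self.layers = [
            DecoderLayer(d_model, n_heads, hidden, rng, dropout)
            for _ in range(n_layers)
        ]
        self.head = Linear(d_model, vocab_size, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, token_ids: np.ndarray, memory: Tensor) -> Tensor:
        """(B, T) token ids + (B, L, d_model) memory -> (B, T, vocab) logits."""
        t = token_ids.shape[-1]
        mask = np.triu(np.full((t, t), _NEG, dtype=np.float32), k=1)
        x = self.drop(self.embed(token_ids) + Tensor(self.positions[:t]))
        for layer in self.layers:
            x = layer(x, memory, mask)
        return self.head(x)
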