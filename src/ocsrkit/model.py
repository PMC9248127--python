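"""The image-to-sequence recognition model and its configuration.

The model maps a binary molecule depiction to a DeepSMILES token sequence:

1. a hierarchical window-attention backbone turns the image into the
   feature sequence ``S_b`` (49 positions x 8*embed_dim channels for a
   224x224 input),
2. a learned linear map projects ``S_b`` to the text dimension and six
   standard encoder layers produce ``S_e``,
3. six masked decoder layers consume the growing token prefix and ``S_e``
   and a linear + softmax head emits per-position token logits.

Greedy decoding appends the arg-max token (lowest id on ties) until the end
marker or the length cap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn.autodiff import Tensor
from .nn.layers import Linear, Module
from .nn.swin import SwinBackbone
from .nn.transformer import Decoder, Encoder


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Backbone stage depths/heads default to the large-model convention that
    accompanies an embedding width of 192; :meth:`tiny` gives a desk-scale
    configuration for tests and demonstrations.
    """

    vocab_size: int
    image_size: int = 224
    patch_size: int = 4
    backbone_embed_dim: int = 192
    stage_depths: tuple = (2, 2, 18, 2)
    stage_heads: tuple = (6, 12, 24, 48)
    window_size: int = 7
    d_model: int = 256
    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    n_heads_transformer: int = 8
    mlp_ratio: float = 4.0
    dropout: float = 0.1
    max_len: int = 150

    def __post_init__(self):
        merges = len(self.stage_depths) - 1
        divisor = self.patch_size * 2**merges
        if self.image_size % divisor:
            raise ValueError(
                f"image_size {self.image_size} must be divisible by {divisor}"
            )
        if self.d_model % self.n_heads_transformer:
            raise ValueError("d_model must be divisible by n_heads_transformer")
        for dim_mult, heads in zip((1, 2, 4, 8), self.stage_heads):
            if (self.backbone_embed_dim * dim_mult) % heads:
                raise ValueError("stage dims must be divisible by stage heads")

    @property
    def backbone_out_dim(self) -> int:
        return self.backbone_embed_dim * 2 ** (len(self.stage_depths) - 1)

    @property
    def backbone_out_len(self) -> int:
        side = self.image_size // (self.patch_size * 2 ** (len(self.stage_depths) - 1))
        return side * side

    @classmethod
    def tiny(cls, vocab_size: int, image_size: int = 64, max_len: int = 48,
             **overrides) -> "ModelConfig":
        """Desk-scale configuration: small dims, 2 layers everywhere."""
        defaults = dict(
            vocab_size=vocab_size,
            image_size=image_size,
            backbone_embed_dim=48,
            stage_depths=(2, 2, 2, 2),
            stage_heads=(2, 4, 8, 16),
            window_size=4,
            d_model=128,
            n_encoder_layers=2,
            n_decoder_layers=2,
            n_heads_transformer=4,
            mlp_ratio=2.0,
            dropout=0.0,
            max_len=max_len,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["stage_depths"] = tuple(d["stage_depths"])
        d["stage_heads"] = tuple(d["stage_heads"])
        return cls(**d)


class OCSRModel(Module):
    """Backbone + encoder + autoregressive decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = SwinBackbone(
            config.image_size, config.patch_size, config.backbone_embed_dim,
            config.stage_depths, config.stage_heads, config.window_size,
            config.mlp_ratio, rng, config.dropout,
        )
        self.input_proj = Linear(self.backbone.out_dim, config.d_model, rng)
        self.encoder = Encoder(
            config.d_model, config.n_encoder_layers, config.n_heads_transformer,
            int(config.d_model * config.mlp_ratio),
            max_positions=self.backbone.out_len, rng=rng, dropout=config.dropout,
        )
        self.decoder = Decoder(
            config.vocab_size, config.d_model, config.n_decoder_layers,
            config.n_heads_transformer, int(config.d_model * config.mlp_ratio),
            config.max_len, rng, config.dropout,
        )

    # ------------------------------------------------------------- components
    def backbone_forward(self, images) -> Tensor:
        """Images (B, H, W, 3) in [0, 1] -> feature sequence S_b (B, L, C_b)."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:3] != (self.config.image_size, self.config.image_size):
            raise ValueError(
                f"expected {self.config.image_size}x{self.config.image_size} "
                f"images, got {images.shape[1:3]}"
            )
        return self.backbone(Tensor(images))

    def project_and_encode(self, s_b: Tensor) -> Tensor:
        """S_b -> S_e: linear projection, positional encoding, encoder stack."""
        return self.encoder(self.input_proj(s_b))

    def decode_logits(self, prefix_ids: np.ndarray, s_e: Tensor,
                      pad_id: int | None = None,
                      end_id: int | None = None) -> Tensor:
        """Token prefix (B, T) + S_e -> logits (B, T, vocab).

        When ``pad_id`` is given, a pad token occurring before the end
        marker (or before the sequence end, if ``end_id`` is None) is
        rejected: such a prefix cannot arise from a well-formed label.
        """
        prefix_ids = np.asarray(prefix_ids)
        if prefix_ids.ndim == 1:
            prefix_ids = prefix_ids[None]
        if prefix_ids.shape[-1] > self.config.max_len:
            raise ValueError("prefix longer than max_len")
        if pad_id is not None:
            for row in prefix_ids:
                seq = row.tolist()
                cut = seq.index(end_id) if end_id in seq else len(seq)
                if pad_id in seq[:cut]:
                    raise ValueError("pad token before the end marker in prefix")
        return self.decoder(prefix_ids, s_e)

    def forward(self, images, input_ids: np.ndarray) -> Tensor:
        """Teacher-forcing pass: images + shifted label ids -> logits."""
        return self.decode_logits(input_ids, self.project_and_encode(
            self.backbone_forward(images)))

    __call__ = forward

    # --------------------------------------------------------------- decoding
    def greedy_decode(self, images, start_id: int, end_id: int,
                      max_len: int | None = None) -> list[list[int]]:
        """Arg-max decoding per image; ties break to the lowest token id.

        Returns the generated ids per sequence, without the start marker and
        without the end marker.
        """
        was_training = self.training
        self.eval()
        try:
            max_len = max_len or self.config.max_len
            s_e = self.project_and_encode(self.backbone_forward(images))
            batch = s_e.shape[0]
            seqs = np.full((batch, 1), start_id, dtype=np.int64)
            finished = np.zeros(batch, dtype=bool)
            while seqs.shape[1] < max_len and not finished.all():
                logits = self.decode_logits(seqs, s_e).data[:, -1, :]
                nxt = logits.argmax(axis=-1)  # np.argmax: first (lowest) index on ties
                nxt = np.where(finished, end_id, nxt)
                finished |= nxt == end_id
                seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
            out = []
            for row in seqs[:, 1:]:
                ids = []
                for tok in row.tolist():
                    if tok == end_id:
                        break
                    ids.append(tok)
                out.append(ids)
            return out
        finally:
            if was_training:
                self.train()

    # ------------------------------------------------------------ persistence
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, seed: int = 0) -> "OCSRModel":
        with np.load(path) as archive:
            config = ModelConfig.from_json(
                bytes(archive["__config__"].tolist()).decode())
            model = cls(config, seed=seed)
            params = dict(model.named_parameters())
            for name in archive.files:
                if name == "__config__":
                    continue
                params[name].data = archive[name].astype(np.float32)
        return model
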