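"""Teacher-forced training loop with split learning-rate schedules.

The optimizer is Adam at an initial learning rate of 5e-4 with two
parameter groups: the image backbone follows a cosine decay over the run,
while the text-side transformer (projection, encoder, decoder) follows a
step decay (default x0.5 every 10 epochs).  The loss is selectable between
softmax cross-entropy and the multi-label focal loss.  Checkpoint selection
uses validation exact-match accuracy.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .losses import ce, mfl
from .model import OCSRModel
from .vocab import Vocabulary


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8          # 256 at full scale; desk-scale default
    lr: float = 5e-4
    loss: str = "ce"             # "ce" or "mfl"
    gamma: float = 2.0           # MFL focusing parameter
    alpha: float | np.ndarray = 0.25
    step_size: int = 10          # transformer step-decay interval (epochs)
    step_factor: float = 0.5
    warmup_epochs: int = 0       # linear LR warmup applied to both groups
    grad_clip: float = 1.0
    seed: int = 0
    eval_every: int = 0          # epochs between validation passes (0 = end only)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("ce", "mfl"):
            raise ValueError(f"unknown loss {self.loss!r}")


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base: float, epoch: int, total: int) -> float:
    return base * 0.5 * (1.0 + math.cos(math.pi * epoch / max(1, total)))


def step_lr(base: float, epoch: int, step_size: int, factor: float) -> float:
    return base * factor ** (epoch // step_size)


@dataclass
class EpochLog:
    epoch: int
    loss: float
    backbone_lr: float
    transformer_lr: float
    val_accuracy: float | None = None
    seconds: float = 0.0


@dataclass
class TrainResult:
    history: list[EpochLog] = field(default_factory=list)
    best_val_accuracy: float = -1.0
    best_state: dict | None = None

    def restore_best(self, model: OCSRModel) -> None:
        if self.best_state is not None:
            for name, p in model.named_parameters():
                p.data = self.best_state[name].copy()


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _clip(params, max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train(
    model: OCSRModel,
    samples,
    vocab: Vocabulary,
    config: TrainConfig,
    val_samples=None,
    log=print,
) -> TrainResult:
    """Teacher-forced next-token training over rendered samples.

    ``samples`` are :class:`~ocsrkit.depiction.RenderedSample` objects.  Per
    batch, the decoder is fed ``label_ids[:-1]`` and scored against
    ``label_ids[1:]`` with pad positions masked.  Deterministic for a fixed
    config seed.
    """
    if not samples:
        raise ValueError("empty training set")
    too_long = [s for s in samples if len(s.label_ids) > model.config.max_len]
    if too_long:
        raise ValueError(f"{len(too_long)} labels exceed max_len={model.config.max_len}")

    images = np.stack([s.image for s in samples]).astype(np.float32)
    labels = np.stack([s.label_ids for s in samples])
    rng = np.random.default_rng(config.seed)

    backbone_params = model.backbone.parameters()
    backbone_ids = {id(p) for p in backbone_params}
    transformer_params = [p for p in model.parameters() if id(p) not in backbone_ids]
    opt_backbone = Adam(backbone_params, config.lr)
    opt_transformer = Adam(transformer_params, config.lr)

    loss_fn = ce if config.loss == "ce" else (
        lambda lg, tg, mask: mfl(lg, tg, config.alpha, config.gamma, mask)
    )

    result = TrainResult()
    model.train()
    for epoch in range(config.epochs):
        t0 = time.time()
        warm = (
            min(1.0, (epoch + 1) / config.warmup_epochs)
            if config.warmup_epochs else 1.0
        )
        opt_backbone.lr = warm * cosine_lr(config.lr, epoch, config.epochs)
        opt_transformer.lr = warm * step_lr(
            config.lr, epoch, config.step_size, config.step_factor
        )
        epoch_loss, n_batches = 0.0, 0
        for idx in _batches(len(samples), config.batch_size, rng):
            model.zero_grad()
            ids = labels[idx]
            logits = model.forward(images[idx], ids[:, :-1])
            targets = ids[:, 1:]
            mask = (targets != vocab.pad_id).astype(np.float32)
            loss = loss_fn(logits, targets, mask)
            loss.backward()
            if config.grad_clip:
                _clip(model.parameters(), config.grad_clip)
            opt_backbone.step()
            opt_transformer.step()
            epoch_loss += loss.item()
            n_batches += 1

        entry = EpochLog(
            epoch=epoch,
            loss=epoch_loss / n_batches,
            backbone_lr=opt_backbone.lr,
            transformer_lr=opt_transformer.lr,
            seconds=time.time() - t0,
        )
        is_last = epoch == config.epochs - 1
        if val_samples and (
            is_last or (config.eval_every and (epoch + 1) % config.eval_every == 0)
        ):
            entry.val_accuracy = evaluate_exact_match(model, val_samples, vocab)
            if entry.val_accuracy >= result.best_val_accuracy:
                result.best_val_accuracy = entry.val_accuracy
                result.best_state = {
                    name: p.data.copy() for name, p in model.named_parameters()
                }
        result.history.append(entry)
        if log:
            val = f" val_acc={entry.val_accuracy:.3f}" if entry.val_accuracy is not None else ""
            log(f"epoch {epoch + 1}/{config.epochs} loss={entry.loss:.4f}"
                f" lr_b={entry.backbone_lr:.2e} lr_t={entry.transformer_lr:.2e}"
                f"{val} ({entry.seconds:.1f}s)")
    model.eval()
    return result


def predict_deepsmiles(model: OCSRModel, images, vocab: Vocabulary,
                       batch_size: int = 16) -> list[str]:
    """Greedy-decode a stack of images to DeepSMILES strings."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    out: list[str] = []
    for start in range(0, len(images), batch_size):
        id_seqs = model.greedy_decode(
            images[start : start + batch_size], vocab.start_id, vocab.end_id
        )
        out.extend(vocab.decode(ids) for ids in id_seqs)
    return out


def evaluate_exact_match(model, samples, vocab) -> float:
    preds = predict_deepsmiles(model, np.stack([s.image for s in samples]), vocab)
    refs = [s.record.deepsmiles for s in samples]
    return float(np.mean([p == r for p, r in zip(preds, refs)]))
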