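"""Character-level DeepSMILES vocabulary, label codecs, and token statistics.

Every DeepSMILES character is one token.  The reference inventory of 76
characters (the full character set observed over a multi-million-molecule
corpus) is bundled; vocabularies can also be built directly from a corpus,
in which case they are a subset of the reference inventory.  Three special
markers — start, end, pad — are appended *after* the character tokens so
that character ids are stable whether or not specials are in play.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

# 76-character reference inventory, in reported order.
REFERENCE_TOKENS = (
    "c", "6", ")", "C", "=", "O", "N", "S", "l", "s", "5", "B", "r", "n",
    "[", "H", "+", "]", "%", "1", "0", "/", "\\", "R", "F", "#", "4", "(",
    "9", "-", "@", "L", "3", "8", "2", "'", "G", "a", "7", "Z", ".", "P",
    "t", "Y", "o", "A", "X", "i", "J", "q", "x", "Q", "m", "b", "d", "E",
    "w", "I", "V", "z", "e", "M", ",", "D", "K", "p", "v", "h", "y", "u",
    "g", "k", "T", "W", "U", "f",
)

START, END, PAD = "<start>", "<end>", "<pad>"
SPECIALS = (START, END, PAD)


class VocabError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Ordered character tokens plus start/end/pad markers.

    ``token_to_id`` and ``id_to_token`` are mutually inverse bijections over
    ``tokens + SPECIALS``; specials occupy the last three ids.
    """

    tokens: tuple[str, ...]
    token_to_id: dict = field(repr=False)
    id_to_token: dict = field(repr=False)

    @classmethod
    def from_tokens(cls, tokens) -> "Vocabulary":
        tokens = tuple(tokens)
        if set(tokens) & set(SPECIALS):
            raise VocabError("character tokens collide with special markers")
        if len(set(tokens)) != len(tokens):
            raise VocabError("duplicate tokens")
        ordered = tokens + SPECIALS
        t2i = {t: i for i, t in enumerate(ordered)}
        i2t = {i: t for i, t in enumerate(ordered)}
        return cls(tokens=tokens, token_to_id=t2i, id_to_token=i2t)

    @classmethod
    def from_corpus(cls, labels) -> "Vocabulary":
        """Vocabulary of every character appearing in *labels*, sorted."""
        chars = sorted({ch for label in labels for ch in label})
        if not chars:
            raise VocabError("empty corpus")
        return cls.from_tokens(chars)

    @classmethod
    def reference(cls) -> "Vocabulary":
        """The bundled 76-character inventory (79 ids with specials)."""
        return cls.from_tokens(REFERENCE_TOKENS)

    @property
    def size(self) -> int:
        return len(self.tokens) + len(SPECIALS)

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    def encode(self, deepsmiles: str, max_len: int) -> np.ndarray:
        """``[start] + character ids + [end]``, padded to *max_len*."""
        if len(deepsmiles) + 2 > max_len:
            raise VocabError(
                f"label of length {len(deepsmiles)} does not fit max_len={max_len}"
            )
        ids = [self.start_id]
        for ch in deepsmiles:
            if ch not in self.token_to_id:
                raise VocabError(f"character {ch!r} not in vocabulary")
            ids.append(self.token_to_id[ch])
        ids.append(self.end_id)
        ids.extend([self.pad_id] * (max_len - len(ids)))
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids) -> str:
        """Invert :meth:`encode`: strip specials, stop at the end marker."""
        chars = []
        for i in np.asarray(ids).tolist():
            if i == self.end_id:
                break
            if i in (self.start_id, self.pad_id):
                continue
            if i not in self.id_to_token:
                raise VocabError(f"id {i} not in vocabulary")
            chars.append(self.id_to_token[i])
        return "".join(chars)

    def save(self, path) -> None:
        """One token per line, character tokens first, specials last."""
        with open(path, "w") as fh:
            for t in self.tokens + SPECIALS:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            lines = [line.rstrip("\n") for line in fh]
        if tuple(lines[-3:]) != SPECIALS:
            raise VocabError(f"{path}: missing special markers")
        return cls.from_tokens(lines[:-3])


@dataclass
class TokenFrequencyTable:
    """Per-token occurrence counts over a corpus of labels."""

    counts: dict
    total: int

    def sorted_counts(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def token_frequencies(labels) -> TokenFrequencyTable:
    counter: Counter = Counter()
    for label in labels:
        counter.update(label)
    return TokenFrequencyTable(counts=dict(counter), total=sum(counter.values()))


def alpha_weights(
    table: TokenFrequencyTable,
    vocab: Vocabulary,
    scheme: str = "uniform",
    alpha0: float = 0.25,
    smoothing: float = 1.0,
) -> np.ndarray:
    """Per-class focal-loss weighting factors over the vocabulary ids.

    ``uniform`` gives every class ``alpha0``.  ``inverse_frequency`` gives
    weights proportional to ``1 / (count + smoothing)``, normalized to mean
    1, upweighting the long tail of rare tokens.
    """
    if scheme == "uniform":
        return np.full(vocab.size, alpha0, dtype=np.float64)
    if scheme == "inverse_frequency":
        counts = np.array(
            [table.counts.get(vocab.id_to_token[i], 0) for i in range(vocab.size)],
            dtype=np.float64,
        )
        w = 1.0 / (counts + smoothing)
        return w / w.mean()
    raise ValueError(f"unknown alpha scheme {scheme!r}")
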