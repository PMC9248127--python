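"""Evaluation protocol: four sequence/structure metrics plus stratification.

* **Exact-match accuracy** — predicted and reference DeepSMILES agree at
  every character (a length mismatch is a miss).
* **Tanimoto similarity** — both strings are decoded back to SMILES and
  fingerprinted with a deterministic path-based binary fingerprint;
  similarity is |A∩B| / |A∪B| over the set bits.  An undecodable
  prediction scores 0 and is flagged invalid.
* **BLEU** — corpus-level BLEU up to 4-grams with brevity penalty, over
  character tokens.
* **ROUGE-L** — mean per-pair F-measure of the longest common subsequence.

Reports additionally stratify exact-match accuracy by corpus category and
by reference-string length bin, and carry the two validity rates: the
fraction of predictions that parse as DeepSMILES, and the fraction that
decode all the way to a valid molecule.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import canonicalize, ChemError
from .deep_smiles import DeepSmilesError, from_deepsmiles

LENGTH_BINS = ((1, 25), (26, 50), (51, 75), (76, 100))

_FP_GENERATORS = {}


def fingerprint_bits(smiles: str, scheme: str = "path", n_bits: int = 2048):
    """Set of on-bit indices of a binary molecular fingerprint."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES {smiles!r}")
    if scheme not in _FP_GENERATORS:
        if scheme == "path":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
        elif scheme == "morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        else:
            raise ValueError(f"unknown fingerprint scheme {scheme!r}")
        _FP_GENERATORS[scheme] = gen
    fp = _FP_GENERATORS[scheme].GetFingerprint(mol)
    return set(fp.GetOnBits())


def exact_match_accuracy(predictions, references) -> float:
    """Fraction of byte-identical prediction/reference string pairs."""
    if len(predictions) != len(references):
        raise ValueError("prediction/reference length mismatch")
    if not references:
        return 0.0
    return float(np.mean([p == r for p, r in zip(predictions, references)]))


def decode_to_smiles(deepsmiles: str) -> str | None:
    """DeepSMILES -> canonical SMILES, or None if either step fails."""
    try:
        return canonicalize(from_deepsmiles(deepsmiles))
    except (DeepSmilesError, ChemError):
        return None


def tanimoto_similarity(pred_deepsmiles: str, ref_deepsmiles: str,
                        fingerprint_scheme: str = "path") -> float:
    """Fingerprint Tanimoto between decoded molecules; invalid prediction -> 0."""
    ref_smiles = decode_to_smiles(ref_deepsmiles)
    if ref_smiles is None:
        raise ValueError(f"reference does not decode: {ref_deepsmiles!r}")
    pred_smiles = decode_to_smiles(pred_deepsmiles)
    if pred_smiles is None:
        return 0.0
    a = fingerprint_bits(pred_smiles, fingerprint_scheme)
    b = fingerprint_bits(ref_smiles, fingerprint_scheme)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _ngrams(tokens, n):
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(predictions, references, max_n: int = 4) -> float:
    """Corpus BLEU with brevity penalty over token sequences (or strings)."""
    if len(predictions) != len(references):
        raise ValueError("prediction/reference length mismatch")
    matched = [0] * max_n
    total = [0] * max_n
    pred_len = ref_len = 0
    for pred, ref in zip(predictions, references):
        pred, ref = list(pred), list(ref)
        pred_len += len(pred)
        ref_len += len(ref)
        for n in range(1, max_n + 1):
            pn = _ngrams(pred, n)
            rn = _ngrams(ref, n)
            matched[n - 1] += sum(min(c, rn[g]) for g, c in pn.items())
            total[n - 1] += max(0, len(pred) - n + 1)
    # drop n-gram orders with no candidate n-grams anywhere in the corpus
    # (all sequences shorter than n): the effective maximum order shrinks
    orders = [(m, t) for m, t in zip(matched, total) if t > 0]
    if pred_len == 0 or not orders or any(m == 0 for m, _ in orders):
        return 0.0
    log_precision = sum(math.log(m / t) for m, t in orders) / len(orders)
    brevity = 1.0 if pred_len >= ref_len else math.exp(1.0 - ref_len / pred_len)
    return brevity * math.exp(log_precision)


def _lcs_length(a, b) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(predictions, references) -> float:
    """Mean per-pair ROUGE-L F-measure over token sequences (or strings)."""
    if len(predictions) != len(references):
        raise ValueError("prediction/reference length mismatch")
    if not references:
        return 0.0
    scores = []
    for pred, ref in zip(predictions, references):
        pred, ref = list(pred), list(ref)
        lcs = _lcs_length(pred, ref)
        if lcs == 0:
            scores.append(0.0)
            continue
        p, r = lcs / len(pred), lcs / len(ref)
        scores.append(2 * p * r / (p + r))
    return float(np.mean(scores))


def is_valid_deepsmiles(s: str) -> bool:
    try:
        from_deepsmiles(s)
        return True
    except DeepSmilesError:
        return False


def length_bin(length: int) -> str:
    for lo, hi in LENGTH_BINS:
        if lo <= length <= hi:
            return f"[{lo},{hi}]"
    return f">{LENGTH_BINS[-1][1]}"


@dataclass
class EvalReport:
    """Per-corpus and stratified evaluation metrics."""

    n_evaluated: int
    accuracy: float
    tanimoto: float
    bleu: float
    rouge: float
    valid_deepsmiles_rate: float
    valid_smiles_rate: float
    per_category_accuracy: dict = field(default_factory=dict)
    per_category_count: dict = field(default_factory=dict)
    per_bin_accuracy: dict = field(default_factory=dict)
    per_bin_count: dict = field(default_factory=dict)
    fingerprint_scheme: str = "path"

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "accuracy": self.accuracy,
            "tanimoto": self.tanimoto,
            "bleu": self.bleu,
            "rouge": self.rouge,
            "valid_deepsmiles_rate": self.valid_deepsmiles_rate,
            "valid_smiles_rate": self.valid_smiles_rate,
            "per_category_accuracy": self.per_category_accuracy,
            "per_category_count": self.per_category_count,
            "per_bin_accuracy": self.per_bin_accuracy,
            "per_bin_count": self.per_bin_count,
            "fingerprint_scheme": self.fingerprint_scheme,
        }

    def summary(self) -> str:
        lines = [
            f"evaluated            {self.n_evaluated}",
            f"accuracy             {self.accuracy:.4f}",
            f"tanimoto             {self.tanimoto:.4f}",
            f"BLEU                 {self.bleu:.4f}",
            f"ROUGE-L              {self.rouge:.4f}",
            f"valid DeepSMILES     {self.valid_deepsmiles_rate:.4f}",
            f"valid SMILES         {self.valid_smiles_rate:.4f}",
        ]
        for cat in sorted(self.per_category_accuracy):
            lines.append(
                f"category {cat} accuracy  {self.per_category_accuracy[cat]:.4f}"
                f"  (n={self.per_category_count[cat]})"
            )
        for name in self.per_bin_accuracy:
            lines.append(
                f"length {name:9} acc  {self.per_bin_accuracy[name]:.4f}"
                f"  (n={self.per_bin_count[name]})"
            )
        return "\n".join(lines)


def stratified_report(predictions, references, records,
                      fingerprint_scheme: str = "path") -> EvalReport:
    """Full four-metric report with category and length-bin stratification.

    ``records`` supply the category and the reference length for each pair;
    stratified counts always sum to the evaluated total.
    """
    if not (len(predictions) == len(references) == len(records)):
        raise ValueError("predictions, references and records must align")
    for r in records:
        if r.category not in (1, 2, 3, 4):
            raise ValueError(f"record missing/invalid category: {r!r}")

    hits = [p == r for p, r in zip(predictions, references)]
    tanimotos = [
        tanimoto_similarity(p, r, fingerprint_scheme)
        for p, r in zip(predictions, references)
    ]
    valid_ds = [is_valid_deepsmiles(p) for p in predictions]
    valid_sm = [decode_to_smiles(p) is not None for p in predictions]

    per_cat_hits: dict[int, list[bool]] = {}
    per_bin_hits: dict[str, list[bool]] = {}
    for hit, ref, record in zip(hits, references, records):
        per_cat_hits.setdefault(record.category, []).append(hit)
        per_bin_hits.setdefault(length_bin(len(ref)), []).append(hit)

    return EvalReport(
        n_evaluated=len(predictions),
        accuracy=float(np.mean(hits)) if hits else 0.0,
        tanimoto=float(np.mean(tanimotos)) if tanimotos else 0.0,
        bleu=bleu(predictions, references),
        rouge=rouge_l(predictions, references),
        valid_deepsmiles_rate=float(np.mean(valid_ds)) if valid_ds else 0.0,
        valid_smiles_rate=float(np.mean(valid_sm)) if valid_sm else 0.0,
        per_category_accuracy={
            c: float(np.mean(h)) for c, h in sorted(per_cat_hits.items())
        },
        per_category_count={c: len(h) for c, h in sorted(per_cat_hits.items())},
        per_bin_accuracy={b: float(np.mean(h)) for b, h in per_bin_hits.items()},
        per_bin_count={b: len(h) for b, h in per_bin_hits.items()},
        fingerprint_scheme=fingerprint_scheme,
    )
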