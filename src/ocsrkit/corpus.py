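"""Four-category synthetic molecule corpus with DeepSMILES labels.

The corpus emulates the composition of large patent/literature training sets
for optical chemical structure recognition:

========  ===========  ============
category  substituent  ring form
========  ===========  ============
1         no           Kekulé
2         no           aromatic
3         yes          Kekulé
4         yes          aromatic
========  ===========  ============

Categories 3 and 4 are derived from 1 and 2 by bonding randomly chosen
patent-style substituents and bracket atoms onto the scaffold.  Each record
carries the molecule in its category's ring form together with its
DeepSMILES label, and corpora are split 18:1:1 (train:validation:test)
within each category.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, replace

from .chem import ChemError, SubstituentPools, canonicalize, to_ring_form, attach_substituents
from .deep_smiles import to_deepsmiles

CATEGORY_FORMS = {1: "kekule", 2: "aromatic", 3: "kekule", 4: "aromatic"}
SPLIT_RATIO = (18, 1, 1)
SPLIT_NAMES = ("train", "validation", "test")


@dataclass
class CorpusRecord:
    """One corpus molecule: SMILES in its category ring form + DeepSMILES label."""

    smiles: str
    deepsmiles: str
    category: int
    split: str | None = None


class CorpusError(ValueError):
    pass


# Bundled desk-scale molecule source: common drug-like and heterocyclic
# scaffolds, all with rings of size >= 5 (or acyclic) and at least one
# substitutable hydrogen.  Drives generate_tiny_corpus and the test suite.
FIXTURE_SMILES = (
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "c1ccncc1",
    "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1cnc[nH]1", "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1", "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "C1COCCN1",
    "CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "OCC1OC(O)C(O)C(O)C1O", "NC(Cc1ccccc1)C(=O)O",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O", "O=C(O)c1ccccc1O", "Clc1ccccc1",
    "Fc1ccc(Br)cc1", "O=[N+]([O-])c1ccccc1", "N#Cc1ccccc1",
    "COc1ccc(CCN)cc1", "CCOC(=O)c1ccccc1", "NS(=O)(=O)c1ccc(N)cc1",
    "c1ccc(-c2ccccc2)cc1", "O=C1CCCCC1", "OC1CCCCC1", "C1CCC2CCCCC2C1",
    "c1ccc(Cc2ccccc2)cc1", "CC(C)NCC(O)COc1cccc2ccccc12", "CN1CCCC1",
    "O=C(O)C1CCNCC1", "NCCc1c[nH]cn1", "OCCN1CCOCC1", "Cc1ccc(C)cc1",
    "Cc1cccc(C)c1", "COc1ccccc1", "CSc1ccccc1", "FC(F)(F)c1ccccc1",
    "CC(N)c1ccccc1", "O=Cc1ccccc1", "CC(=O)c1ccccc1", "OCc1ccccc1",
    "NC(=O)c1ccccc1", "O=c1cc[nH]c(=O)[nH]1", "Nc1ncnc2[nH]cnc12",
    "CNC(=O)Cc1ccccc1", "c1ccc(N2CCOCC2)cc1", "C1CC2CCC1CC2",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
)


def make_record(canonical_smiles: str, category: int) -> CorpusRecord:
    """Build a record from an (aromatic-form) canonical SMILES."""
    form_smiles = to_ring_form(canonical_smiles, CATEGORY_FORMS[category])
    return CorpusRecord(
        smiles=form_smiles,
        deepsmiles=to_deepsmiles(form_smiles),
        category=category,
    )


def build_corpus(
    source_smiles,
    sizes_per_category,
    pools: SubstituentPools | None = None,
    rng: random.Random | None = None,
    n_attach_range: tuple[int, int] = (1, 3),
) -> list[CorpusRecord]:
    """Assemble the four-category corpus from a source SMILES list.

    Categories 1/2 take source molecules directly (Kekulé / aromatic form);
    categories 3/4 decorate them with 1-3 substituents drawn from *pools*.
    Within each category the canonical SMILES are unique.  Deterministic for
    a fixed ``rng`` state.

    Raises
    ------
    CorpusError
        If a category cannot be filled from the unique sources available;
        the message names the category and the shortfall.
    """
    if len(sizes_per_category) != 4:
        raise ValueError("sizes_per_category must have exactly 4 entries")
    pools = pools or SubstituentPools()
    rng = rng or random.Random(0)

    sources: list[str] = []
    seen = set()
    for s in source_smiles:
        try:
            can = canonicalize(s)
        except ChemError:
            continue
        if can not in seen:
            seen.add(can)
            sources.append(can)

    records: list[CorpusRecord] = []
    for category, size in zip((1, 2, 3, 4), sizes_per_category):
        shuffled = sources[:]
        rng.shuffle(shuffled)
        chosen: list[CorpusRecord] = []
        used = set()
        for base in shuffled:
            if len(chosen) == size:
                break
            try:
                if category in (3, 4):
                    n_attach = rng.randint(*n_attach_range)
                    decorated = attach_substituents(base, pools, n_attach, rng)
                else:
                    decorated = base
                key = canonicalize(decorated)
                if key in used:
                    continue
                record = make_record(key, category)
            except ChemError:
                continue
            used.add(key)
            chosen.append(record)
        if len(chosen) < size:
            raise CorpusError(
                f"category {category}: only {len(chosen)} of {size} requested "
                f"unique molecules could be built from {len(sources)} sources"
            )
        records.extend(chosen)
    return records


def split_corpus(
    records,
    ratio: tuple[int, int, int] = SPLIT_RATIO,
    rng: random.Random | None = None,
) -> list[CorpusRecord]:
    """Assign train/validation/test splits in *ratio* within each category.

    Integer rounding assigns remainders to the training split, so 20 records
    per category yield exactly 18/1/1 and 1,250,000 yield
    1,125,000/62,500/62,500.  Categories with fewer records than one ratio
    unit are still split proportionally, with a warning.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio parts must be positive")
    rng = rng or random.Random(0)
    unit = sum(ratio)
    out: list[CorpusRecord] = []
    for category in sorted({r.category for r in records}):
        group = [r for r in records if r.category == category]
        n = len(group)
        if n < unit:
            warnings.warn(
                f"category {category} has {n} < {unit} records; "
                "split will be degenerate", stacklevel=2,
            )
        n_val = n * ratio[1] // unit
        n_test = n * ratio[2] // unit
        n_train = n - n_val - n_test
        order = list(range(n))
        rng.shuffle(order)
        names = (
            ["train"] * n_train + ["validation"] * n_val + ["test"] * n_test
        )
        for idx, name in zip(order, names):
            out.append(replace(group[idx], split=name))
    return out


def generate_tiny_corpus(n_per_category: int, seed: int = 0) -> list[CorpusRecord]:
    """Seeded desk-scale corpus from the bundled molecule list.

    Emits ``4 * n_per_category`` records covering all four categories with
    splits assigned; byte-identical for identical seeds.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = random.Random(seed)
    records = build_corpus(FIXTURE_SMILES, [n_per_category] * 4, rng=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return split_corpus(records, rng=rng)


def write_manifest(records, path) -> None:
    """Write records as tab-separated text: smiles, deepsmiles, category, split."""
    with open(path, "w") as fh:
        fh.write("smiles\tdeepsmiles\tcategory\tsplit\n")
        for r in records:
            fh.write(f"{r.smiles}\t{r.deepsmiles}\t{r.category}\t{r.split or ''}\n")


def read_manifest(path) -> list[CorpusRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("smiles\t"):
            raise CorpusError(f"{path}: not a corpus manifest")
        for line in fh:
            smiles, ds, cat, split = line.rstrip("\n").split("\t")
            records.append(CorpusRecord(smiles, ds, int(cat), split or None))
    return records
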