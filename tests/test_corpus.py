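import random
import warnings
from collections import Counter

import pytest

from ocsrkit.chem import SubstituentPools, canonicalize
from ocsrkit.corpus import (
    CorpusError, FIXTURE_SMILES, build_corpus, generate_tiny_corpus,
    read_manifest, split_corpus, write_manifest,
)
from ocsrkit.deep_smiles import from_deepsmiles


class TestBuildCorpus:
    def test_forced_counts_and_uniqueness(self):
        records = build_corpus(
            FIXTURE_SMILES[:10], (2, 2, 2, 2), rng=random.Random(1)
        )
        assert len(records) == 8
        counts = Counter(r.category for r in records)
        assert counts == {1: 2, 2: 2, 3: 2, 4: 2}
        for cat in (1, 2, 3, 4):
            keys = [canonicalize(r.smiles) for r in records if r.category == cat]
            assert len(set(keys)) == len(keys)

    def test_decorated_categories_gain_atoms(self):
        """Category 3/4 molecules carry attached substituents."""
        records = build_corpus(
            FIXTURE_SMILES, (4, 4, 4, 4), rng=random.Random(2)
        )
        from rdkit import Chem

        base_sizes = {
            canonicalize(s): Chem.MolFromSmiles(s).GetNumAtoms()
            for s in FIXTURE_SMILES
        }
        decorated = [r for r in records if r.category in (3, 4)]
        assert decorated
        min_base = min(base_sizes.values())
        for r in decorated:
            n = Chem.MolFromSmiles(r.smiles).GetNumAtoms()
            assert n > min_base  # strictly grew beyond the smallest scaffold

    def test_deterministic_manifest(self, tmp_path):
        a = build_corpus(FIXTURE_SMILES, (3, 3, 3, 3), rng=random.Random(7))
        b = build_corpus(FIXTURE_SMILES, (3, 3, 3, 3), rng=random.Random(7))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_manifest(a, pa)
        write_manifest(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_shortfall_reported(self):
        with pytest.raises(CorpusError, match="category 1"):
            build_corpus(FIXTURE_SMILES[:3], (10, 1, 1, 1), rng=random.Random(0))

    def test_round_trip_invariant_all_records(self):
        records = build_corpus(FIXTURE_SMILES, (3, 3, 3, 3), rng=random.Random(4))
        for r in records:
            assert canonicalize(from_deepsmiles(r.deepsmiles)) == canonicalize(r.smiles)

    def test_ring_form_matches_category(self):
        records = build_corpus(FIXTURE_SMILES, (3, 3, 0, 0), rng=random.Random(4))
        for r in records:
            if r.category == 1:
                assert not any(c in r.smiles for c in "cnos")
        aromatic = [r for r in records if r.category == 2]
        assert any(any(c in r.smiles for c in "cnos") for r in aromatic)


class TestSplitCorpus:
    @pytest.mark.parametrize("n,expected", [
        (20, (18, 1, 1)),
        (40, (36, 2, 2)),
        (1_250_000, (1_125_000, 62_500, 62_500)),
    ])
    def test_ratio_with_remainders_to_train(self, n, expected):
        from ocsrkit.corpus import CorpusRecord

        records = [CorpusRecord(f"s{i}", f"d{i}", 1) for i in range(n)]
        out = split_corpus(records, rng=random.Random(0))
        counts = Counter(r.split for r in out)
        assert (counts["train"], counts["validation"], counts["test"]) == expected

    def test_full_scale_split_totals(self):
        from ocsrkit.corpus import CorpusRecord

        per_cat = 1_250_000 // 500  # scaled 1:500 to stay desk-sized
        records = [
            CorpusRecord(f"s{c}_{i}", "d", c)
            for c in (1, 2, 3, 4) for i in range(per_cat)
        ]
        out = split_corpus(records, rng=random.Random(0))
        counts = Counter(r.split for r in out)
        assert counts["train"] == 4 * per_cat * 18 // 20
        assert counts["validation"] == counts["test"] == 4 * per_cat // 20

    def test_partitions_disjoint_and_exhaustive(self, tiny_records):
        # every record carries exactly one split and totals are conserved
        assert all(r.split in ("train", "validation", "test") for r in tiny_records)
        assert len(tiny_records) == sum(
            1 for r in tiny_records if r.split in ("train", "validation", "test")
        )

    def test_small_category_warns(self):
        from ocsrkit.corpus import CorpusRecord

        records = [CorpusRecord(f"s{i}", "d", 1) for i in range(5)]
        with pytest.warns(UserWarning, match="category 1"):
            split_corpus(records, rng=random.Random(0))

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_corpus([], ratio=(18, 0, 1))


class TestTinyCorpus:
    def test_counts_and_categories(self, tiny_records):
        assert len(tiny_records) == 24
        assert Counter(r.category for r in tiny_records) == {1: 6, 2: 6, 3: 6, 4: 6}

    def test_label_lengths_span_two_bins(self, tiny_records):
        bins = set()
        for r in tiny_records:
            n = len(r.deepsmiles)
            for lo, hi in ((1, 25), (26, 50), (51, 75), (76, 100)):
                if lo <= n <= hi:
                    bins.add((lo, hi))
        assert len(bins) >= 2

    def test_contains_bracket_atom(self):
        records = generate_tiny_corpus(8, seed=1)
        assert any("[" in r.deepsmiles for r in records)

    def test_seed_determinism(self, tiny_records):
        assert generate_tiny_corpus(6, seed=1) == tiny_records
        assert generate_tiny_corpus(6, seed=2) != tiny_records


def test_manifest_round_trip(tmp_path, tiny_records):
    path = tmp_path / "manifest.tsv"
    write_manifest(tiny_records, path)
    assert read_manifest(path) == tiny_records
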