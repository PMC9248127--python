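import numpy as np
import pytest

from ocsrkit.corpus import CorpusRecord, make_record
from ocsrkit.chem import canonicalize
from ocsrkit.deep_smiles import to_deepsmiles
from ocsrkit.metrics import (
    bleu, exact_match_accuracy, fingerprint_bits, length_bin, rouge_l,
    stratified_report, tanimoto_similarity,
)


class TestExactMatch:
    def test_identical_lists(self):
        assert exact_match_accuracy(["ab", "cd"], ["ab", "cd"]) == 1.0

    def test_counting(self):
        preds = ["aa", "bb", "cc", "dX"]
        refs = ["aa", "bb", "cc", "dd"]
        assert exact_match_accuracy(preds, refs) == 0.75

    def test_trailing_token_is_a_miss(self):
        assert exact_match_accuracy(["abcX"], ["abc"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            exact_match_accuracy(["a"], ["a", "b"])


class TestTanimoto:
    def test_identity(self):
        for s in ("CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"):
            ds = to_deepsmiles(canonicalize(s))
            assert tanimoto_similarity(ds, ds) == 1.0

    def test_invalid_prediction_scores_zero(self):
        assert tanimoto_similarity("(((", to_deepsmiles("CCO")) == 0.0
        assert tanimoto_similarity("cccccc9", to_deepsmiles("CCO")) == 0.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_similarity("CCO", "(((")

    def test_matches_independent_bit_set_computation(self):
        """Tanimoto equals |A&B| / |A|B| on independently extracted bit sets."""
        a, b = "CCO", "CCCO"
        bits_a = fingerprint_bits(a)
        bits_b = fingerprint_bits(b)
        expected = len(bits_a & bits_b) / len(bits_a | bits_b)
        got = tanimoto_similarity(to_deepsmiles(a), to_deepsmiles(b))
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0.0 < got < 1.0


class TestBleuRouge:
    def test_identical_corpora(self):
        seqs = ["cccccc6", "CC=O)O"]
        assert bleu(seqs, seqs) == pytest.approx(1.0)
        assert rouge_l(seqs, seqs) == pytest.approx(1.0)

    def test_disjoint_token_sets(self):
        assert bleu(["aaaa"], ["bbbb"]) == 0.0
        assert rouge_l(["aaaa"], ["bbbb"]) == 0.0

    def test_empty_prediction_zero_overlap(self):
        assert bleu([""], ["abc"]) == 0.0
        assert rouge_l([""], ["abc"]) == 0.0

    def test_rouge_matches_hand_lcs(self):
        # pred "acd" vs ref "abc": LCS = "ac" (length 2)
        # precision 2/3, recall 2/3 -> F1 = 2/3
        assert rouge_l(["acd"], ["abc"]) == pytest.approx(2 / 3)

    def test_bleu_brevity_penalty(self):
        # prediction is a strict prefix: all precisions 1, penalized for length
        score = bleu(["abcde"], ["abcdefghij"])
        assert score == pytest.approx(np.exp(1 - 10 / 5))


class TestStratifiedReport:
    def _records(self):
        smiles = ["CCO", "CCN", "CCOC", "CCCN"]
        return [make_record(canonicalize(s), c)
                for s, c in zip(smiles, (1, 2, 3, 4))]

    def test_all_correct_every_stratum_one(self):
        records = self._records()
        refs = [r.deepsmiles for r in records]
        report = stratified_report(refs, refs, records)
        assert report.accuracy == 1.0
        assert report.tanimoto == 1.0
        assert report.bleu == pytest.approx(1.0)
        assert report.rouge == pytest.approx(1.0)
        assert report.valid_deepsmiles_rate == 1.0
        assert report.valid_smiles_rate == 1.0
        assert all(v == 1.0 for v in report.per_category_accuracy.values())
        assert all(v == 1.0 for v in report.per_bin_accuracy.values())

    def test_bin_assignment_bounds(self):
        assert length_bin(10) == "[1,25]"
        assert length_bin(25) == "[1,25]"
        assert length_bin(26) == "[26,50]"
        assert length_bin(80) == "[76,100]"

    def test_stratum_counts_conserve_total(self, tiny_records):
        refs = [r.deepsmiles for r in tiny_records]
        preds = refs[:-1] + ["cccccc6"]
        report = stratified_report(preds, refs, tiny_records)
        assert sum(report.per_category_count.values()) == report.n_evaluated
        assert sum(report.per_bin_count.values()) == report.n_evaluated

    def test_permutation_invariance(self, tiny_records):
        refs = [r.deepsmiles for r in tiny_records]
        preds = ["cccccc6"] * 4 + refs[4:]
        fwd = stratified_report(preds, refs, tiny_records)
        order = np.random.default_rng(0).permutation(len(refs))
        rev = stratified_report(
            [preds[i] for i in order], [refs[i] for i in order],
            [tiny_records[i] for i in order])
        assert fwd.accuracy == rev.accuracy
        assert fwd.tanimoto == pytest.approx(rev.tanimoto)
        assert fwd.per_category_accuracy == rev.per_category_accuracy
        assert fwd.per_bin_accuracy == rev.per_bin_accuracy

    def test_invalid_category_rejected(self):
        record = CorpusRecord("CCO", "CCO", 9)
        with pytest.raises(ValueError):
            stratified_report(["CCO"], ["CCO"], [record])

    def test_exact_match_implies_all_metrics_one(self):
        """For any byte-identical pair, every similarity metric is 1."""
        for s in ("CCO", "c1ccc2[nH]ccc2c1", "CC(=O)Nc1ccc(O)cc1"):
            ds = to_deepsmiles(canonicalize(s))
            assert exact_match_accuracy([ds], [ds]) == 1.0
            assert tanimoto_similarity(ds, ds) == 1.0
            assert bleu([ds], [ds]) == pytest.approx(1.0)
            assert rouge_l([ds], [ds]) == pytest.approx(1.0)
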