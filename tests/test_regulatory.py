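"""Promoter/UTR scanners and the replication-dependency rules."""

import math
import random

import numpy as np
import pytest

from histokit import regulatory
from histokit.errors import InputError
from histokit.seq_io import ExpressionEvidence, reverse_complement
from histokit.synthetic_data import _mutate_stem

CONSENSUS = regulatory.DEFAULT_STEM_LOOP_CONSENSUS


def perfect_utr(offset=10, rng=None):
    rng = rng or random.Random(3)
    spacer = "".join(rng.choices("ACGT", k=offset))
    tail = "".join(rng.choices("CT", k=20))
    return spacer + CONSENSUS + tail


class TestTata:
    def test_tataaa_hit(self):
        upstream = "C" * 50 + "TATAAA" + "C" * 25
        hits = regulatory.scan_tata(upstream)
        assert hits == [-31]

    def test_w_position_accepts_a_and_t(self):
        # TAWAAA: the degenerate W position matches A or T
        assert regulatory.scan_tata("C" * 20 + "TATAAA" + "C" * 10)
        assert regulatory.scan_tata("C" * 20 + "TAAAAA" + "C" * 10)

    def test_non_consensus_rejected(self):
        assert regulatory.scan_tata("C" * 20 + "TACAAA" + "C" * 10) == []

    def test_random_hit_rate_matches_binomial_expectation(self):
        rng = random.Random(12)
        n = 100_000
        seq = "".join(rng.choices("ACGT", k=n))
        hits = regulatory.scan_tata(seq, window=n)
        p = 2 * (1 / 4) ** 6
        expectation = (n - 5) * p
        sigma = math.sqrt((n - 5) * p * (1 - p))
        assert abs(len(hits) - expectation) < 3 * sigma

    def test_overlapping_hits_all_reported(self):
        # TATAAAAA matches at offset 0 (TATAAA) and offset 2 (TAAAAA)
        upstream = "C" * 20 + "TATAAAAA" + "C" * 10
        assert len(regulatory.scan_tata(upstream)) == 2


class TestStemLoop:
    def test_perfect_hairpin_found_at_offset(self):
        hit = regulatory.find_stem_loop(perfect_utr(offset=10))
        assert hit is not None
        assert hit.offset_after_stop == 10
        assert hit.stem_mismatches == 0
        assert hit.element_sequence == CONSENSUS

    def test_three_mismatches_found_but_unstable(self):
        rng = np.random.default_rng(5)
        element = _mutate_stem(CONSENSUS, 3, rng)
        utr = "CCTCC" + element + "CTCTCTCTCT"
        hit = regulatory.find_stem_loop(utr)
        assert hit is not None
        assert hit.stem_mismatches == 3
        assert hit.stability_score < regulatory.DEFAULT_STABILITY_THRESHOLD

    def test_poly_a_has_no_hairpin(self):
        assert regulatory.find_stem_loop("A" * 100) is None

    def test_short_utr_returns_none(self):
        assert regulatory.find_stem_loop("ACGT") is None

    def test_stability_monotone_in_mismatches(self):
        """Breaking stem pairs one at a time never raises the score."""
        element = list(CONSENSUS)
        prev = regulatory.score_hairpin(CONSENSUS)[1]
        for i in range(regulatory.STEM_LEN):
            partner = element[regulatory.ELEMENT_LEN - 1 - i]
            element[i] = next(
                b for b in "ACGT"
                if regulatory.stem_pair_score(b, partner) == regulatory.MISMATCH_SCORE
            )
            mism, score = regulatory.score_hairpin("".join(element))
            assert mism == i + 1
            assert score <= prev
            prev = score

    def test_reverse_complement_does_not_report_same_element(self):
        utr = perfect_utr(offset=12)
        fwd = regulatory.find_stem_loop(utr)
        rev = regulatory.find_stem_loop(reverse_complement(utr))
        assert fwd is not None
        assert rev is None or rev.element_sequence != fwd.element_sequence

    def test_ties_resolved_leftmost(self):
        utr = "CC" + CONSENSUS + "AA" + CONSENSUS + "CC"
        hit = regulatory.find_stem_loop(utr)
        assert hit.offset_after_stop == 2


class TestHde:
    def test_pure_purine_window(self):
        pos, frac = regulatory.scan_hde("GAAAGAGAGA")
        assert (pos, frac) == (0, 1.0)

    def test_pyrimidine_run_rejected(self):
        assert regulatory.scan_hde("CTCTCTCTCT") is None

    def test_random_windows_average_half_purine(self):
        rng = random.Random(9)
        fracs = []
        for _ in range(500):
            window = "".join(rng.choices("ACGT", k=10))
            fracs.append(sum(c in "AG" for c in window) / 10)
        assert abs(sum(fracs) / len(fracs) - 0.5) < 3 * 0.16 / math.sqrt(500)


class TestPolyA:
    def test_first_occurrence_position(self):
        assert regulatory.scan_polyA("CCCCAATAAACC") == 4

    def test_alternative_motif(self):
        assert regulatory.scan_polyA("CCATTAAACC") == 2

    def test_rna_alphabet_rejected(self):
        with pytest.raises(InputError, match="DNA"):
            regulatory.scan_polyA("CCAAUAAACC")

    def test_absent(self):
        assert regulatory.scan_polyA("CCCCGGGG") is None


def _features(gene_id, utr, upstream="C" * 40 + "TATAAA" + "C" * 25):
    return regulatory.compute_utr_features(gene_id, upstream, utr)


class TestDependencyRules:
    def test_canonical_cluster_gene_is_dependent(self):
        utr = "CCTCC" + CONSENSUS + "CTCTC" + "GAGAGAAGAG" + "CCTCC"
        call = regulatory.call_dependency(_features("g", utr))
        assert call.verdict == regulatory.REPLICATION_DEPENDENT
        assert call.rationale

    def test_polya_gene_is_independent(self):
        utr = "CCTCCGCTCC" + "AATAAA" + "CCTCCGCTCCGATCG"
        call = regulatory.call_dependency(_features("g", utr))
        assert call.verdict == regulatory.REPLICATION_INDEPENDENT

    def test_unstable_unexpressed_gene_is_pseudogene_candidate(self):
        rng = np.random.default_rng(5)
        utr = "CCTCC" + _mutate_stem(CONSENSUS, 3, rng) + "CTCTCTCTCTCTC"
        expression = [ExpressionEvidence("g", s, False) for s in ("larva", "male")]
        call = regulatory.call_dependency(_features("g", utr), expression)
        assert call.verdict == regulatory.PSEUDOGENE_CANDIDATE

    def test_expression_rescues_unstable_gene_to_ambiguous(self):
        rng = np.random.default_rng(5)
        utr = "CCTCC" + _mutate_stem(CONSENSUS, 3, rng) + "CTCTCTCTCTCTC"
        expression = [ExpressionEvidence("g", "male", True)]
        call = regulatory.call_dependency(_features("g", utr), expression)
        assert call.verdict == regulatory.AMBIGUOUS

    def test_pure_function_and_rationale(self):
        utr = "CCTCC" + CONSENSUS + "CTCTC" + "GAGAGAAGAG" + "CCTCC"
        f = _features("g", utr)
        a = regulatory.call_dependency(f)
        b = regulatory.call_dependency(f)
        assert a == b
        assert len(a.rationale) >= 1
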