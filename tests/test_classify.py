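"""Family/variant assignment against oracles and known variant hallmarks."""

import functools
import itertools
import random

import pytest
from Bio.Align import substitution_matrices

from histokit import classify
from histokit.errors import InputError
from histokit.seq_io import PROTEIN, SequenceRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXT = 10.0, 1.0


def alignment_score_oracle(a: str, b: str) -> float:
    """Independent best-score search over the alignment space.

    Recursion over (position in a, position in b, state of the previous
    column), where a gap of length L costs GAP_OPEN + GAP_EXT * L; small
    inputs only.
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = GAP_EXT if prev == "A" else GAP_OPEN + GAP_EXT
            options.append(-cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = GAP_EXT if prev == "B" else GAP_OPEN + GAP_EXT
            options.append(-cost + best(i, j + 1, "B"))
        return max(options)

    return best(0, 0, "M")


def enumerate_all_alignments_score(a: str, b: str) -> float:
    """Exhaustive path enumeration (no memoisation) for tiny inputs."""
    best = [float("-inf")]

    def walk(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", score + BLOSUM62[a[i], b[j]])
        if i < len(a):
            cost = GAP_EXT if prev == "A" else GAP_OPEN + GAP_EXT
            walk(i + 1, j, "A", score - cost)
        if j < len(b):
            cost = GAP_EXT if prev == "B" else GAP_OPEN + GAP_EXT
            walk(i, j + 1, "B", score - cost)

    walk(0, 0, "M", 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = classify.global_align("HAK", "HAK")
        assert res.identity == 1.0

    def test_single_substitution(self):
        res = classify.global_align("A", "G")
        assert res.identity == 0.0
        assert res.score == BLOSUM62["A", "G"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            classify.global_align("", "HAK")

    def test_oracle_agreement_exhaustive_short(self):
        """All pairs over a 4-letter sub-alphabet up to length 2, full enumeration."""
        alphabet = "ARND"
        seqs = [
            "".join(t)
            for n in (1, 2)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                expected = enumerate_all_alignments_score(a, b)
                assert classify.global_align(a, b).score == pytest.approx(expected)

    def test_oracle_agreement_random_pairs(self):
        """50 random pairs of length <= 8 against the recursive oracle."""
        rng = random.Random(7)
        alphabet = "ARND"
        for _ in range(50):
            a = "".join(rng.choices(alphabet, k=rng.randint(1, 8)))
            b = "".join(rng.choices(alphabet, k=rng.randint(1, 8)))
            assert classify.global_align(a, b).score == pytest.approx(
                alignment_score_oracle(a, b)
            )

    def test_layered_oracle_consistency(self):
        """The memoised oracle agrees with brute enumeration at tiny sizes."""
        rng = random.Random(1)
        for _ in range(20):
            a = "".join(rng.choices("ARND", k=rng.randint(1, 4)))
            b = "".join(rng.choices("ARND", k=rng.randint(1, 4)))
            assert alignment_score_oracle(a, b) == pytest.approx(
                enumerate_all_alignments_score(a, b)
            )


class TestAssignFamily:
    def test_references_self_classify(self, refs):
        for ref in refs:
            call = classify.assign_family(ref.record, refs)
            assert (call.family, call.variant) == (ref.family, ref.variant)
            assert call.identity == 1.0

    def test_reference_order_invariance(self, refs):
        query = refs.get("H2A", "H2A.X").record
        shuffled = classify.ReferenceSet(tuple(reversed(refs.references)))
        a = classify.assign_family(query, refs)
        b = classify.assign_family(query, shuffled)
        assert (a.family, a.variant, a.score) == (b.family, b.variant, b.score)

    def test_shuffled_h4_unclassified(self, refs):
        """Composition-preserving shuffles fall below the identity floor."""
        h4 = refs.get("H4", "canonical").record.residues
        rng = random.Random(42)
        worst = 0.0
        for i in range(100):
            residues = list(h4)
            rng.shuffle(residues)
            call = classify.assign_family(
                SequenceRecord(f"shuf{i}", "".join(residues), PROTEIN), refs
            )
            worst = max(worst, call.identity)
            assert call.family == classify.UNCLASSIFIED
            assert call.variant == ""
        assert worst < classify.DEFAULT_MIN_IDENTITY

    def test_h2ax_called_from_sq_tail(self, refs):
        rec = refs.get("H2A", "H2A.X").record
        call = classify.assign_family(rec, refs)
        assert call.variant == "H2A.X"
        assert any("SQ tetrad" in e for e in call.evidence)


class TestH2axCterm:
    @pytest.mark.parametrize(
        "tail,match,near",
        [
            ("MHAKSQEY", True, False),
            ("MHAKSQDF", True, False),
            ("MHAKSQIL", True, False),
            ("MHAKSQAY", False, True),
            ("MHAKAQEY", False, False),
            ("MHAKSQEA", False, False),
        ],
    )
    def test_tetrad_states(self, tail, match, near):
        res = classify.h2ax_cterm_check(tail)
        assert (res["match"], res["near_match"]) == (match, near)
        assert res["tetrad"] == tail[-4:]

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            classify.h2ax_cterm_check("SQ")


class TestMacroLength:
    def test_macro_reference_passes(self, refs):
        macro = refs.get("H2A", "macroH2A").record.residues
        canon = refs.get("H2A", "canonical").record.residues
        assert classify.macro_length_check(macro, len(canon))

    def test_canonical_fails(self, refs):
        canon = refs.get("H2A", "canonical").record.residues
        assert not classify.macro_length_check(canon, len(canon))

    def test_short_tag_below_factor(self, refs):
        canon = refs.get("H2A", "canonical").record.residues
        assert not classify.macro_length_check(canon + "G" * 10, len(canon))


class TestH3Diagnostics:
    def test_human_h33_scores_all_sites(self, refs):
        h3 = refs.get("H3", "canonical").record.residues
        h33 = refs.get("H3", "H3.3").record.residues
        report = classify.h3_variant_diagnostics(h33, h3)
        assert report.matches == 5

    def test_self_comparison_scores_zero(self, refs):
        h3 = refs.get("H3", "canonical").record.residues
        assert classify.h3_variant_diagnostics(h3, h3).matches == 0

    def test_site96_reversion_scores_four(self, refs):
        """An H3.3 whose site-96 change is absent scores 4/5."""
        h3 = refs.get("H3", "canonical").record.residues
        h33 = refs.get("H3", "H3.3").record.residues
        reverted = h33[:95] + "C" + h33[96:]
        report = classify.h3_variant_diagnostics(reverted, h3)
        assert report.matches == 4
        assert report.observed(96) == "C"

    def test_gap_at_site_is_indeterminate(self, refs):
        h3 = refs.get("H3", "canonical").record.residues
        h33 = refs.get("H3", "H3.3").record.residues
        deleted = h33[:93] + h33[99:]  # interior deletion spanning site 96
        report = classify.h3_variant_diagnostics(deleted, h3)
        assert report.observed(96) == "-"
        assert report.matches == 4


class TestInventory:
    def test_empty_input(self):
        df = classify.inventory([])
        assert classify.inventory_total(df) == 0
        assert set(df.family) == set(classify.FAMILIES)

    def test_counts_sum_to_inputs(self, refs):
        calls = [classify.assign_family(r.record, refs) for r in refs]
        df = classify.inventory(calls)
        assert classify.inventory_total(df) == len(refs.references)
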