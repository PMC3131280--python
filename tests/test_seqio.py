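"""Sequence, coordinate and structure-file handling."""

import collections

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reifold.seqio import (
    RnaSequence,
    SecondaryStructure,
    SeqFormatError,
    composition,
    composition_percent,
    index_to_neg,
    neg_to_index,
    parse_dotbracket,
    read_ct,
    read_dotbracket,
    read_fasta,
    write_ct,
    write_dotbracket,
    write_fasta,
)

from oracles import random_structure


class TestFasta:
    def test_t_converted_and_case_normalised(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacGT\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACGU"

    def test_multi_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAA\n>b\nCC\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert [len(r) for r in recs] == [2, 2]

    def test_anchor_token_parsed(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">lead anchor=11\nACGUACGUAC\n")
        (rec,) = read_fasta(p)
        assert rec.anchor_index == 11

    def test_ambiguity_code_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nACBD\n")
        with pytest.raises(SeqFormatError) as err:
            read_fasta(p)
        assert "B" in str(err.value)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(SeqFormatError):
            read_fasta(p)

    def test_write_read_roundtrip(self, tmp_path):
        seqs = [
            RnaSequence("a", "ACGUACGU", anchor_index=9),
            RnaSequence("b", "AAAA"),
        ]
        p = tmp_path / "out.fa"
        write_fasta(p, seqs)
        back = read_fasta(p)
        assert [(s.id, s.residues, s.anchor_index) for s in back] == [
            (s.id, s.residues, s.anchor_index) for s in seqs
        ]


class TestCoordinates:
    def test_minus_one_abuts_the_aug(self):
        seq = RnaSequence("lead", "A" * 229, anchor_index=230)
        assert neg_to_index(-1, seq) == 229

    def test_rpe_iv_span_maps_to_printed_indices(self):
        # -129 through -83 with the AUG A at 230 covers indices 101..147
        seq = RnaSequence("lead", "A" * 229, anchor_index=230)
        assert neg_to_index(-129, seq) == 101
        assert neg_to_index(-83, seq) == 147

    def test_out_of_range_rejected(self):
        seq = RnaSequence("lead", "A" * 229, anchor_index=230)
        with pytest.raises(SeqFormatError):
            neg_to_index(-231, seq)
        with pytest.raises(SeqFormatError):
            neg_to_index(0, seq)

    def test_missing_anchor_rejected(self):
        seq = RnaSequence("lead", "ACGUACGU")
        with pytest.raises(SeqFormatError):
            neg_to_index(-1, seq)

    def test_round_trip_identity_everywhere(self):
        seq = RnaSequence("lead", "ACGU" * 12, anchor_index=49)
        for i in range(1, len(seq) + 1):
            assert neg_to_index(index_to_neg(i, seq), seq) == i

    @given(st.text(alphabet="ACGU", min_size=1, max_size=80), st.data())
    def test_round_trip_identity_property(self, residues, data):
        seq = RnaSequence("lead", residues, anchor_index=len(residues) + 1)
        i = data.draw(st.integers(1, len(seq)))
        assert neg_to_index(index_to_neg(i, seq), seq) == i
        assert sum(composition(seq).values()) == pytest.approx(1.0)


class TestComposition:
    def test_uniform(self):
        frac = composition(RnaSequence("x", "ACGU"))
        assert frac == {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        seq = RnaSequence("r", "".join(rng.choice(list("ACGU"), 377)))
        assert sum(composition(seq).values()) == pytest.approx(1.0, abs=0)

    def test_matches_letter_counting_oracle(self):
        rng = np.random.default_rng(1)
        res = "".join(rng.choice(list("ACGU"), 1000, p=[0.4, 0.22, 0.07, 0.31]))
        counts = collections.Counter(res)
        frac = composition(RnaSequence("r", res))
        for b in "ACGU":
            assert frac[b] == counts[b] / 1000

    def test_integer_percent_rounding(self):
        seq = RnaSequence("x", "AAAC")
        assert composition_percent(seq) == {"A": 75, "C": 25, "G": 0, "U": 0}


class TestDotBracket:
    def test_simple_hairpin(self):
        s = parse_dotbracket("(((...)))")
        assert s.pairs == frozenset({(1, 9), (2, 8), (3, 7)})

    def test_open_chain(self):
        assert parse_dotbracket("......").pairs == frozenset()

    def test_unbalanced_rejected(self):
        with pytest.raises(SeqFormatError):
            parse_dotbracket("(()")
        with pytest.raises(SeqFormatError):
            parse_dotbracket("())")

    def test_short_hairpin_rejected(self):
        with pytest.raises(SeqFormatError):
            parse_dotbracket("(.)((..))")

    def test_crossing_pairs_rejected(self):
        with pytest.raises(SeqFormatError):
            SecondaryStructure(12, frozenset({(1, 7), (3, 11)}))

    def test_double_pairing_rejected(self):
        with pytest.raises(SeqFormatError):
            SecondaryStructure(12, frozenset({(1, 7), (1, 11)}))

    def test_roundtrip_on_random_structures(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            s = random_structure(rng, n)
            assert parse_dotbracket(s.dot_bracket).pairs == s.pairs


class TestFileFormats:
    def test_dotbracket_file_roundtrip(self, tmp_path):
        seq = RnaSequence("probe", "GGGAAAACCCAA")
        s = SecondaryStructure(12, frozenset({(1, 10), (2, 9), (3, 8)}), -1.2)
        p = tmp_path / "s.dbn"
        write_dotbracket(p, seq, s)
        seq2, s2 = read_dotbracket(p)
        assert (seq2.residues, s2.pairs, s2.energy) == (seq.residues, s.pairs, -1.2)

    def test_ct_roundtrip_on_random_structures(self, tmp_path):
        rng = np.random.default_rng(11)
        p = tmp_path / "s.ct"
        for k in range(50):
            n = int(rng.integers(5, 50))
            s = random_structure(rng, n)
            seq = RnaSequence("r", "".join(rng.choice(list("ACGU"), n)))
            write_ct(p, seq, s)
            seq2, s2 = read_ct(p)
            assert s2.pairs == s.pairs
            assert seq2.residues == seq.residues

    def test_ct_inconsistency_rejected(self, tmp_path):
        p = tmp_path / "bad.ct"
        p.write_text("2 x\n1 A 0 2 2 1\n2 U 1 0 0 2\n")  # 1-2 not reciprocal
        with pytest.raises(SeqFormatError):
            read_ct(p)
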