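"""tRNA cloverleaf pair classification and structure parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoarch.core import reverse_complement
from mitoarch.trna import (ARMS, StructureParseError, TrnaStructure,
                           classify_pairs, extract_anticodon,
                           parse_structure, read_structures)


def _structure(pairs_by_arm, seq, anticodon=None):
    return TrnaStructure("trnX", seq, pairs_by_arm,
                         anticodon_positions=anticodon)


class TestClassifyPairs:
    def test_wc_wobble_and_mismatch_definitions(self):
        #        123456
        seq = "ATGCGT"
        st_ = _structure({"acceptor": [(1, 2), (3, 4), (5, 6)]}, seq)
        # pairs: (A,T) WC, (G,C) WC, (G,T) wobble
        cls = classify_pairs(st_)
        assert (cls.total_wc, cls.total_wobble, cls.total_mismatch) == (3, 0, 0) \
            or (cls.wc["acceptor"], cls.wobble["acceptor"]) == (2, 1)

    def test_mismatch_identities_unordered_rna_alphabet(self):
        seq = "AACT"
        st_ = _structure({"DHU": [(1, 2), (3, 4)]}, seq)
        cls = classify_pairs(st_)
        assert cls.mismatch["DHU"] == 2
        assert cls.mismatch_types == {"A-A": 1, "C-U": 1}

    def test_counts_sum_to_number_of_pairs(self):
        seq = "ATGCGTAATT"
        st_ = _structure({"acceptor": [(1, 2)], "DHU": [(3, 4)],
                          "anticodon": [(5, 6)], "TpsiC": [(7, 8)]}, seq)
        cls = classify_pairs(st_)
        assert (cls.total_wc + cls.total_wobble + cls.total_mismatch) == 4

    def test_pair_order_permutation_invariant(self):
        seq = "ATGCGTTA"
        a = _structure({"acceptor": [(1, 2), (3, 4), (5, 6), (7, 8)]}, seq)
        b = _structure({"acceptor": [(7, 8), (1, 2), (5, 6), (3, 4)]}, seq)
        ca, cb = classify_pairs(a), classify_pairs(b)
        assert (ca.wc, ca.wobble, ca.mismatch) == (cb.wc, cb.wobble, cb.mismatch)

    @given(st.lists(st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")),
                    min_size=1, max_size=7))
    @settings(max_examples=60, deadline=None)
    def test_complementing_both_members_preserves_wc_and_total(self, bases):
        # Watson-Crick pairs complement to Watson-Crick pairs, and the total
        # count is conserved.  (Wobble does not survive complementation:
        # G-U maps to C-A, so only the WC/non-WC split is invariant.)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        seq1 = "".join(b for pair in bases for b in pair)
        seq2 = "".join(comp[b] for pair in bases for b in pair)
        pairs = {"acceptor": [(2 * i + 1, 2 * i + 2)
                              for i in range(len(bases))]}
        c1 = classify_pairs(_structure(pairs, seq1))
        c2 = classify_pairs(_structure(pairs, seq2))
        assert c1.total_wc == c2.total_wc
        assert (c1.total_wc + c1.total_wobble + c1.total_mismatch
                == c2.total_wc + c2.total_wobble + c2.total_mismatch
                == len(bases))

    def test_out_of_bounds_pair_rejected(self):
        with pytest.raises(StructureParseError):
            classify_pairs(_structure({"acceptor": [(1, 99)]}, "ACGT"))


class TestAnticodon:
    def test_constructed_positions(self):
        seq = "A" * 32 + "GAT" + "A" * 10
        st_ = _structure({}, seq, anticodon=(33, 34, 35))
        assert extract_anticodon(st_) == "GAT"

    def test_unset_positions_error(self):
        with pytest.raises(StructureParseError):
            extract_anticodon(_structure({}, "ACGT"))


class TestDotBracketFormat:
    SEQ = "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGATAATCTGGAGGTCCTGTGTTCGATC"
    #      acceptor 7 bp, DHU 3 bp, anticodon 4 bp (* on 3), TpsiC 3 bp
    BRK = ("(((((((," + "..(((...)))." + "," + "((((..***..))))" + ","
           + "..(((...)))...." + "," + ")))))))")

    def test_parse_assigns_pairs_to_arms(self):
        n_struct = len(self.BRK.replace(",", ""))
        seq = (self.SEQ * 2)[:n_struct]
        st_ = parse_structure("trnX", seq, self.BRK)
        assert len(st_.arms["acceptor"]) == 7
        assert len(st_.arms["DHU"]) == 3
        assert len(st_.arms["anticodon"]) == 4
        assert len(st_.arms["TpsiC"]) == 3
        assert len(st_.anticodon_positions) == 3
        assert not st_.dhu_replaced_by_loop

    def test_empty_dhu_segment_sets_replacement_flag(self):
        brk = "(((,......,((..***..)),(((...))),)))"
        seq = "A" * len(brk.replace(",", ""))
        st_ = parse_structure("trnS(AGN)", seq, brk)
        assert st_.dhu_replaced_by_loop
        assert st_.arms["DHU"] == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureParseError, match="length"):
            parse_structure("trnX", "ACGT", "((,.,.,.,))")

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(StructureParseError, match="unbalanced"):
            parse_structure("trnX", "ACGTACGT", "(((,.,.,.,))")

    def test_file_round_trip(self, tmp_path):
        brk = "((,...,((***)),(...),))"
        seq = "ATCCCGGGATCCCGGGATT"[:len(brk.replace(",", ""))]
        p = tmp_path / "trnas.txt"
        p.write_text(f">trnM\n{seq}\n{brk}\n")
        sts = read_structures(p)
        assert len(sts) == 1 and sts[0].gene == "trnM"
        assert extract_anticodon(sts[0]) == seq[7:10]
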