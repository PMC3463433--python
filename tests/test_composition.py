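"""Composition, skew, and codon-usage statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoarch.composition import (CODON_FAMILIES, base_composition,
                                  codon_usage, composition_by_codon_position,
                                  pcg_sense_sequences, rscu,
                                  record_composition_table, skew_scatter,
                                  CodonUsageTable)
from mitoarch.core import ValidationError, reverse_complement

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestBaseComposition:
    def test_symmetric_sequences_have_zero_skew(self):
        assert base_composition("AATT").at_skew == 0
        assert base_composition("GGCC").gc_skew == 0

    def test_at_skew_direct_evaluation(self):
        assert base_composition("AAAT").at_skew == pytest.approx(0.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            base_composition("")

    def test_missing_bases_give_nan_skew_not_zero(self):
        comp = base_composition("AATT")
        assert math.isnan(comp.gc_skew)

    def test_n_residues_excluded_from_denominator(self):
        comp = base_composition("AANN")
        assert comp.a_pct == 100.0

    @given(SEQ)
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, seq):
        c = base_composition(seq)
        assert c.a_pct + c.c_pct + c.g_pct + c.t_pct == pytest.approx(100, abs=0.01)

    @given(SEQ)
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_negates_both_skews(self, seq):
        fwd = base_composition(seq)
        rev = base_composition(reverse_complement(seq))
        for a, b in [(fwd.at_skew, rev.at_skew), (fwd.gc_skew, rev.gc_skew)]:
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(-b)


class TestCodonPositionComposition:
    def test_position_one_of_repeated_codon(self):
        rows = composition_by_codon_position(["ATAATA"])
        assert rows[0].a_pct == 100.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=3 * rng.integers(5, 40)))
                for _ in range(6)]
        rows = composition_by_codon_position(seqs)
        for k in range(3):
            tally = Counter()
            for s in seqs:
                for i in range(k, len(s), 3):
                    tally[s[i]] += 1
            n = sum(tally.values())
            assert rows[k].a_pct == pytest.approx(100 * tally["A"] / n)
            assert rows[k].t_pct == pytest.approx(100 * tally["T"] / n)

    def test_length_not_multiple_of_three_names_gene(self):
        with pytest.raises(ValidationError, match="nad2"):
            composition_by_codon_position({"nad2": "ATGA"})


class TestRscu:
    def test_uniform_family_gives_rscu_one(self):
        counts = {c: 0 for fam in CODON_FAMILIES.values() for c in fam}
        for c in CODON_FAMILIES["P"]:  # proline box CCN
            counts[c] = 5
        table = rscu(CodonUsageTable(counts))
        for c in CODON_FAMILIES["P"]:
            assert table.rscu[c] == pytest.approx(1.0)

    def test_single_used_codon_takes_whole_family_weight(self):
        counts = {c: 0 for fam in CODON_FAMILIES.values() for c in fam}
        fam = CODON_FAMILIES["V"]
        counts[fam[0]] = 4
        table = rscu(CodonUsageTable(counts))
        assert table.rscu[fam[0]] == pytest.approx(4.0)
        assert all(table.rscu[c] == 0 for c in fam[1:])

    def test_zero_count_family_yields_nan(self):
        counts = {c: 0 for fam in CODON_FAMILIES.values() for c in fam}
        table = rscu(CodonUsageTable(counts))
        assert all(math.isnan(v) for v in table.rscu.values())

    def test_leu_and_ser_families_are_split(self):
        assert len(CODON_FAMILIES["Leu(UUR)"]) == 2
        assert len(CODON_FAMILIES["Leu(CUN)"]) == 4
        assert len(CODON_FAMILIES["Ser(UCN)"]) == 4
        assert len(CODON_FAMILIES["Ser(AGN)"]) == 4  # AGA/AGG are Ser here
        n_codons = sum(len(f) for f in CODON_FAMILIES.values())
        assert n_codons == 62  # 64 minus the two stops of table 5

    def test_rscu_family_sums_equal_family_size(self, synthetic_genome):
        rec, _ = synthetic_genome
        table = codon_usage(pcg_sense_sequences(rec))
        for fam, codons in table.families.items():
            if sum(table.counts[c] for c in codons):
                assert sum(table.rscu[c] for c in codons) == \
                    pytest.approx(len(codons))

    def test_codons_per_thousand_sum_to_1000(self, synthetic_genome):
        rec, _ = synthetic_genome
        table = codon_usage(pcg_sense_sequences(rec))
        assert sum(table.per_thousand.values()) == pytest.approx(1000, abs=0.01)

    def test_usage_total_matches_count_codons(self, synthetic_genome):
        from mitoarch.annotation import count_codons
        rec, _ = synthetic_genome
        table = codon_usage(pcg_sense_sequences(rec))
        assert table.total == count_codons(rec)


class TestSkewScatter:
    def test_points_match_base_composition(self, synthetic_genome):
        rec, _ = synthetic_genome
        pts = skew_scatter([rec])
        comp = base_composition(rec.sequence)
        assert pts.at_skew[0] == pytest.approx(comp.at_skew)
        assert pts.gc_skew[0] == pytest.approx(comp.gc_skew)

    def test_all_g_genome_has_unit_gc_skew(self):
        from mitoarch.core import GenomeRecord
        pts = skew_scatter([GenomeRecord("g", "G" * 50)])
        assert pts.gc_skew[0] == 1.0


def test_composition_table_rows_present(synthetic_genome):
    rec, _ = synthetic_genome
    df = record_composition_table(rec)
    assert list(df["region"][:2]) == ["whole genome", "protein-coding genes"]
    assert "A+T-rich region" in set(df["region"])
    assert ((df["A%"] + df["C%"] + df["G%"] + df["T%"]).round(1) == 100).all()
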