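"""Overlap/spacer accounting and gene-order rearrangement classification."""

import itertools

import numpy as np
import pytest

from mitoarch.architecture import (ANCESTRAL_INSECT_ORDER,
                                   LEPIDOPTERA_DITRYSIAN_ORDER, GeneOrder,
                                   classify_rearrangements,
                                   conservation_check, extract_gene_order,
                                   find_intergenic_spacers, find_overlaps,
                                   pairwise_gap)
from mitoarch.core import FeatureAnnotation, GenomeRecord, ValidationError


def _feat(gene, start, end, strand="J", cls="tRNA"):
    return FeatureAnnotation(gene, cls, strand, start, end)


class TestPairwiseGap:
    def test_overlap_between_trnw_and_trnc(self):
        f1 = _feat("trnW", 1227, 1292)
        f2 = _feat("trnC", 1285, 1351, "N")
        assert pairwise_gap(f1, f2, 16173) == -8

    def test_contiguous_features_have_zero_gap(self):
        assert pairwise_gap(_feat("trnA", 1, 10), _feat("trnR", 11, 20), 100) == 0

    def test_yunnanensis_trni_trnq_spacer(self):
        assert pairwise_gap(_feat("trnI", 1, 67),
                            _feat("trnQ", 95, 163, "N"), 15816) == 27

    def test_wrap_around_origin(self):
        # last feature ends at 95 of 100; first starts at 3
        assert pairwise_gap(_feat("rrnS", 60, 95, cls="rRNA"),
                            _feat("trnI", 3, 40), 100) == 7


class TestOverlapsAndSpacers:
    def test_renzhiensis_three_overlaps(self, renzhiensis):
        rep = find_overlaps(renzhiensis)
        got = {(e.upstream, e.downstream): e.length for e in rep.entries}
        assert got == {("trnW", "trnC"): 8, ("trnK", "trnD"): 1,
                       ("atp8", "atp6"): 7}
        assert rep.total == 16

    def test_spacer_totals(self, renzhiensis, yunnanensis):
        assert find_intergenic_spacers(renzhiensis).total == 49
        assert find_intergenic_spacers(yunnanensis).total == 81

    def test_yunnanensis_named_spacers(self, yunnanensis):
        rep = find_intergenic_spacers(yunnanensis)
        got = {(e.upstream, e.downstream): e.length for e in rep.entries}
        assert got[("trnI", "trnQ")] == 27
        assert got[("trnS(UCN)", "nad1")] == 15

    def test_disjoint_features_no_overlaps(self):
        rec = GenomeRecord("x", length=100, features=[
            _feat("trnI", 1, 30), _feat("trnQ", 31, 60, "N"),
            _feat("trnM", 61, 100)])
        assert find_overlaps(rec).entries == []
        assert find_intergenic_spacers(rec).entries == []

    def test_random_records_match_brute_force_adjacent_scan(self):
        rng = np.random.default_rng(42)
        genes = sorted(set(f"g{i}" for i in range(12)))
        for _ in range(25):
            bounds = np.sort(rng.choice(np.arange(1, 400), size=24,
                                        replace=False))
            feats = []
            for i in range(12):
                s, e = int(bounds[2 * i]), int(bounds[2 * i + 1])
                # jitter starts backwards to create overlaps
                s = max(1, s - int(rng.integers(0, 5)))
                feats.append(FeatureAnnotation(genes[i], "tRNA", "J",
                                               min(s, e), max(s, e)))
            feats.sort(key=lambda f: f.start)
            L = 450
            rec = GenomeRecord("r", length=L, features=feats)
            ov = find_overlaps(rec)
            sp = find_intergenic_spacers(rec)
            # brute force over adjacent circular pairs
            exp_ov = exp_sp = 0
            for i in range(12):
                f1, f2 = feats[i], feats[(i + 1) % 12]
                if i < 11:
                    gap = f2.start - f1.end - 1
                else:
                    gap = (L - f1.end) + (f2.start - 1)
                exp_ov += max(0, -gap)
                exp_sp += max(0, gap)
            assert ov.total == exp_ov
            assert sp.total == exp_sp

    def test_conservation_identity_on_both_tables(self, renzhiensis,
                                                  yunnanensis):
        assert conservation_check(renzhiensis)
        assert conservation_check(yunnanensis)


class TestGeneOrder:
    def test_renzhiensis_order_is_ancestral(self, renzhiensis):
        assert extract_gene_order(renzhiensis) == ANCESTRAL_INSECT_ORDER

    def test_rotation_invariance(self, renzhiensis):
        order = extract_gene_order(renzhiensis)
        rotated = GeneOrder(order.genes[7:] + order.genes[:7])
        assert rotated == order

    def test_ditrysian_differs_only_in_trni_trnq_trnm_block(self):
        anc = {g: ANCESTRAL_INSECT_ORDER.context(g)
               for g in ANCESTRAL_INSECT_ORDER.names()}
        dit = {g: LEPIDOPTERA_DITRYSIAN_ORDER.context(g)
               for g in LEPIDOPTERA_DITRYSIAN_ORDER.names()}
        changed = {g for g in anc if anc[g] != dit[g]}
        assert changed <= {"trnI", "trnQ", "trnM", "nad2", "at_rich_region"}

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            GeneOrder((("trnI", "J"), ("trnI", "J")))


class TestClassifyRearrangements:
    def test_identical_orders_yield_no_events(self):
        assert classify_rearrangements(ANCESTRAL_INSECT_ORDER,
                                       ANCESTRAL_INSECT_ORDER) == []

    def test_ditrysian_is_single_trnm_translocation(self):
        events = classify_rearrangements(LEPIDOPTERA_DITRYSIAN_ORDER,
                                         ANCESTRAL_INSECT_ORDER)
        assert [(e.gene, e.kind) for e in events] == \
            [("trnM", "translocation")]

    def test_invariant_under_rotation_of_either_order(self):
        rot = GeneOrder(LEPIDOPTERA_DITRYSIAN_ORDER.genes[5:]
                        + LEPIDOPTERA_DITRYSIAN_ORDER.genes[:5])
        events = classify_rearrangements(rot, ANCESTRAL_INSECT_ORDER)
        assert [(e.gene, e.kind) for e in events] == \
            [("trnM", "translocation")]

    def test_strand_flip_in_place_is_local_inversion(self):
        flipped = GeneOrder(tuple(
            (g, "J" if g == "trnC" else s)
            for g, s in ANCESTRAL_INSECT_ORDER.genes))
        events = classify_rearrangements(flipped, ANCESTRAL_INSECT_ORDER)
        assert [(e.gene, e.kind) for e in events] == \
            [("trnC", "local_inversion")]

    def test_moved_and_flipped_is_remote_inversion(self):
        base = GeneOrder((("cox1", "J"), ("trnA", "J"), ("trnB", "J"),
                          ("trnC2", "N"), ("trnD", "J")))
        moved = GeneOrder((("cox1", "J"), ("trnC2", "J"), ("trnA", "J"),
                           ("trnB", "J"), ("trnD", "J")))
        events = classify_rearrangements(moved, base)
        assert [(e.gene, e.kind) for e in events] == \
            [("trnC2", "remote_inversion")]

    def test_gene_set_mismatch_lists_difference(self):
        a = GeneOrder((("cox1", "J"), ("trnA", "J")))
        b = GeneOrder((("cox1", "J"), ("trnB", "J")))
        with pytest.raises(ValidationError, match="trnA"):
            classify_rearrangements(a, b)

    def test_minimal_mover_matches_exhaustive_search_on_small_orders(self):
        rng = np.random.default_rng(3)
        genes = [("cox1", "J")] + [(f"trn{c}", "J") for c in "ABDEFG"]
        base = GeneOrder(tuple(genes))
        for _ in range(20):
            perm = list(genes)
            i, j = rng.choice(range(1, 7), size=2, replace=False)
            gene = perm.pop(i)
            perm.insert(j, gene)
            obs = GeneOrder(tuple(perm))
            events = classify_rearrangements(obs, base)
            # exhaustive: smallest removal set making circular orders equal
            best = None
            for k in range(0, 4):
                for S in itertools.combinations([g for g, _ in genes[1:]], k):
                    if obs.without(S) == base.without(S):
                        best = k
                        break
                if best is not None:
                    break
            assert len(events) == best
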