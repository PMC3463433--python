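"""Genome architecture: gene order, overlaps, intergenic spacers, and tRNA
rearrangement classification.

Rearrangements of single genes between two circular gene orders fall into
three classes: *translocation* (the gene moved to a new neighbour context,
same strand), *local inversion* (same neighbours, strand flipped) and
*remote inversion* (moved and flipped).  The classifier reports a minimal
set of "mover" genes whose removal reconciles the two circular orders, so a
gene whose context changed only because its neighbour moved is not itself
reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core import CONTROL_REGION, GenomeRecord, ValidationError, feature_length

__all__ = [
    "GeneOrder", "RearrangementEvent", "GapEntry", "SpacerReport",
    "OverlapReport", "ANCESTRAL_INSECT_ORDER", "LEPIDOPTERA_DITRYSIAN_ORDER",
    "pairwise_gap", "find_overlaps", "find_intergenic_spacers",
    "extract_gene_order", "classify_rearrangements", "conservation_check",
]


@dataclass(frozen=True)
class GeneOrder:
    """A circular sequence of (gene, strand) pairs in genomic order.

    Equality is rotation-invariant; the canonical rotation aligns on cox1,
    which is present and unmoved in all known lepidopteran arrangements.
    """

    genes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [g for g, _ in self.genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate genes in order: {sorted(dupes)}")

    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def rotate_to(self, gene: str) -> "GeneOrder":
        names = self.names()
        if gene not in names:
            raise KeyError(gene)
        i = names.index(gene)
        return GeneOrder(self.genes[i:] + self.genes[:i])

    def canonical(self) -> "GeneOrder":
        names = self.names()
        anchor = "cox1" if "cox1" in names else min(names)
        return self.rotate_to(anchor)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if len(self.genes) != len(other.genes):
            return False
        if not self.genes:
            return True
        doubled = other.genes + other.genes
        return any(doubled[i:i + len(self.genes)] == self.genes
                   for i in range(len(other.genes)))

    def __hash__(self):
        return hash(frozenset(self.genes))

    def context(self, gene: str) -> tuple[str, str]:
        """(left neighbour, right neighbour) of a gene in circular order."""
        names = self.names()
        i = names.index(gene)
        n = len(names)
        return names[(i - 1) % n], names[(i + 1) % n]

    def strand(self, gene: str) -> str:
        for g, s in self.genes:
            if g == gene:
                return s
        raise KeyError(gene)

    def without(self, remove) -> "GeneOrder":
        rm = set(remove)
        return GeneOrder(tuple(p for p in self.genes if p[0] not in rm))


def _order(pairs) -> GeneOrder:
    return GeneOrder(tuple(pairs))


#: The Drosophila yakuba arrangement, inferred ancestral for Insecta, in the
#: conventional linearization (trnI first, control region last).
ANCESTRAL_INSECT_ORDER = _order([
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnL(UUR)", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS(AGN)", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
    ("trnH", "N"), ("nad4", "N"), ("nad4L", "N"), ("trnT", "J"),
    ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS(UCN)", "J"),
    ("nad1", "N"), ("trnL(CUN)", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"), (CONTROL_REGION, "J"),
])

#: The derived arrangement of all ditrysian Lepidoptera: trnM translocated
#: upstream of trnI-trnQ.
LEPIDOPTERA_DITRYSIAN_ORDER = _order(
    [("trnM", "J"), ("trnI", "J"), ("trnQ", "N")]
    + [p for p in ANCESTRAL_INSECT_ORDER.genes
       if p[0] not in ("trnI", "trnQ", "trnM")])

REFERENCE_ORDERS = {
    "ancestral": ANCESTRAL_INSECT_ORDER,
    "ditrysian": LEPIDOPTERA_DITRYSIAN_ORDER,
}


# ---------------------------------------------------------------------------
# Overlap / spacer accounting

def pairwise_gap(f1, f2, genome_length: int) -> int:
    """Signed gap between consecutive features: ``start(f2) - end(f1) - 1``.

    Negative values denote overlap of that many bp.  When f2 is the first
    feature after the origin the wrap is ``(L - end(f1)) + (start(f2) - 1)``.
    """
    if f2.start > f1.start or (f2.start == f1.start and f2.end >= f1.end):
        return f2.start - f1.start - (f1.end - f1.start + 1)
    # f2 precedes f1 in linear coordinates: the pair spans the origin
    return (genome_length - f1.end) + (f2.start - 1)


@dataclass
class GapEntry:
    upstream: str
    downstream: str
    length: int
    sequence: str | None = None


@dataclass
class OverlapReport:
    entries: list[GapEntry] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(e.length for e in self.entries)


@dataclass
class SpacerReport:
    entries: list[GapEntry] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(e.length for e in self.entries)


def _consecutive_pairs(record: GenomeRecord):
    feats = record.features
    for i, f1 in enumerate(feats):
        f2 = feats[(i + 1) % len(feats)]
        yield f1, f2, pairwise_gap(f1, f2, record.length)


def find_overlaps(record: GenomeRecord) -> OverlapReport:
    """All overlaps between consecutive features in circular order."""
    rep = OverlapReport()
    if not record.features:
        return rep
    for f1, f2, gap in _consecutive_pairs(record):
        if gap < 0:
            seq = None
            if record.sequence is not None:
                seq = record.sequence[f2.start - 1:f2.start - 1 - gap]
            rep.entries.append(GapEntry(f1.gene, f2.gene, -gap, seq))
    return rep


def find_intergenic_spacers(record: GenomeRecord) -> SpacerReport:
    """All positive inter-feature gaps in circular order.

    The control region must be present as a feature so that its interior is
    never counted; the reported total is the genome's noncoding complement
    outside the A+T-rich region when the table includes it.
    """
    rep = SpacerReport()
    if not record.features:
        return rep
    for f1, f2, gap in _consecutive_pairs(record):
        if gap > 0:
            seq = None
            if record.sequence is not None:
                s = f1.end % record.length  # 0-based start of the gap
                seq = (record.sequence + record.sequence)[s:s + gap]
            rep.entries.append(GapEntry(f1.gene, f2.gene, gap, seq))
    return rep


def conservation_check(record: GenomeRecord) -> bool:
    """Verify sum(feature lengths) + spacers - overlaps == genome length."""
    total = sum(feature_length(f, record.length) for f in record.features)
    total += find_intergenic_spacers(record).total
    total -= find_overlaps(record).total
    return total == record.length


# ---------------------------------------------------------------------------
# Gene order and rearrangement classification

def extract_gene_order(record: GenomeRecord) -> GeneOrder:
    """The circular (gene, strand) order of a validated record."""
    return GeneOrder(tuple((f.gene, f.strand) for f in record.features))


@dataclass
class RearrangementEvent:
    """A single-gene rearrangement relative to a reference order."""

    gene: str
    kind: str  # translocation | local_inversion | remote_inversion
    from_context: tuple[str, str]
    to_context: tuple[str, str]


def _classify_one(gene: str, reference: GeneOrder, observed: GeneOrder) -> RearrangementEvent:
    ctx_ref = reference.context(gene)
    ctx_obs = observed.context(gene)
    flipped = reference.strand(gene) != observed.strand(gene)
    moved = ctx_ref != ctx_obs
    if flipped and not moved:
        kind = "local_inversion"
    elif moved and not flipped:
        kind = "translocation"
    elif moved and flipped:
        kind = "remote_inversion"
    else:  # unchanged gene should never be classified
        raise ValidationError(f"{gene}: no rearrangement detected")
    return RearrangementEvent(gene, kind, ctx_ref, ctx_obs)


def classify_rearrangements(observed: GeneOrder, reference: GeneOrder,
                            max_movers: int = 6) -> list[RearrangementEvent]:
    """Minimal set of single-gene rearrangement events between two orders.

    Both orders must cover the same gene set (the control region is part of
    the order when present in both).  The smallest set of genes whose removal
    makes the circular orders identical is reported, ties broken in favour
    of tRNA movers (tRNAs are empirically the common movers).
    """
    obs_set = set(observed.names())
    ref_set = set(reference.names())
    if obs_set != ref_set:
        raise ValidationError(
            f"gene sets differ: {sorted(obs_set ^ ref_set)}")
    if observed == reference:
        return []
    # candidate movers: genes whose neighbour context or strand differs
    candidates = [g for g in reference.names()
                  if reference.context(g) != observed.context(g)
                  or reference.strand(g) != observed.strand(g)]

    def tie_break(subset):
        return sum(0 if g.startswith("trn") else 1 for g in subset)

    for k in range(1, min(max_movers, len(candidates)) + 1):
        hits = [S for S in itertools.combinations(candidates, k)
                if observed.without(S) == reference.without(S)]
        if hits:
            best = min(hits, key=tie_break)
            order_index = {g: i for i, g in enumerate(observed.names())}
            return [_classify_one(g, reference, observed)
                    for g in sorted(best, key=order_index.get)]
    raise ValidationError(
        f"orders not reconcilable by removing up to {max_movers} genes")
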