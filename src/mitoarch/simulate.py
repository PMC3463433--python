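"""Synthetic circular insect mitogenomes with ground-truth annotations.

The generator emulates the statistical structure the analysis modules
assume: a 37-gene circular genome plus A+T-rich region, strong A+T bias,
AT-biased codon usage in the 13 PCGs, planned gene overlaps (by default the
canonical 7-bp atp8/atp6 overlap), truncated stop codons abutting the
downstream gene, and a control-region tandem-repeat array with a fractional
trailing copy.  tRNA and rRNA sequences are placeholders — random A+T-biased
strings of realistic length carrying a planted anticodon — because their
folding is out of scope; they exist to exercise coordinates, gene order and
spacer/overlap accounting.

Every draw flows from one :class:`numpy.random.Generator`, so a fixed seed
yields a byte-identical genome.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import INVERTEBRATE_MITO, STOP_LENGTH
from .architecture import (ANCESTRAL_INSECT_ORDER, REFERENCE_ORDERS, GeneOrder)
from .core import (CONTROL_REGION, FeatureAnnotation, GenomeRecord,
                   ValidationError, infer_feature_class, reverse_complement)

__all__ = ["SyntheticGenomeSpec", "generate_genome", "generate_control_region"]

#: canonical anticodons of the 22 insect mitochondrial tRNAs (DNA alphabet)
CANONICAL_ANTICODONS = {
    "trnI": "GAT", "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA",
    "trnC": "GCA", "trnY": "GTA", "trnL(UUR)": "TAA", "trnK": "CTT",
    "trnD": "GTC", "trnG": "TCC", "trnA": "TGC", "trnR": "TCG",
    "trnN": "GTT", "trnS(AGN)": "TCT", "trnE": "TTC", "trnF": "GAA",
    "trnH": "GTG", "trnT": "TGT", "trnP": "TGG", "trnS(UCN)": "TGA",
    "trnL(CUN)": "TAG", "trnV": "TAC",
}

#: per-gene length targets (bp), mirroring a typical hepialid mitogenome
DEFAULT_GENE_LENGTHS = {
    "trnI": 65, "trnQ": 69, "trnM": 70, "nad2": 1018, "trnW": 66,
    "trnC": 67, "trnY": 67, "cox1": 1531, "trnL(UUR)": 69, "cox2": 682,
    "trnK": 71, "trnD": 65, "atp8": 162, "atp6": 677, "cox3": 789,
    "trnG": 66, "nad3": 352, "trnA": 69, "trnR": 66, "trnN": 66,
    "trnS(AGN)": 60, "trnE": 65, "trnF": 66, "nad5": 1738, "trnH": 67,
    "nad4": 1341, "nad4L": 293, "trnT": 66, "trnP": 64, "nad6": 524,
    "cob": 1146, "trnS(UCN)": 73, "nad1": 933, "trnL(CUN)": 71,
    "rrnL": 1335, "trnV": 65, "rrnS": 779,
}

DEFAULT_START_CODONS = {
    "nad2": "ATT", "cox1": "CGA", "cox2": "ATG", "atp8": "ATA",
    "atp6": "ATG", "cox3": "ATG", "nad3": "ATT", "nad5": "ATT",
    "nad4": "ATG", "nad4L": "ATG", "nad6": "ATA", "cob": "ATG",
    "nad1": "TTG",
}

#: PCGs forced to end on an incomplete stop abutting the downstream gene
DEFAULT_TRUNCATED_STOPS = {
    "nad2": "T--", "cox1": "T--", "cox2": "T--", "nad3": "T--",
    "nad5": "T--", "atp6": "TA-", "nad4L": "TA-", "nad6": "TA-",
}

#: intergenic spacers planted between consecutive genes (bp)
DEFAULT_SPACERS = {
    ("trnQ", "trnM"): 4, ("trnC", "trnY"): 6, ("trnY", "cox1"): 2,
    ("trnL(UUR)", "cox2"): 1, ("cox3", "trnG"): 2, ("trnA", "trnR"): 3,
    ("trnR", "trnN"): 4, ("trnE", "trnF"): 2, ("trnH", "nad4"): 1,
    ("nad4L", "trnT"): 2, ("trnP", "nad6"): 2, ("cob", "trnS(UCN)"): 5,
    ("trnS(UCN)", "nad1"): 15,
}

_BASES = np.array(list("ACGT"))


@dataclass
class ControlRegionPlan:
    unit_length: int = 113
    full_copies: int = 8
    partial_bp: int = 57
    noise: float = 0.0
    flank: int = 200
    at_content: float = 0.90


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic mitogenome.

    Defaults emulate the architecture of a hepialid moth mitogenome:
    ancestral insect gene order, whole-genome A+T content ~0.82, a 7-bp
    atp8/atp6 overlap, eight PCGs with truncated stops, and a control region
    carrying 8 full copies plus a 57-bp partial copy of a 113-bp unit.
    """

    template: str | GeneOrder = "ancestral"
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    at_content: float = 0.82
    codon_weights: dict | None = None
    overlap_plan: dict = field(default_factory=lambda: {("atp8", "atp6"): 7})
    truncated_stops: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUNCATED_STOPS))
    spacer_plan: dict = field(default_factory=lambda: dict(DEFAULT_SPACERS))
    control_region: ControlRegionPlan | None = field(
        default_factory=ControlRegionPlan)
    seed: int = 0

    def resolve_order(self) -> GeneOrder:
        if isinstance(self.template, GeneOrder):
            return self.template
        try:
            return REFERENCE_ORDERS[self.template]
        except KeyError:
            raise ValidationError(
                f"unknown template {self.template!r}; choose from "
                f"{sorted(REFERENCE_ORDERS)} or pass a GeneOrder") from None

    def validate(self) -> "SyntheticGenomeSpec":
        order = self.resolve_order()
        names = set(order.names())
        for (up, down), k in self.overlap_plan.items():
            if up not in names or down not in names:
                raise ValidationError(f"overlap plan names unknown gene: "
                                      f"{up}/{down}")
            for g in (up, down):
                if g != CONTROL_REGION and k >= self.gene_lengths.get(g, 0):
                    raise ValidationError(
                        f"overlap {k} bp >= length of {g}")
            up_cls = infer_feature_class(up)
            down_cls = infer_feature_class(down)
            if up_cls == "PCG" and down_cls == "PCG":
                if up in self.truncated_stops:
                    raise ValidationError(
                        f"{up}: cannot both overlap {down} and carry a "
                        "truncated stop")
                if k < 7 or (order.strand(up) != "J"
                             or order.strand(down) != "J"):
                    raise ValidationError(
                        "PCG/PCG overlaps are only supported for >=7 bp on "
                        "the majority strand")
        cr = self.control_region
        if cr is not None and cr.partial_bp >= cr.unit_length:
            raise ValidationError("partial_bp must be < unit_length")
        if not 0 < self.at_content < 1:
            raise ValidationError("at_content must be in (0, 1)")
        return self


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _default_codon_weights(at: float) -> dict[str, float]:
    """i.i.d.-base codon weights at the target A+T fraction, stops excluded."""
    p = {"A": at / 2, "T": at / 2, "C": (1 - at) / 2, "G": (1 - at) / 2}
    w = {}
    for c in INVERTEBRATE_MITO.forward_table:
        if all(b in "ACGT" for b in c):
            w[c] = p[c[0]] * p[c[1]] * p[c[2]]
    return w


def _sample_codons(rng: np.random.Generator, n: int,
                   weights: dict[str, float]) -> list[str]:
    codons = sorted(weights)
    p = np.array([weights[c] for c in codons], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(codons), size=n, p=p)
    return [codons[i] for i in idx]


def generate_control_region(unit_length: int, full_copies: int,
                            partial_bp: int, noise: float,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            at_content: float = 0.90,
                            flank: int = 200) -> str:
    """A+T-rich control-region sequence with a planted tandem-repeat array.

    A random A+T-biased unit is repeated ``full_copies`` times, followed by
    its first ``partial_bp`` bases, with i.i.d. substitutions at the
    ``noise`` rate over the array, embedded between two non-repetitive
    ``flank``-bp A+T-biased stretches.  "Non-repetitive" is enforced at the
    junctions: the six flank bases adjacent to the array are forced to
    differ from the bases that would continue the repeat, so the planted
    array has an exact boundary.  With ``full_copies == 0`` only the flanks
    are emitted.
    """
    if partial_bp and partial_bp >= unit_length:
        raise ValidationError("partial_bp must be < unit_length")
    if rng is None:
        rng = np.random.default_rng(seed)
    left = _random_bases(rng, flank, at_content)
    right = _random_bases(rng, flank, at_content)
    if full_copies <= 0:
        return left + right
    unit = _random_bases(rng, unit_length, at_content)

    def _differing(base: str) -> str:
        choices = [b for b in "ACGT" if b != base]
        return choices[rng.integers(3)]

    lchars, rchars = list(left), list(right)
    for i in range(1, min(6, flank) + 1):
        lchars[-i] = _differing(unit[-i % unit_length])
    for i in range(min(6, flank)):
        rchars[i] = _differing(unit[(partial_bp + i) % unit_length])
    left, right = "".join(lchars), "".join(rchars)
    array = unit * full_copies + unit[:partial_bp]
    if noise > 0:
        chars = np.array(list(array))
        hit = rng.random(len(chars)) < noise
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[rng.integers(3)]
        array = "".join(chars)
    return left + array + right


def _pcg_length(gene: str, target: int, stop_token: str) -> tuple[int, int]:
    """Feasible PCG length nearest the target: 3 (start) + 3m + stop bases."""
    stop_len = STOP_LENGTH[stop_token]
    m = (target - 3 - stop_len) // 3
    if m < 1:
        raise ValidationError(f"{gene}: target length {target} too short")
    return 3 + 3 * m + stop_len, m


def _build_pcg(rng, gene, target_len, stop_token, start_codon, weights,
               force_prev_tail: str | None = None) -> str:
    """Sense sequence of one PCG: start codon, stop-free internal codons,
    then a full or truncated stop."""
    length, m = _pcg_length(gene, target_len, stop_token)
    codons = _sample_codons(rng, m, weights)
    stop = {"TAA": "TAA", "TAG": "TAG", "TA-": "TA", "T--": "T"}[stop_token]
    return start_codon + "".join(codons) + stop


def _build_overlapping_pcg_pair(rng, up, down, k, lengths, stops, starts,
                                weights) -> tuple[str, str]:
    """Sense sequences for a J-strand PCG pair overlapping by ``k`` bp in the
    atp8/atp6 style: the downstream start codon opens the overlap and the
    upstream gene's full TAA stop closes it, inside the downstream gene.

    The shared tail reads ``A TG <k-6 shared bases> TAA``: the leading A is
    the final base of an upstream codon (so the downstream ATG begins at
    codon offset 2 upstream, the canonical atp8/atp6 frame relation, which
    requires ``k % 3 == 1``), and both reading frames cross the tail without
    an in-frame stop.
    """
    if stops.get(up, "TAA") not in ("TAA", "TAG"):
        raise ValidationError(f"{up}: overlapping upstream gene needs a "
                              "full stop")
    if k % 3 != 1:
        raise ValidationError("PCG/PCG overlap must satisfy k % 3 == 1")
    up_len, m_up = _pcg_length(up, lengths[up], "TAA")
    n_tail_codons = (k - 4) // 3  # upstream codons fully inside the tail
    n_head = m_up - n_tail_codons  # remaining internal codons, incl. ``pre``
    if n_head < 1:
        raise ValidationError(f"{up}: too short for a {k}-bp overlap")

    def frames_clean(sh: str) -> bool:
        up_tail = "TG" + sh  # upstream codons after the leading A
        up_cods = [up_tail[i:i + 3] for i in range(0, len(up_tail), 3)]
        down_body = sh + "TA"  # downstream codons after its ATG (final A of
        down_cods = [down_body[i:i + 3]  # TAA starts the next codon: A..)
                     for i in range(0, len(down_body) - 2, 3)]
        return not any(c in ("TAA", "TAG") for c in up_cods + down_cods)

    shared = _random_bases(rng, k - 6, 0.8)
    for _ in range(200):
        if frames_clean(shared):
            break
        shared = _random_bases(rng, k - 6, 0.8)
    else:
        raise ValidationError(f"{up}/{down}: could not build a stop-free "
                              f"{k}-bp overlap")
    head = _sample_codons(rng, n_head - 1, weights)
    # the codon immediately before the tail must end in A without being a stop
    pre = next((c for c in _sample_codons(rng, 50, weights)
                if c.endswith("A")), "ATA")
    up_seq = (starts.get(up, "ATG") + "".join(head) + pre
              + "TG" + shared + "TAA")
    assert len(up_seq) == up_len

    down_stop = stops.get(down, "TAA")
    stop = {"TAA": "TAA", "TAG": "TAG", "TA-": "TA", "T--": "T"}[down_stop]
    down_len, m_down = _pcg_length(down, lengths[down], down_stop)
    m_rest = m_down - n_tail_codons - 1
    if m_rest < 0:
        raise ValidationError(f"{down}: too short for a {k}-bp overlap")
    prefix = up_seq[-k:]  # == "ATG" + shared + "TAA"
    # the prefix leaves one dangling A that opens a downstream codon A??
    filler = _random_bases(rng, 2, 0.8)
    down_seq = prefix + filler + "".join(_sample_codons(rng, m_rest, weights)) + stop
    assert len(down_seq) == down_len and down_seq[:k] == up_seq[-k:]
    return up_seq, down_seq


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[GenomeRecord, list[FeatureAnnotation]]:
    """Generate a circular mitogenome and its ground-truth feature table.

    Returns ``(record, truth)`` where ``record`` carries the sequence and the
    truth features, and ``truth`` is an independent copy of the feature list
    (safe to mutate, e.g. to build degraded hints for annotation tests).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.resolve_order()
    weights = spec.codon_weights or _default_codon_weights(spec.at_content)
    overlaps = dict(spec.overlap_plan)
    lengths = spec.gene_lengths

    # pre-build sense sequences for PCG/PCG overlap pairs
    pcg_pair_seqs: dict[str, str] = {}
    for (up, down), k in overlaps.items():
        if infer_feature_class(up) == "PCG" and infer_feature_class(down) == "PCG":
            s_up, s_down = _build_overlapping_pcg_pair(
                rng, up, down, k, lengths, spec.truncated_stops,
                DEFAULT_START_CODONS, weights)
            pcg_pair_seqs[up] = s_up
            pcg_pair_seqs[down] = s_down

    genome = ""
    features: list[FeatureAnnotation] = []
    prev_gene: str | None = None
    for gene, strand in order.genes:
        cls = infer_feature_class(gene)
        # ---- sense sequence -------------------------------------------------
        start_codon = stop_token = anticodon = None
        if cls == "PCG":
            start_codon = DEFAULT_START_CODONS.get(gene, "ATG")
            stop_token = spec.truncated_stops.get(gene, "TAA")
            if gene in pcg_pair_seqs:
                sense = pcg_pair_seqs[gene]
            else:
                sense = _build_pcg(rng, gene, lengths[gene], stop_token,
                                   start_codon, weights)
        elif cls == "tRNA":
            n = lengths.get(gene) or int(rng.integers(60, 74))
            anticodon = CANONICAL_ANTICODONS.get(gene, "NNN")
            body = _random_bases(rng, n, spec.at_content)
            sense = body[:32] + anticodon + body[35:]
        elif cls == "rRNA":
            sense = _random_bases(rng, lengths[gene], spec.at_content)
        else:  # control region
            if spec.control_region is None:
                continue
            cr = spec.control_region
            sense = generate_control_region(
                cr.unit_length, cr.full_copies, cr.partial_bp, cr.noise,
                rng=rng, at_content=cr.at_content, flank=cr.flank)
        gslice = sense if strand == "J" else reverse_complement(sense)

        # ---- layout ---------------------------------------------------------
        k = overlaps.get((prev_gene, gene), 0) if prev_gene else 0
        if k:
            tail = genome[-k:]
            if cls == "PCG":
                if gslice[:k] != tail:
                    raise ValidationError(
                        f"{prev_gene}/{gene}: overlap construction failed")
            else:
                gslice = tail + gslice[k:]  # placeholder genes adopt the tail
            start = len(genome) - k + 1
            genome += gslice[k:]
        else:
            gap = spec.spacer_plan.get((prev_gene, gene), 0) if prev_gene else 0
            if gap:
                genome += _random_bases(rng, gap, spec.at_content)
            start = len(genome) + 1
            genome += gslice
        end = start + len(gslice) - 1
        features.append(FeatureAnnotation(
            gene=gene, feature_class=cls, strand=strand, start=start, end=end,
            start_codon=start_codon, stop_codon=stop_token,
            anticodon=anticodon))
        prev_gene = gene

    record = GenomeRecord(f"synthetic_seed{spec.seed}", genome,
                          features=features).validate()
    return record, copy.deepcopy(features)
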