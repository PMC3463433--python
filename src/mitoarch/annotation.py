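"""Protein-coding gene boundary determination under the invertebrate
mitochondrial genetic code (NCBI translation table 5).

Animal mitochondrial PCGs frequently end on an incomplete stop codon (``T``
or ``TA``) abutting the downstream gene; the codon is completed to UAA by
post-transcriptional polyadenylation.  The boundary rules implemented here:

* the 5' end is the first legitimate in-frame start codon
  (ATN, GTG, TTG, GTT, plus per-gene overrides such as CGA for cox1) that is
  not located inside an upstream gene on the same strand;
* the 3' end is the first in-frame TAA/TAG downstream — unless that stop
  lies within a downstream same-strand gene, in which case a truncated stop
  (``TA-`` or ``T--``) ending immediately before the downstream gene is
  designated instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .core import GenomeRecord, ValidationError, feature_length, reverse_complement

__all__ = [
    "GeneticCode", "PcgCall", "AnnotationError", "NoStartFound", "OpenOrf",
    "INVERTEBRATE_MITO", "STOP_LENGTH",
    "find_start", "find_stop", "annotate_pcgs", "count_codons", "translate",
]

#: bases contributed by each stop token to the gene span
STOP_LENGTH = {"TAA": 3, "TAG": 3, "TA-": 2, "T--": 1}


class AnnotationError(ValueError):
    pass


class NoStartFound(AnnotationError):
    pass


class OpenOrf(AnnotationError):
    """Neither a full nor a truncated stop codon could be constructed."""


@dataclass(frozen=True)
class GeneticCode:
    """A mitochondrial genetic code with an explicit legitimate-start set.

    The default is the invertebrate mitochondrial code (table 5), under which
    AGA/AGG encode serine and the only stop codons are TAA and TAG.  The
    legitimate start set is the one conventionally applied when refining
    insect mitogenome PCG boundaries: ATN, GTG, TTG and GTT.
    """

    table_id: int = 5
    forward_table: dict = field(default_factory=dict)
    stop_codons: frozenset = frozenset()
    start_codons: frozenset = frozenset(
        ["ATA", "ATT", "ATC", "ATG", "GTG", "TTG", "GTT"])

    @classmethod
    def from_ncbi(cls, table_id: int = 5,
                  start_codons: frozenset | None = None) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        kwargs = {}
        if start_codons is not None:
            kwargs["start_codons"] = frozenset(start_codons)
        return cls(table_id=table_id,
                   forward_table=dict(t.forward_table),
                   stop_codons=frozenset(t.stop_codons), **kwargs)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_start(self, codon: str, overrides: frozenset | set | None = None) -> bool:
        return codon in self.start_codons or (overrides is not None
                                              and codon in overrides)

    def amino_acid(self, codon: str) -> str:
        return self.forward_table[codon]


def _default_code() -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[5]
    return GeneticCode(5, dict(t.forward_table), frozenset(t.stop_codons))


INVERTEBRATE_MITO = _default_code()

#: genes whose tentative start codon falls outside the legitimate set
DEFAULT_START_OVERRIDES: dict[str, frozenset] = {"cox1": frozenset({"CGA"})}


def translate(sense_codons: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Translate a stop-free sense coding sequence (length divisible by 3)."""
    if len(sense_codons) % 3:
        raise AnnotationError("coding sequence length not divisible by 3")
    aa = []
    for i in range(0, len(sense_codons), 3):
        c = sense_codons[i:i + 3]
        if code.is_stop(c):
            raise AnnotationError(f"internal stop codon {c} at offset {i}")
        aa.append(code.amino_acid(c))
    return "".join(aa)


def find_start(sense_sequence: str, search_window: tuple[int, int],
               code: GeneticCode = INVERTEBRATE_MITO,
               overrides: frozenset | set | None = None,
               not_before: int | None = None) -> tuple[int, str]:
    """Locate the first legitimate start codon within a window.

    ``search_window`` is a half-open 0-based offset range scanned in
    ascending order at every offset (the frame is fixed afterwards by the
    chosen start).  ``not_before`` excludes offsets lying inside an upstream
    same-strand gene.  Returns ``(offset, triplet)``.
    """
    lo, hi = search_window
    lo = max(lo, 0, not_before if not_before is not None else 0)
    hi = min(hi, len(sense_sequence) - 2)
    for off in range(lo, hi):
        codon = sense_sequence[off:off + 3]
        if code.is_start(codon, overrides):
            return off, codon
    raise NoStartFound(
        f"no legitimate start codon in window [{lo}, {hi})")


def find_stop(sense_sequence: str, start_offset: int,
              downstream_gene_boundary: int | None = None,
              code: GeneticCode = INVERTEBRATE_MITO) -> tuple[int, str]:
    """Locate the 3' end of a PCG whose start is at ``start_offset``.

    Scans in frame for the first TAA/TAG.  A full stop wins when it ends
    before the downstream same-strand gene (``downstream_gene_boundary``,
    0-based offset of its first base); otherwise the gene is truncated
    immediately before the downstream gene with token ``TA-`` or ``T--``.
    Returns ``(end_offset_inclusive, stop_token)``.
    """
    n = len(sense_sequence)
    ds = downstream_gene_boundary
    p = start_offset + 3
    while p + 3 <= n:
        if ds is not None and p + 2 >= ds:
            break  # next full codon would reach into the downstream gene
        codon = sense_sequence[p:p + 3]
        if code.is_stop(codon):
            return p + 2, codon
        p += 3
    if ds is None:
        raise OpenOrf("no in-frame stop codon before end of sequence")
    remainder = (ds - start_offset) % 3
    if remainder == 0:
        raise OpenOrf("downstream gene starts on a codon boundary; "
                      "no truncated stop constructible")
    tail = sense_sequence[ds - remainder:ds]
    if tail not in ("T", "TA"):
        raise OpenOrf(f"truncated tail {tail!r} is not T/TA")
    token = "T--" if remainder == 1 else "TA-"
    return ds - 1, token


@dataclass
class PcgCall:
    """A resolved protein-coding gene boundary on the genome."""

    gene: str
    strand: str
    start: int  # 1-based inclusive, majority-strand coordinates
    end: int
    start_codon: str
    stop_codon: str
    codon_count: int

    def validate(self) -> "PcgCall":
        span = self.end - self.start + 1
        stop_len = STOP_LENGTH[self.stop_codon]
        if (span - stop_len) % 3:
            raise ValidationError(
                f"{self.gene}: span {span} minus stop length {stop_len} "
                "not divisible by 3")
        return self


def _sense_coords(start: int, end: int, strand: str, L: int) -> tuple[int, int]:
    """Map majority-strand 1-based coords to 0-based offsets on the sense
    strand (the reverse complement for strand N)."""
    if strand == "J":
        return start - 1, end - 1
    return L - end, L - start


def annotate_pcgs(record: GenomeRecord,
                  code: GeneticCode = INVERTEBRATE_MITO,
                  start_overrides: dict[str, frozenset] | None = None,
                  window: int = 60,
                  upstream_slack: int = 0) -> list[PcgCall]:
    """Refine PCG boundaries on a genome with approximate region hints.

    The record's PCG features act as hints: the hinted 5' end anchors the
    start-codon search window (``upstream_slack`` bp upstream through
    ``window`` bp downstream, scanned 5'→3'), and the nearest same-strand
    feature starting beyond the hinted 3' end bounds the stop search, so
    that planned overlaps (e.g. atp8/atp6) never trigger stop truncation.

    Returns one :class:`PcgCall` per resolvable PCG; unresolvable genes are
    reported in the raised :class:`AnnotationError` only if *none* resolve.
    """
    if record.sequence is None:
        raise ValidationError(f"{record.identifier}: sequence required")
    if start_overrides is None:
        start_overrides = DEFAULT_START_OVERRIDES
    L = record.length
    fwd = record.sequence
    rev = reverse_complement(fwd)
    calls: list[PcgCall] = []
    failures: list[str] = []
    for f in record.features:
        if f.feature_class != "PCG":
            continue
        sense = fwd if f.strand == "J" else rev
        s5, s3 = _sense_coords(f.start, f.end, f.strand, L)
        # nearest same-strand feature starting past this gene's hinted 3' end
        ds = None
        for g in record.features:
            if g is f or g.strand != f.strand:
                continue
            g5, _ = _sense_coords(g.start, g.end, g.strand, L)
            if g5 > s3 and (ds is None or g5 < ds):
                ds = g5
        # same-strand features ending before the hint bound the start search
        not_before = None
        for g in record.features:
            if g is f or g.strand != f.strand:
                continue
            _, g3 = _sense_coords(g.start, g.end, g.strand, L)
            if g3 < s5 + 3 and (not_before is None or g3 + 1 > not_before):
                if g3 >= s5 - upstream_slack:
                    not_before = g3 + 1
        try:
            off, start_codon = find_start(
                sense, (s5 - upstream_slack, s5 + window), code,
                overrides=start_overrides.get(f.gene), not_before=not_before)
            end_off, stop_token = find_stop(sense, off, ds, code)
        except AnnotationError as exc:
            failures.append(f"{f.gene}: {exc}")
            continue
        if f.strand == "J":
            g_start, g_end = off + 1, end_off + 1
        else:
            g_start, g_end = L - end_off, L - off
        span = end_off - off + 1
        calls.append(PcgCall(f.gene, f.strand, g_start, g_end, start_codon,
                             stop_token,
                             (span - STOP_LENGTH[stop_token]) // 3).validate())
    if failures and not calls:
        raise AnnotationError("; ".join(failures))
    if failures:
        # partial failure: surface per-gene problems without aborting
        calls_failed = AnnotationError("; ".join(failures))
        calls_failed.partial = calls  # type: ignore[attr-defined]
        raise calls_failed
    return calls


def count_codons(record_or_calls) -> int:
    """Total sense codons across all PCGs, excluding stop codons.

    Accepts a :class:`GenomeRecord` whose PCG features carry stop tokens, or
    a list of :class:`PcgCall`.  Each gene contributes
    ``(length - stop_length) / 3`` codons, with stop_length 3 for TAA/TAG,
    2 for TA- and 1 for T--.
    """
    total = 0
    if isinstance(record_or_calls, GenomeRecord):
        record = record_or_calls
        for f in record.features:
            if f.feature_class != "PCG":
                continue
            if f.stop_codon is None:
                raise ValidationError(f"{f.gene}: stop codon token required")
            span = feature_length(f, record.length)
            stop_len = STOP_LENGTH[f.stop_codon]
            if (span - stop_len) % 3:
                raise ValidationError(
                    f"{f.gene}: span {span} minus stop {stop_len} not "
                    "divisible by 3")
            total += (span - stop_len) // 3
    else:
        for call in record_or_calls:
            call.validate()
            total += call.codon_count
    return total
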