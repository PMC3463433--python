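"""Circular mitogenome data model and flat-file I/O.

Coordinates are 1-based and inclusive throughout the public interface, the
convention used in published mitogenome annotation tables.  A feature whose
``end`` is smaller than its ``start`` wraps around the origin of the circular
molecule.  Conversions to half-open intervals happen only inside arithmetic
helpers.

Strand is encoded ``J`` (majority strand) / ``N`` (minority strand) in files
and in :class:`FeatureAnnotation`; the majority strand is the one carrying
most genes, conventionally the strand deposited in GenBank.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "FeatureAnnotation",
    "GenomeRecord",
    "FeatureTableError",
    "ValidationError",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "CONTROL_REGION",
    "feature_length",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "load_builtin_record",
    "builtin_record_names",
    "reverse_complement",
]

STRANDS = ("J", "N")
FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control")
STOP_TOKENS = ("TAA", "TAG", "TA-", "T--")

PCG_NAMES = frozenset(
    ["atp6", "atp8", "cob", "cox1", "cox2", "cox3",
     "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"]
)
TRNA_NAMES = frozenset(
    ["trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
     "trnL(CUN)", "trnL(UUR)", "trnM", "trnN", "trnP", "trnQ", "trnR",
     "trnS(AGN)", "trnS(UCN)", "trnT", "trnV", "trnW", "trnY"]
)
RRNA_NAMES = frozenset(["rrnL", "rrnS"])
CONTROL_REGION = "at_rich_region"

_IUPAC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class FeatureTableError(ValueError):
    """Malformed feature-table file."""


class ValidationError(ValueError):
    """A record or feature violates the data-model invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def infer_feature_class(gene: str) -> str:
    if gene in PCG_NAMES:
        return "PCG"
    if gene in TRNA_NAMES or gene.startswith("trn"):
        return "tRNA"
    if gene in RRNA_NAMES:
        return "rRNA"
    if gene == CONTROL_REGION:
        return "control"
    raise ValidationError(f"cannot infer feature class for gene {gene!r}")


@dataclass
class FeatureAnnotation:
    """One annotated gene or region on the circular genome.

    ``start``/``end`` are 1-based inclusive on the majority strand; for
    minority-strand (``N``) features they still refer to majority-strand
    coordinates with ``start <= end`` unless the feature spans the origin.
    """

    gene: str
    feature_class: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def validate(self, genome_length: int | None = None) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"{self.gene}: strand must be one of {STRANDS}, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"{self.gene}: feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}")
        try:
            expected = infer_feature_class(self.gene)
        except ValidationError:
            expected = None
        if expected is not None and expected != self.feature_class:
            raise ValidationError(
                f"{self.gene}: feature_class {self.feature_class!r} inconsistent "
                f"with gene name (expected {expected!r})")
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.gene}: coordinates must be >= 1")
        if genome_length is not None and (self.start > genome_length
                                          or self.end > genome_length):
            raise ValidationError(
                f"{self.gene}: coordinates ({self.start}, {self.end}) outside "
                f"[1, {genome_length}]")
        if self.stop_codon is not None and self.stop_codon not in STOP_TOKENS:
            raise ValidationError(
                f"{self.gene}: stop codon token {self.stop_codon!r} not in "
                f"{STOP_TOKENS}")
        if self.feature_class != "PCG" and (self.start_codon or self.stop_codon):
            raise ValidationError(
                f"{self.gene}: start/stop codons are only valid on PCGs")
        if self.feature_class != "tRNA" and self.anticodon:
            raise ValidationError(f"{self.gene}: anticodon only valid on tRNAs")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


def feature_length(f: FeatureAnnotation, genome_length: int | None = None) -> int:
    """Inclusive length of a feature in bp, handling origin-spanning features.

    For a feature with ``end < start`` the length is
    ``(genome_length - start + 1) + end``.
    """
    if f.wraps_origin:
        if genome_length is None:
            raise ValidationError(
                f"{f.gene}: genome length required for origin-spanning feature")
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


@dataclass
class GenomeRecord:
    """A circular genome: an optional sequence plus ordered feature list.

    A record may be coordinate-only (``sequence is None``) when built from a
    printed annotation table; composition/codon operations then refuse to run
    but all architecture accounting still works.
    """

    identifier: str
    sequence: str | None = None
    length: int | None = None
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - _IUPAC
            if bad:
                raise ValidationError(
                    f"{self.identifier}: non-IUPAC residues {sorted(bad)}")
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise ValidationError(
                    f"{self.identifier}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}")
        elif self.length is None and self.features:
            self.length = max(f.end for f in self.features)

    def validate(self) -> "GenomeRecord":
        for f in self.features:
            f.validate(self.length)
        names = [f.gene for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(
                f"{self.identifier}: duplicate features {sorted(dupes)}")
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise ValidationError(
                f"{self.identifier}: features not sorted by start coordinate")
        return self

    def feature(self, gene: str) -> FeatureAnnotation:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)

    def feature_sequence(self, f: FeatureAnnotation, sense: bool = True) -> str:
        """Majority-strand slice of a feature, or its sense-strand sequence
        (reverse complement for strand N) when ``sense`` is true."""
        if self.sequence is None:
            raise ValidationError(f"{self.identifier}: sequence required")
        if f.wraps_origin:
            s = self.sequence[f.start - 1:] + self.sequence[:f.end]
        else:
            s = self.sequence[f.start - 1:f.end]
        if sense and f.strand == "N":
            s = reverse_complement(s)
        return s

    def linearize_at(self, gene: str) -> "GenomeRecord":
        """Rotate the circular record so that ``gene`` starts at position 1.

        This is the conventional linearization of insect mitogenome tables
        (trnI first, control region last).  Requires a sequence.
        """
        pivot = self.feature(gene)
        if pivot.start == 1:
            return self
        if self.sequence is None:
            raise ValidationError("cannot rotate a coordinate-only record")
        off = pivot.start - 1
        L = self.length
        seq = self.sequence[off:] + self.sequence[:off]

        def shift(p: int) -> int:
            return (p - 1 - off) % L + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end))
                 for f in self.features]
        feats.sort(key=lambda f: f.start)
        return GenomeRecord(self.identifier, seq, L, self.circular, feats)


# ---------------------------------------------------------------------------
# Feature-table TSV

_TABLE_COLUMNS = ["gene", "class", "strand", "start", "end",
                  "start_codon", "stop_codon", "anticodon"]


def read_feature_table(path: str | Path, identifier: str | None = None,
                       length: int | None = None) -> GenomeRecord:
    """Read a tab-separated feature table into a coordinate-only record.

    The header must name at least ``gene, class, strand, start, end``; the
    codon/anticodon columns are optional and may be empty.  Genome length is
    inferred as ``max(end)`` when not given explicitly.
    """
    path = Path(path)
    feats: list[FeatureAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise FeatureTableError(f"{path}: missing header line")
        missing = {"gene", "class", "strand", "start", "end"} - set(reader.fieldnames)
        if missing:
            raise FeatureTableError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                feats.append(FeatureAnnotation(
                    gene=row["gene"].strip(),
                    feature_class=row["class"].strip(),
                    strand=row["strand"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    start_codon=(row.get("start_codon") or "").strip() or None,
                    stop_codon=(row.get("stop_codon") or "").strip() or None,
                    anticodon=(row.get("anticodon") or "").strip() or None,
                ))
            except (TypeError, ValueError, KeyError) as exc:
                raise FeatureTableError(f"{path}:{lineno}: malformed row: {exc}") from exc
    rec = GenomeRecord(identifier or path.stem, length=length, features=feats)
    return rec.validate()


def write_feature_table(record: GenomeRecord, path: str | Path) -> None:
    """Write the feature list as TSV; round-trips bit-exactly with
    :func:`read_feature_table` (truncated stops keep their hyphens)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TABLE_COLUMNS)
        for f in record.features:
            w.writerow([f.gene, f.feature_class, f.strand, f.start, f.end,
                        f.start_codon or "", f.stop_codon or "", f.anticodon or ""])


# ---------------------------------------------------------------------------
# FASTA / GenBank

def read_fasta(path: str | Path) -> GenomeRecord:
    """Read a single-sequence FASTA file; lowercase residues are uppercased."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise FeatureTableError(f"{path}: no FASTA records")
    if len(recs) > 1:
        raise FeatureTableError(f"{path}: expected one sequence, found {len(recs)}")
    return GenomeRecord(recs[0].id, str(recs[0].seq).upper())


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 70) -> None:
    if record.sequence is None:
        raise ValidationError("record has no sequence")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{record.identifier}\n")
        for i in range(0, len(record.sequence), width):
            fh.write(record.sequence[i:i + width] + "\n")


_GB_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
             "misc_feature": "control", "D-loop": "control"}

_GB_GENE_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6", "cytb": "cob",
    "cob": "cob", "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "atp6": "atp6", "atp8": "atp8", "12s": "rrnS", "16s": "rrnL",
    "rrns": "rrnS", "rrnl": "rrnL", "nad4l": "nad4L",
}


def _genbank_gene_name(feat) -> str | None:
    for key in ("gene", "product", "note"):
        vals = feat.qualifiers.get(key)
        if vals:
            name = vals[0].strip()
            low = name.lower().replace("-", "").replace(" ", "")
            return _GB_GENE_ALIASES.get(low, name)
    return None


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read one GenBank flat file; CDS/tRNA/rRNA/misc_feature map to feature
    classes and ``complement()`` locations to strand N."""
    recs = list(SeqIO.parse(str(path), "genbank"))
    if not recs:
        raise FeatureTableError(f"{path}: no GenBank records")
    gb = recs[0]
    feats: list[FeatureAnnotation] = []
    for feat in gb.features:
        cls = _GB_CLASS.get(feat.type)
        if cls is None:
            continue
        gene = _genbank_gene_name(feat)
        if gene is None:
            if cls == "control":
                gene = CONTROL_REGION
            else:
                continue
        feats.append(FeatureAnnotation(
            gene=gene,
            feature_class=cls,
            strand="N" if feat.location.strand == -1 else "J",
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
        ))
    feats.sort(key=lambda f: f.start)
    rec = GenomeRecord(gb.id, str(gb.seq).upper(), features=feats)
    # published tables linearize with trnI first; rotate if needed and possible
    if any(f.gene == "trnI" for f in feats) and rec.feature("trnI").start != 1:
        rec = rec.linearize_at("trnI")
    return rec


# ---------------------------------------------------------------------------
# Bundled annotation tables (printed coordinates of the two ghost-moth
# mitogenomes, GenBank HM744694 and HM744695)

_BUILTIN = {
    "HM744694": "HM744694_T_renzhiensis.features.tsv",
    "T_renzhiensis": "HM744694_T_renzhiensis.features.tsv",
    "HM744695": "HM744695_T_yunnanensis.features.tsv",
    "T_yunnanensis": "HM744695_T_yunnanensis.features.tsv",
}


def builtin_record_names() -> list[str]:
    return sorted(set(_BUILTIN.values()))


def load_builtin_record(name: str) -> GenomeRecord:
    """Load a bundled coordinate-only annotation table by accession or
    species tag (``HM744694``/``T_renzhiensis``, ``HM744695``/``T_yunnanensis``)."""
    try:
        fname = _BUILTIN[name]
    except KeyError:
        raise KeyError(f"unknown builtin record {name!r}; "
                       f"choose from {sorted(_BUILTIN)}") from None
    res = importlib.resources.files("mitoarch.data").joinpath(fname)
    with importlib.resources.as_file(res) as p:
        return read_feature_table(p, identifier=fname.split("_")[0])
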