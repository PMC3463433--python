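"""Nucleotide composition, strand skew, and codon-usage statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on the
majority strand; reverse-complementing a sequence negates both skews exactly.
RSCU (relative synonymous codon usage) is a codon's observed count divided by
its expected count under uniform usage within its synonymous family; the Leu
and Ser families are each split into their two codon boxes (UUR/CUN and
UCN/AGN), the presentation conventional for mitogenome codon-usage figures.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .annotation import INVERTEBRATE_MITO, STOP_LENGTH, GeneticCode
from .core import GenomeRecord, ValidationError, reverse_complement

__all__ = [
    "CompositionSummary", "CodonUsageTable", "CODON_FAMILIES",
    "base_composition", "composition_by_codon_position",
    "codon_usage", "rscu", "skew_scatter", "pcg_sense_sequences",
    "record_composition_table",
]


@dataclass
class CompositionSummary:
    """One composition row: base percentages, A+T content and strand skews.

    Percentages are over A/C/G/T only (ambiguity codes excluded from the
    denominator).  Skews with a zero denominator are NaN, never zero.
    """

    label: str
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    at_content: float
    at_skew: float
    gc_skew: float
    n_bases: int

    def as_dict(self) -> dict:
        return {
            "region": self.label, "A%": round(self.a_pct, 2),
            "C%": round(self.c_pct, 2), "G%": round(self.g_pct, 2),
            "T%": round(self.t_pct, 2), "A+T%": round(self.at_content, 2),
            "AT-skew": round(self.at_skew, 3) if math.isfinite(self.at_skew) else None,
            "GC-skew": round(self.gc_skew, 3) if math.isfinite(self.gc_skew) else None,
        }


def base_composition(sequence: str, label: str = "sequence") -> CompositionSummary:
    """Composition summary of a nucleotide string (majority strand)."""
    if not sequence:
        raise ValidationError("empty sequence")
    c = Counter(sequence.upper())
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    n = a + t + g + cc
    if n == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    at_skew = (a - t) / (a + t) if a + t else math.nan
    gc_skew = (g - cc) / (g + cc) if g + cc else math.nan
    return CompositionSummary(
        label, 100 * a / n, 100 * cc / n, 100 * g / n, 100 * t / n,
        100 * (a + t) / n, at_skew, gc_skew, n)


def pcg_sense_sequences(record: GenomeRecord, trim_stops: bool = True) -> dict[str, str]:
    """Sense (coding-strand) sequence of every PCG, in genomic order.

    Minority-strand genes are reverse complemented.  With ``trim_stops`` the
    1–3 bases of the stop token are removed, leaving only sense codons.
    """
    out: dict[str, str] = {}
    for f in record.features:
        if f.feature_class != "PCG":
            continue
        s = record.feature_sequence(f, sense=True)
        if trim_stops:
            if f.stop_codon is None:
                raise ValidationError(f"{f.gene}: stop codon token required")
            s = s[:len(s) - STOP_LENGTH[f.stop_codon]]
        out[f.gene] = s
    return out


def composition_by_codon_position(sense_sequences) -> list[CompositionSummary]:
    """Per-codon-position composition of stop-trimmed sense sequences.

    Accepts a dict (gene -> sequence) or iterable of sequences; each must
    have length divisible by 3.  Returns three rows, positions 1..3.
    """
    if isinstance(sense_sequences, dict):
        items = list(sense_sequences.items())
    else:
        items = [(f"seq{i}", s) for i, s in enumerate(sense_sequences)]
    parts = ["", "", ""]
    for gene, s in items:
        if len(s) % 3:
            raise ValidationError(f"{gene}: length {len(s)} not divisible by 3")
        for k in range(3):
            parts[k] += s[k::3]
    return [base_composition(parts[k], f"codon position {k + 1}")
            for k in range(3)]


def _build_families(code: GeneticCode) -> dict[str, list[str]]:
    """Synonymous families under the code, with Leu and Ser split into their
    UUR/CUN and UCN/AGN boxes."""
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(code.forward_table.items()):
        if any(b not in "ACGT" for b in codon):
            continue
        key = aa
        if aa == "L":
            key = "Leu(UUR)" if codon.startswith("TT") else "Leu(CUN)"
        elif aa == "S":
            key = "Ser(UCN)" if codon.startswith("TC") else "Ser(AGN)"
        fams.setdefault(key, []).append(codon)
    return fams


CODON_FAMILIES = _build_families(INVERTEBRATE_MITO)


@dataclass
class CodonUsageTable:
    """Counts, codons-per-thousand and RSCU over the 62 sense codons."""

    counts: dict[str, int]
    families: dict[str, list[str]] = field(
        default_factory=lambda: dict(CODON_FAMILIES))
    rscu: dict[str, float] = field(default_factory=dict)
    per_thousand: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def absent_codons(self) -> list[str]:
        return sorted(c for c, n in self.counts.items() if n == 0)

    def family_of(self, codon: str) -> str:
        for fam, codons in self.families.items():
            if codon in codons:
                return fam
        raise KeyError(codon)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, codons in self.families.items():
            for c in codons:
                rows.append({
                    "family": fam, "codon": c,
                    "rna_codon": c.replace("T", "U"),
                    "count": self.counts.get(c, 0),
                    "per_thousand": self.per_thousand.get(c, math.nan),
                    "rscu": self.rscu.get(c, math.nan),
                })
        return pd.DataFrame(rows)


def codon_usage(sense_sequences, code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Tally sense codons (stops excluded by construction) and fill RSCU and
    codons-per-thousand."""
    seqs = (sense_sequences.values() if isinstance(sense_sequences, dict)
            else sense_sequences)
    counts = {c: 0 for fam in CODON_FAMILIES.values() for c in fam}
    for s in seqs:
        if len(s) % 3:
            raise ValidationError(f"sequence length {len(s)} not divisible by 3")
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            if code.is_stop(codon):
                raise ValidationError(
                    f"stop codon {codon} in sense sequence at offset {i}")
            if codon in counts:
                counts[codon] += 1
    return rscu(CodonUsageTable(counts))


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU and codons-per-thousand in place and return the table.

    RSCU(c) = count(c) * family_size / family_total; families with zero total
    get NaN for every member.
    """
    total = table.total
    for fam, codons in table.families.items():
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        for c in codons:
            n = table.counts.get(c, 0)
            table.rscu[c] = (n * len(codons) / fam_total if fam_total
                             else math.nan)
            table.per_thousand[c] = 1000 * n / total if total else math.nan
    return table


def expected_rscu(weights: dict[str, float]) -> dict[str, float]:
    """RSCU values implied by per-codon sampling weights.

    Normalizes the weights within each synonymous family exactly as
    :func:`rscu` normalizes observed counts, so realized RSCU on sequences
    sampled from ``weights`` converges to these values.
    """
    out: dict[str, float] = {}
    for codons in CODON_FAMILIES.values():
        fam_total = sum(weights[c] for c in codons)
        for c in codons:
            out[c] = weights[c] * len(codons) / fam_total if fam_total else math.nan
    return out


def skew_scatter(records) -> pd.DataFrame:
    """Per-genome (AT-skew, GC-skew) points for a skew scatter plot."""
    rows = []
    for rec in records:
        if rec.sequence is None:
            raise ValidationError(f"{rec.identifier}: sequence required")
        comp = base_composition(rec.sequence, rec.identifier)
        rows.append({"genome": rec.identifier, "at_skew": comp.at_skew,
                     "gc_skew": comp.gc_skew})
    return pd.DataFrame(rows)


def plot_skew_scatter(points: pd.DataFrame, ax=None):
    """Thin matplotlib layer over :func:`skew_scatter` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(points["at_skew"], points["gc_skew"])
    for _, r in points.iterrows():
        ax.annotate(r["genome"], (r["at_skew"], r["gc_skew"]), fontsize=7)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("AT-skew")
    ax.set_ylabel("GC-skew")
    return ax


def record_composition_table(record: GenomeRecord) -> pd.DataFrame:
    """Composition rows for the standard region classes of a mitogenome:
    whole genome, concatenated PCGs (stop-trimmed sense sequence, genomic
    order), the three codon positions, concatenated tRNAs, each rRNA, and
    the A+T-rich region."""
    if record.sequence is None:
        raise ValidationError(f"{record.identifier}: sequence required")
    rows = [base_composition(record.sequence, "whole genome")]
    pcgs = pcg_sense_sequences(record)
    if pcgs:
        rows.append(base_composition("".join(pcgs.values()),
                                     "protein-coding genes"))
        rows.extend(composition_by_codon_position(pcgs))
    trnas = [record.feature_sequence(f) for f in record.features
             if f.feature_class == "tRNA"]
    if trnas:
        rows.append(base_composition("".join(trnas), "tRNA genes"))
    for f in record.features:
        if f.feature_class == "rRNA":
            rows.append(base_composition(record.feature_sequence(f), f.gene))
        if f.feature_class == "control":
            rows.append(base_composition(record.feature_sequence(f),
                                         "A+T-rich region"))
    return pd.DataFrame([r.as_dict() for r in rows])
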