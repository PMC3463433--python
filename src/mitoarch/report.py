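"""Combined per-genome analysis report.

Aggregates the individual analyses (feature table, composition rows,
overlap/spacer accounting, gene-order comparison, control-region repeats and
motifs, codon usage) into one :class:`AnalysisReport`, writing TSV tables
plus a JSON mirror.  Sections that need a sequence are explicitly marked
skipped when only a coordinate table is supplied; the report never computes
anything the individual operations do not.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import architecture, composition, control_region as cr_mod
from .architecture import REFERENCE_ORDERS, GeneOrder
from .core import GenomeRecord, read_fasta, read_feature_table, write_feature_table

log = logging.getLogger("mitoarch")

__all__ = ["AnalysisReport", "run_full_report"]

SKIPPED = "skipped (no sequence supplied)"


@dataclass
class AnalysisReport:
    identifier: str
    record: GenomeRecord
    composition: pd.DataFrame | str
    overlaps: architecture.OverlapReport
    spacers: architecture.SpacerReport
    gene_order: GeneOrder
    reference: str
    events: list[architecture.RearrangementEvent]
    repeats: list | str
    motifs: dict | str
    codon_usage: composition.CodonUsageTable | str

    def to_json_dict(self) -> dict:
        def gaps(rep):
            return {"total": rep.total,
                    "entries": [dataclasses.asdict(e) for e in rep.entries]}

        out = {
            "genome": self.identifier,
            "length": self.record.length,
            "n_features": len(self.record.features),
            "overlaps": gaps(self.overlaps),
            "spacers": gaps(self.spacers),
            "reference_order": self.reference,
            "order_matches_reference":
                self.gene_order == REFERENCE_ORDERS.get(self.reference,
                                                        self.gene_order),
            "rearrangements": [dataclasses.asdict(e) for e in self.events],
        }
        for key, val in [("composition", self.composition),
                         ("repeats", self.repeats), ("motifs", self.motifs),
                         ("codon_usage", self.codon_usage)]:
            if isinstance(val, str):
                out[key] = val
            elif key == "composition":
                out[key] = val.to_dict(orient="records")
            elif key == "repeats":
                out[key] = [dataclasses.asdict(r) for r in val]
            elif key == "motifs":
                out[key] = {m: [dataclasses.asdict(h) for h in hits]
                            for m, hits in val.items()}
            else:
                out[key] = {"total_codons": val.total,
                            "absent_codons": val.absent_codons}
        return out


def run_full_report(table_path: str | Path,
                    fasta_path: str | Path | None = None,
                    reference: str = "ancestral",
                    out_dir: str | Path | None = None) -> AnalysisReport:
    """Run every analysis applicable to the supplied inputs.

    A feature table is required; a FASTA sequence enables the
    composition/codon/control-region sections.  When ``out_dir`` is given,
    TSV tables and a ``report.json`` mirror are written there.
    """
    record = read_feature_table(table_path)
    if fasta_path is not None:
        seq_rec = read_fasta(fasta_path)
        if record.length != seq_rec.length:
            raise ValueError(
                f"table length {record.length} != sequence length "
                f"{seq_rec.length}")
        record = GenomeRecord(seq_rec.identifier, seq_rec.sequence,
                              features=record.features).validate()
    log.info("loaded %s: %d features, %s bp", record.identifier,
             len(record.features), record.length)

    overlaps = architecture.find_overlaps(record)
    spacers = architecture.find_intergenic_spacers(record)
    order = architecture.extract_gene_order(record)
    ref_order = REFERENCE_ORDERS[reference] if isinstance(reference, str) \
        else reference
    try:
        events = architecture.classify_rearrangements(order, ref_order)
    except Exception as exc:  # gene-set mismatch: report, don't abort
        log.warning("rearrangement classification skipped: %s", exc)
        events = []

    if record.sequence is not None:
        comp = composition.record_composition_table(record)
        usage = composition.codon_usage(composition.pcg_sense_sequences(record))
        ctrl = next((f for f in record.features
                     if f.feature_class == "control"), None)
        if ctrl is not None:
            region = record.feature_sequence(ctrl)
            repeats = cr_mod.find_tandem_repeats(region)
            motifs = {"ATAGA": cr_mod.find_motif(region, "ATAGA"),
                      "ATACTAA": cr_mod.find_motif(region, "ATACTAA",
                                                   max_mismatch=1),
                      "poly-T": cr_mod.find_poly_t(region)}
        else:
            repeats, motifs = "skipped (no control region feature)", {}
    else:
        comp = usage = repeats = motifs = SKIPPED

    report = AnalysisReport(
        identifier=record.identifier, record=record, composition=comp,
        overlaps=overlaps, spacers=spacers, gene_order=order,
        reference=reference if isinstance(reference, str) else "custom",
        events=events, repeats=repeats, motifs=motifs, codon_usage=usage)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(record, out / "features.tsv")
        if isinstance(comp, pd.DataFrame):
            comp.to_csv(out / "composition.tsv", sep="\t", index=False)
            usage.to_frame().to_csv(out / "codon_usage.tsv", sep="\t",
                                    index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in spacers.entries]).to_csv(
            out / "spacers.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in overlaps.entries]).to_csv(
            out / "overlaps.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2)
        log.info("wrote report to %s", out)
    return report
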