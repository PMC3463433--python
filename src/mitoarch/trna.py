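"""tRNA cloverleaf stem-pair accounting and anticodon extraction.

Secondary structures are *consumed*, not predicted: covariance-model or MFE
folding belongs to dedicated predictors, whose output (plus manual
adjustment) is the usual provenance of published mitogenome cloverleafs.
The interchange format is a per-tRNA record with a sequence line and a
dot-bracket line whose four stems are delimited by commas:

    >trnM
    AGTAAGGTCAGCTAATTAAGCTATCGGGCCCATACCCCGAAAATGTTGGTTTAAACCCTTCCTTTACTA
    ((((((( , ..((((.....)))) , (((((..***...))))) , ((((....)))) , )))))))

The five comma-separated segments are acceptor-5', DHU arm, anticodon arm,
TpsiC arm (any variable loop included as dots), and acceptor-3'.  Brackets
are matched globally with one stack; a pair belongs to the arm in which its
opening bracket lies.  The three ``*`` characters mark the anticodon.  A
DHU segment without brackets means the DHU arm is replaced by a simple loop,
as in trnS(AGN) of many arthropods.

Pair classes: Watson-Crick (A-U, G-C), G-U wobble, and mismatches tallied by
unordered identity (A-C and C-A are the same class), reported in the RNA
alphabet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TrnaStructure", "PairClassification", "StructureParseError",
    "ARMS", "classify_pairs", "extract_anticodon",
    "read_structures", "parse_structure",
]

ARMS = ("acceptor", "DHU", "anticodon", "TpsiC")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


class StructureParseError(ValueError):
    pass


@dataclass
class TrnaStructure:
    """A tRNA sequence plus per-arm paired positions (1-based indices)."""

    gene: str
    sequence: str
    arms: dict[str, list[tuple[int, int]]]
    anticodon_positions: tuple[int, int, int] | None = None
    dhu_replaced_by_loop: bool = False

    def validate(self) -> "TrnaStructure":
        n = len(self.sequence)
        seen: set[int] = set()
        for arm, pairs in self.arms.items():
            if arm not in ARMS:
                raise StructureParseError(f"{self.gene}: unknown arm {arm!r}")
            for i, j in pairs:
                if not (1 <= i <= n and 1 <= j <= n):
                    raise StructureParseError(
                        f"{self.gene}: pair ({i},{j}) outside 1..{n}")
                if i in seen or j in seen:
                    raise StructureParseError(
                        f"{self.gene}: position reused across pairs")
                seen.update((i, j))
        if self.anticodon_positions is not None:
            for p in self.anticodon_positions:
                if not 1 <= p <= n:
                    raise StructureParseError(
                        f"{self.gene}: anticodon position {p} out of bounds")
                if p in seen:
                    raise StructureParseError(
                        f"{self.gene}: anticodon position {p} is paired")
        return self


@dataclass
class PairClassification:
    """Per-arm Watson-Crick / wobble / mismatch counts for one or more tRNAs."""

    wc: Counter = field(default_factory=Counter)
    wobble: Counter = field(default_factory=Counter)
    mismatch: Counter = field(default_factory=Counter)
    mismatch_types: Counter = field(default_factory=Counter)

    @property
    def total_wc(self) -> int:
        return sum(self.wc.values())

    @property
    def total_wobble(self) -> int:
        return sum(self.wobble.values())

    @property
    def total_mismatch(self) -> int:
        return sum(self.mismatch.values())

    def noncanonical_by_arm(self) -> dict[str, int]:
        """Mismatch + wobble count per arm (the quantity usually reported)."""
        return {arm: self.mismatch.get(arm, 0) + self.wobble.get(arm, 0)
                for arm in ARMS}

    def merge(self, other: "PairClassification") -> "PairClassification":
        out = PairClassification()
        for attr in ("wc", "wobble", "mismatch", "mismatch_types"):
            getattr(out, attr).update(getattr(self, attr))
            getattr(out, attr).update(getattr(other, attr))
        return out


def _rna(b: str) -> str:
    return "U" if b == "T" else b


def classify_pairs(structure: TrnaStructure) -> PairClassification:
    """Classify every stem pair of a cloverleaf as WC, G-U wobble or mismatch.

    Mismatch identities use the unordered convention (A-C == C-A) in the RNA
    alphabet, e.g. ``U-U`` or ``A-C``.
    """
    structure.validate()
    seq = structure.sequence.upper().replace("U", "T")
    out = PairClassification()
    for arm, pairs in structure.arms.items():
        for i, j in pairs:
            b = (seq[i - 1], seq[j - 1])
            if b in _WC:
                out.wc[arm] += 1
            elif b in _WOBBLE:
                out.wobble[arm] += 1
            else:
                out.mismatch[arm] += 1
                out.mismatch_types["-".join(sorted(_rna(x) for x in b))] += 1
    return out


def extract_anticodon(structure: TrnaStructure) -> str:
    """The anticodon triplet read 5'->3' from the tRNA sense sequence (DNA
    alphabet, e.g. TCT for the UCU anticodon)."""
    if structure.anticodon_positions is None:
        raise StructureParseError(f"{structure.gene}: anticodon positions unset")
    seq = structure.sequence.upper().replace("U", "T")
    return "".join(seq[p - 1] for p in structure.anticodon_positions)


# ---------------------------------------------------------------------------
# Dot-bracket interchange format

def parse_structure(gene: str, sequence: str, bracket_line: str) -> TrnaStructure:
    """Parse one comma-delimited dot-bracket line against its sequence."""
    segments = [s.strip() for s in bracket_line.split(",")]
    if len(segments) != 5:
        raise StructureParseError(
            f"{gene}: expected 5 comma-delimited segments "
            f"(acceptor-5', DHU, anticodon, TpsiC, acceptor-3'), "
            f"got {len(segments)}")
    flat = "".join(segments)
    if len(flat) != len(sequence):
        raise StructureParseError(
            f"{gene}: structure length {len(flat)} != sequence length "
            f"{len(sequence)}")
    seg_of: list[int] = []
    for k, seg in enumerate(segments):
        seg_of.extend([k] * len(seg))
    seg_arm = {0: "acceptor", 1: "DHU", 2: "anticodon", 3: "TpsiC",
               4: "acceptor"}
    arms: dict[str, list[tuple[int, int]]] = {a: [] for a in ARMS}
    stack: list[int] = []
    anticodon: list[int] = []
    for pos0, ch in enumerate(flat):
        if ch == "(":
            stack.append(pos0)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"{gene}: unbalanced ')' at "
                                          f"position {pos0 + 1}")
            i = stack.pop()
            arms[seg_arm[seg_of[i]]].append((i + 1, pos0 + 1))
        elif ch == "*":
            anticodon.append(pos0 + 1)
        elif ch != ".":
            raise StructureParseError(f"{gene}: illegal character {ch!r}")
    if stack:
        raise StructureParseError(f"{gene}: unbalanced '(' remaining")
    if anticodon and len(anticodon) != 3:
        raise StructureParseError(
            f"{gene}: anticodon marker must cover exactly 3 positions")
    for arm in arms:
        arms[arm].sort()
    return TrnaStructure(
        gene=gene, sequence=sequence.upper(),
        arms={a: p for a, p in arms.items()},
        anticodon_positions=tuple(anticodon) if anticodon else None,
        dhu_replaced_by_loop=not arms["DHU"],
    ).validate()


def read_structures(path: str | Path) -> list[TrnaStructure]:
    """Read a multi-record structure file (``>name`` / sequence / brackets)."""
    structures = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureParseError(
                f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise StructureParseError(f"{path}: truncated record at end")
        structures.append(parse_structure(
            lines[i][1:].strip(), lines[i + 1].strip().replace(" ", ""),
            lines[i + 2]))
        i += 3
    return structures
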