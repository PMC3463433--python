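# Methods

## Data model

A genome is a circular sequence over {A,C,G,T,N} plus an ordered feature
table with 1-based inclusive coordinates on the majority (J) strand;
minority-strand (N) features keep majority-strand coordinates. A feature
with `end < start` wraps the origin; its length is
`(L − start + 1) + end`. Records may be coordinate-only (no sequence), the
mode used for printed annotation tables; architecture accounting works in
that mode, composition/codon statistics require the sequence. The
linearization convention puts trnI at position 1 and the A+T-rich region
last; GenBank records are rotated to this convention on load. N residues
are allowed in sequences but excluded from composition denominators so that
percentages stay comparable across records.

## PCG boundary refinement

Boundaries are refined under the invertebrate mitochondrial code
(translation table 5, via Biopython's codon tables). Legitimate starts are
ATN, GTG, TTG and GTT, with per-gene overrides (cox1 → CGA) handled as
overrides rather than globally legitimizing CGA, since that start is a
gene-specific convention. The start scan anchors at the hinted 5' end and
walks downstream offset by offset over a window (default 60 bp; an
`upstream_slack` parameter, default 0, lets the scan begin before the
hint). The window width is a free parameter of the procedure, not a
biologically derived constant.

The stop scan walks in frame from the start. A full TAA/TAG that ends
before the downstream same-strand gene is accepted; otherwise the gene is
truncated immediately before that gene with token `TA-` or `T--`, and the
truncated bases must literally read TA/T. The "downstream gene" used to
bound the scan is the nearest same-strand feature *starting after the
hinted 3' end*. This bound deliberately excludes overlap partners: the
canonical atp8/atp6 arrangement keeps atp8's full TAA seven bases inside
atp6, and treating atp6 as a truncation boundary would mis-call it. If the
downstream gene starts on a codon boundary no truncated stop is
constructible and the gene is reported as an open ORF.

Codon totals count sense codons including the start codon and excluding the
stop: each gene contributes `(length − stop_length)/3` with stop_length
3/2/1 for `TAA|TAG` / `TA-` / `T--`.

## Composition and codon usage

Percentages are reported to two decimals; AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C) are computed on the majority strand, and a zero
denominator yields NaN, never 0. Reverse-complementing a sequence negates
both skews exactly (a property test). Codon-position composition and codon
usage operate on stop-trimmed *sense* sequences (minority-strand genes
reverse-complemented) concatenated in genomic order; whether published
"PCG" composition rows complement minority-strand genes first is not
standardized, so the sense-strand convention is fixed here and documented.
RSCU families split Leu and Ser into their two boxes each (10 + 2
families covering the 62 sense codons of table 5); within a family
Σ RSCU = family size whenever the family is used at all, and zero-count
families report NaN.

## Architecture accounting

Overlaps and spacers are evaluated between consecutive features in circular
order only (every reported overlap in typical mitogenomes is an adjacent
pair; nested features are a validation concern, not an overlap). The
signed gap between consecutive features is `start₂ − end₁ − 1`, with the
origin-spanning pair closed by `(L − end₁) + (start₂ − 1)`. The noncoding
total counts every positive inter-feature gap, including gaps adjacent to
the control region but never its interior — the control region must be a
feature. Every validated record satisfies
Σ lengths + Σ spacers − Σ overlaps = L.

Gene orders are circular sequences of (gene, strand) pairs with
rotation-invariant equality; the canonical rotation aligns on cox1, which
is present and unmoved in all known lepidopteran arrangements. Two
reference orders are built in: the ancestral insect arrangement
(*Drosophila yakuba*) and the derived ditrysian arrangement with trnM
translocated ahead of trnI-trnQ. Rearrangement classification searches for
the smallest set of genes whose removal makes the two circular orders
equal (exhaustive over subsets of the context-changed genes, capped at six
movers), breaking ties in favour of tRNA movers, which are empirically the
common movers. Each mover is then classed by the invariant: context
unchanged + strand flipped → local inversion; context changed + strand
kept → translocation; both changed → remote inversion. How to attribute
events when two blocks move symmetrically is genuinely underdetermined;
the minimal-mover rule is this package's documented choice.

## Control-region analysis

The tandem-repeat detector is a bespoke period scan (it does not reproduce
the alignment scoring of external repeat finders). For each candidate unit
length u in [min_unit, max_unit] (defaults 10–300 bp, bracketing reported
lepidopteran macrorepeats of ~50–250 bp), positions whose lag-u
self-similarity over a u-window reaches 1 − max_mismatch_frac seed an
extension: successive u-windows are accepted while they match the running
consensus within ceil(max_mismatch_frac · u) mismatches (default 10%).
The consensus is the per-column majority over full copies; partial copies
do not vote. Array edges are then refined with a match +1 / mismatch −2
score: a trailing partial copy is the best-scoring consensus prefix, a
leading partial the best-scoring suffix, and low-scoring edge bases are
trimmed — without this, flanking sequence admitted by the mismatch
tolerance systematically inflates the span. Extension re-anchors at the
trimmed start until stable so that a seed landing a few bases off does not
put every window out of phase. Copy number is span/unit to one decimal
(so 8 copies + 57/113 → 8.5 and 4 + 101/107 → 4.9), and calls need
min_copies (default 2.5). Overlapping calls collapse to the longest span,
then the smallest unit; spans differing by less than one (smaller) unit
count as ties, which prevents the 2u harmonic of an array — essentially
the same span — from outranking the fundamental period.

Motif search is plain Hamming matching with overlapping hits; the poly-T
scan reports maximal runs ≥ min_len (default 16 bp, the short end of the
16–22 bp stretch conserved in ditrysian control regions).

## tRNA stem accounting

Secondary structures are consumed, not predicted. The interchange format is
a sequence line plus a comma-delimited dot-bracket line whose five segments
are acceptor-5', DHU, anticodon, TψC (variable loop as dots) and
acceptor-3'; brackets match globally on one stack and a pair belongs to the
arm of its opening bracket; `***` marks the anticodon; an empty DHU segment
flags the arm-replaced-by-loop topology of trnS(AGN). Pairs are classed WC
{A-U, G-C}, wobble {G-U}, else mismatch, with unordered identities in the
RNA alphabet (A-C ≡ C-A). Note that complementing both members preserves
WC-ness and the pair total but not the wobble/mismatch split (G-U ↔ C-A).

## Synthetic genomes

The generator emulates the architecture the analyses assume, with defaults
chosen to mirror a hepialid mitogenome: ancestral gene order, per-gene
length targets matching the T. renzhiensis table (hence 3,720 sense codons
by construction), whole-genome A+T target 0.82, a 7-bp atp8/atp6 overlap,
the canonical eight truncated stops, spacers reproducing the published gap
pattern, and a control region of 8 × 113 bp + 57 bp at noise 0 between
200-bp flanks. PCG codons are sampled from per-codon weights (default:
i.i.d.-base weights at the A+T target, stops excluded), so coding sequences
are stop-free in frame by construction. tRNA/rRNA sequences are A+T-biased
placeholders (tRNAs carry the canonical anticodon at positions 33–35);
they make no attempt at foldability. The PCG/PCG overlap is constructed so
the downstream ATG and the upstream TAA share the overlap without either
frame crossing a stop; this construction requires overlap ≡ 1 (mod 3) on
the majority strand — the canonical atp8/atp6 geometry — and other PCG/PCG
geometries are rejected at validation. Control-region flanks are
non-repetitive by construction: the six flank bases at each array junction
are forced to differ from the repeat continuation, so planted copy numbers
have exact boundaries. The noise model is i.i.d. substitution only (no
indels), keeping planted units length-exact for copy-number tests. All
randomness flows from one seeded NumPy generator; equal seeds give
byte-identical genomes.

What passing tests on synthetic data do *not* show: recovery on real
sequence with homology-ambiguous starts, rRNA boundary placement (which in
practice needs orthologous alignment), tRNA folding, or repeat arrays with
indel-mutated units.

## Parameter-recovery checks

Boundary recovery is exact on generator truth tables across seeds because
hints anchor the start scan at the true 5' end and internal codons exclude
stops. RSCU recovery is measured as Spearman correlation between realized
RSCU and the RSCU *implied* by the sampling weights (weights normalized
within each family exactly as observed counts are); raw weights and RSCU
live on different normalizations, so comparing them directly would
understate recovery. At 3,720 codons the correlation is ≈0.87 against the
>0.8 requirement.

## Problem sizes

Tests and the acceptance script run at the natural scale of the problem:
single ~16-kb genomes, control regions of ~1.4 kb, and sweeps of 20–25
seeds for the stochastic recovery properties. The whole suite completes in
well under a minute.

## Known limitations

- No de-novo gene finding: PCG refinement needs region hints, tRNA/rRNA
  coordinates are inputs.
- The minimal-mover classifier is exhaustive over ≤6 movers; heavily
  shuffled genomes (beyond anything reported in Lepidoptera) would need a
  breakpoint-distance method, which is out of scope.
- The repeat detector assumes substitution-only divergence between copies;
  indel-bearing arrays would need alignment-based extension.
- Multi-chromosome mitogenomes and GFF3 input are unsupported.
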