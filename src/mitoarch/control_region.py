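"""A+T-rich (control) region characterization.

The control region of insect mitogenomes commonly carries arrays of long
tandem repeats ("macrorepeats", >50 bp units) plus short conserved motifs
(in ditrysian Lepidoptera: ATAGA followed by a 16-22 bp poly-T stretch near
the rrnS boundary, and ATACTAA upstream of nad1).  This module detects both.

The tandem-repeat detector is a period scan: for every candidate unit length
``u`` it looks for maximal arrays in which each successive ``u``-window
matches the array consensus within a Hamming-distance tolerance, then scores
a trailing partial copy.  Copy number is reported as span / unit length to
one decimal, so eight full copies of a 113-bp unit plus a 57-bp partial copy
report 8.5 copies.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TandemRepeatArray", "MotifHit",
    "find_tandem_repeats", "find_motif", "find_poly_t",
]


@dataclass
class TandemRepeatArray:
    """A tandem repeat array within a region (1-based inclusive span)."""

    unit_length: int
    consensus_unit: str
    copies: float  # fractional, one decimal
    start: int
    end: int
    mismatch_fraction: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifHit:
    motif: str
    position: int  # 1-based within the searched region
    mismatches: int
    matched_text: str


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _consensus(windows: list[str]) -> str:
    """Majority base per column over the full copies (partials do not vote)."""
    arr = np.stack([_to_array(w) for w in windows])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append(chr(vals[np.argmax(counts)]))
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_array(region: str, anchor: int, u: int,
                  max_mm_frac: float) -> tuple[int, int, str, int] | None:
    """Grow a repeat array of period ``u`` anchored at 0-based ``anchor``.

    Full copies are accepted while each window matches the running consensus
    within ``max_mm_frac * u`` mismatches.  Both edges are then refined with
    a match +1 / mismatch -2 score so that flanking sequence admitted by the
    mismatch tolerance is trimmed: the trailing partial copy is the
    prefix of the consensus maximizing the score, and the leading edge drops
    the prefix with the lowest cumulative score.  Returns
    (start, end_exclusive, consensus_in_start_phase, mismatches) or None.
    """
    n = len(region)
    tol = math.ceil(max_mm_frac * u)
    windows = [region[anchor:anchor + u]]
    pos = anchor + u
    while pos + u <= n:
        cons = _consensus(windows) if len(windows) > 1 else windows[0]
        w = region[pos:pos + u]
        if _hamming(w, cons) > tol:
            break
        windows.append(w)
        pos += u
    if len(windows) < 2:
        return None
    cons = _consensus(windows)
    # trailing partial copy: best-scoring consensus prefix
    best_p, best_score = 0, 0
    score = 0
    for p in range(1, min(u, n - pos) + 1):
        score += 1 if region[pos + p - 1] == cons[p - 1] else -2
        if score > best_score:
            best_p, best_score = p, score
    end = pos + best_p
    # leading partial copy: best-scoring consensus suffix (recovers bases an
    # anchor that landed inside the array would otherwise miss)
    lead, lbest, lscore = 0, 0, 0
    for p in range(1, min(u, anchor) + 1):
        lscore += 1 if region[anchor - p] == cons[u - p] else -2
        if lscore > lbest:
            lbest, lead = lscore, p
    start = anchor - lead
    phi = (u - lead) % u  # cons index of region[start]

    def ref(i: int) -> str:
        return cons[(phi + i) % u]

    # leading edge: drop the minimum-cumulative-score prefix
    cum, cmin, t = 0, 0, 0
    for i in range(min(u, end - start)):
        cum += 1 if region[start + i] == ref(i) else -2
        if cum < cmin:
            cmin, t = cum, i + 1
    start += t
    phi = (phi + t) % u
    # trailing edge likewise: a final "full" window may have swallowed flank
    # sequence within the mismatch tolerance
    cum, cmin, r = 0, 0, 0
    for j in range(min(u, end - start)):
        i = end - 1 - j
        cum += 1 if region[i] == cons[(phi + (i - start)) % u] else -2
        if cum < cmin:
            cmin, r = cum, j + 1
    end -= r
    if end - start < 2 * u:  # no longer two full copies after trimming
        return None
    cons = cons[phi:] + cons[:phi]  # phase-align consensus to the start
    mm = sum(1 for i in range(end - start)
             if region[start + i] != cons[i % u])
    return start, end, cons, mm


def find_tandem_repeats(region: str, min_unit: int = 10, max_unit: int = 300,
                        min_copies: float = 2.5,
                        max_mismatch_frac: float = 0.1) -> list[TandemRepeatArray]:
    """Detect tandem repeat arrays in a nucleotide region by period scan.

    For each candidate period, positions with high self-similarity at lag
    ``u`` seed consensus-extension; overlapping calls collapse to the
    highest-scoring (longest span, then smallest unit).  ``copies`` is
    span / unit, rounded to one decimal, and must reach ``min_copies``.
    """
    region = region.upper()
    n = len(region)
    if n == 0:
        return []
    max_unit = min(max_unit, n // 2)
    if min_unit < 2 or min_unit > max_unit:
        return []
    x = _to_array(region)
    calls: list[TandemRepeatArray] = []
    for u in range(min_unit, max_unit + 1):
        m = (x[:-u] == x[u:]).astype(np.float64)
        if len(m) < u:
            continue
        # fraction of self-matches at lag u over each u-long window
        cs = np.concatenate([[0.0], np.cumsum(m)])
        frac = (cs[u:] - cs[:-u]) / u
        anchors = np.flatnonzero(frac >= 1.0 - max_mismatch_frac)
        skip_until = -1
        for a in anchors:
            if a < skip_until:
                continue
            # re-anchor at the trimmed start until stable: an anchor a few
            # bases early would otherwise put every window out of phase
            a0, ext = int(a), None
            for _ in range(4):
                nxt = _extend_array(region, a0, u, max_mismatch_frac)
                if nxt is None or nxt[0] == a0:
                    ext = nxt
                    break
                a0, ext = nxt[0], nxt
            if ext is None:
                continue
            start, end, cons, mm = ext
            span = end - start
            copies = round(span / u, 1)
            if copies < min_copies:
                continue
            calls.append(TandemRepeatArray(
                unit_length=u, consensus_unit=cons, copies=copies,
                start=start + 1, end=end, mismatch_fraction=mm / span))
            skip_until = end  # do not re-seed inside this array
    # collapse overlapping calls: longest span wins, then smallest unit;
    # spans closer than one (smaller) unit carry no extra copy information
    # and count as ties, so a 2u harmonic never beats the fundamental period
    def beats(a: TandemRepeatArray, b: TandemRepeatArray) -> int:
        if abs(a.span - b.span) <= min(a.unit_length, b.unit_length):
            return a.unit_length - b.unit_length
        return b.span - a.span

    calls.sort(key=functools.cmp_to_key(beats))
    kept: list[TandemRepeatArray] = []
    for c in calls:
        if all(c.end < k.start or c.start > k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def find_motif(region: str, motif: str, max_mismatch: int = 0) -> list[MotifHit]:
    """All (possibly overlapping) positions where the motif matches within
    ``max_mismatch`` Hamming distance."""
    if not motif:
        raise ValueError("motif must be nonempty")
    region = region.upper()
    motif = motif.upper()
    hits = []
    for i in range(len(region) - len(motif) + 1):
        text = region[i:i + len(motif)]
        mm = _hamming(text, motif)
        if mm <= max_mismatch:
            hits.append(MotifHit(motif, i + 1, mm, text))
    return hits


def find_poly_t(region: str, min_len: int = 16) -> list[MotifHit]:
    """Maximal runs of T of length >= ``min_len`` (1-based positions)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    region = region.upper()
    hits = []
    i = 0
    while i < len(region):
        if region[i] == "T":
            j = i
            while j < len(region) and region[j] == "T":
                j += 1
            if j - i >= min_len:
                hits.append(MotifHit("T" * (j - i), i + 1, 0, region[i:j]))
            i = j
        else:
            i += 1
    return hits
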