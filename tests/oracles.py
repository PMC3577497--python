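"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-base position sets, exhaustive
span enumeration, explicit textbook loops — and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import math

from scipy import stats

_PRIORITY = {"=": 0, "c": 1, "j": 2, "o": 3, "i": 4, "x": 5, "s": 6, "u": 7}
_STOPS = ("TAA", "TAG", "TGA")


class NaiveTranscript:
    """Per-base view of a transcript for the brute-force classifier."""

    def __init__(self, t):
        self.t = t
        self.chrom = t.chrom
        self.strand = t.strand
        self.start = t.start
        self.end = t.end
        self.tid = t.transcript_id
        self.exon_positions = set()
        for e in t.exons:
            self.exon_positions.update(range(e.start, e.end + 1))
        self.introns = [
            (a.end + 1, b.start - 1) for a, b in zip(t.exons, t.exons[1:])
        ]
        self.intron_positions = set()
        for s, e in self.introns:
            self.intron_positions.update(range(s, e + 1))
        self.chain = tuple(self.introns)
        self.junctions = set(self.introns)
        self.exons = [(e.start, e.end) for e in t.exons]


def _pair_code(q: NaiveTranscript, r: NaiveTranscript) -> str | None:
    if q.chrom != r.chrom:
        return None
    strand_known = q.strand in "+-"
    if strand_known:
        same = q.strand == r.strand
        opposite = not same
    else:
        same, opposite = True, False
    if same:
        if strand_known and q.chain and q.chain == r.chain:
            return "="
        if len(q.exons) >= 2:
            n = len(q.chain)
            is_sub = n > 0 and any(
                r.chain[k : k + n] == q.chain for k in range(len(r.chain) - n + 1)
            )
            if is_sub and r.start <= q.start and q.end <= r.end:
                return "c"
        else:
            if any(s <= q.start and q.end <= e for s, e in r.exons):
                return "c"
        if strand_known and q.junctions & r.junctions:
            return "j"
        if q.exon_positions & r.exon_positions:
            return "o"
        if any(s <= q.start and q.end <= e for s, e in r.introns):
            return "i"
        return None
    if opposite:
        if q.exon_positions & r.exon_positions:
            return "x"
        if (q.intron_positions & r.intron_positions) and not (
            q.exon_positions & r.exon_positions
        ):
            return "s"
    return None


def brute_force_classify(
    query: NaiveTranscript, refs: list[NaiveTranscript]
) -> tuple[str, str | None]:
    """Best (code, reference id) over every reference, no interval index."""
    best = None
    for r in refs:
        code = _pair_code(query, r)
        if code is None:
            continue
        key = (_PRIORITY[code], (r.chrom, r.start, r.tid))
        if best is None or key < best[0]:
            best = (key, r.tid, code)
    if best is None:
        return "u", None
    return best[2], best[1]


def exhaustive_orf(seq: str) -> tuple[int, int]:
    """(longest ORF nt length, earliest start offset) by enumerating every
    ATG...stop span in all three frames, including stop-less runs."""
    s = seq.upper()
    best_len, best_start = 0, -1
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        i = start
        length = None
        while i + 3 <= len(s):
            if s[i : i + 3] in _STOPS and i > start:
                length = i - start
                break
            i += 3
        if length is None:
            length = ((len(s) - start) // 3) * 3
        if length > best_len or (length == best_len and length > 0 and (
            best_start == -1 or start < best_start
        )):
            best_len, best_start = length, start
    return best_len, best_start


def bh_reference(p_values) -> list[float]:
    """Textbook Benjamini-Hochberg step-up, explicit loops."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = float("inf")
    for rank in range(m, 0, -1):
        idx = indexed[rank - 1]
        value = min(1.0, m * p_values[idx] / rank)
        running_min = min(running_min, value)
        q[idx] = running_min
    return q


def welch_reference(a, b) -> tuple[float, float]:
    """Welch t statistic and two-sided p from the textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def mann_whitney_probability(pos, neg) -> float:
    """P(X_pos > X_neg) + 0.5 P(X_pos = X_neg) by direct pair counting."""
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))
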