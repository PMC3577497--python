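"""Class-code assignment of assembled transcripts against a reference annotation.

Reimplements the cuffcompare-style transfrag classification: every
assembled transcript ("transfrag") receives exactly one one-letter class
code describing its structural relation to the closest reference
transcript:

=  complete match of intron chain (same strand)
c  contained: the transfrag's chain is a contiguous sub-chain of a
   reference chain and all exons lie within the reference span
j  at least one splice junction (donor and acceptor coordinates) shared
i  transfrag falls entirely within a reference intron (same strand)
o  generic exonic overlap with a reference exon on the same strand
x  exonic overlap with the reference on the opposite strand
s  an intron overlaps a reference intron on the opposite strand, with no
   exonic overlap
u  unknown / intergenic: no overlap with any reference span

Codes are evaluated per reference transcript in the priority order above
and the best code across the whole reference set wins; ties between
reference transcripts yielding the same code break on (chrom, start,
transcript_id) so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .transcript_model import (
    AnnotationSet,
    GenomicInterval,
    STRAND_UNKNOWN,
    TranscriptModel,
    intron_chain,
    splice_junctions,
)

CLASS_CODES = ("=", "c", "j", "o", "i", "x", "s", "u")
#: the five categories scanned for novel lncRNAs (pipeline step 1)
CANDIDATE_CODES = frozenset({"i", "j", "o", "u", "x"})

_PRIORITY = {code: rank for rank, code in enumerate(CLASS_CODES)}


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    code: str
    ref_transcript_id: str | None = None
    ref_gene_id: str | None = None
    strand_unknown: bool = False

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"invalid class code {self.code!r}")
        if (self.code != "u") != (self.ref_transcript_id is not None):
            raise ValueError("reference ids must be present iff code is not 'u'")


def _chain_coords(t: TranscriptModel) -> tuple[tuple[int, int], ...]:
    if t.exon_count < 2:
        return ()
    return tuple((iv.start, iv.end) for iv in intron_chain(t))


def _is_contiguous_subchain(
    sub: Sequence[tuple[int, int]], full: Sequence[tuple[int, int]]
) -> bool:
    n = len(sub)
    if n == 0 or n > len(full):
        return False
    return any(tuple(full[k : k + n]) == tuple(sub) for k in range(len(full) - n + 1))


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for ea in a.exons:
        for eb in b.exons:
            if ea.start <= eb.end and eb.start <= ea.end:
                return True
    return False


def _intronic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.exon_count < 2 or b.exon_count < 2:
        return False
    for ia in intron_chain(a):
        for ib in intron_chain(b):
            if ia.start <= ib.end and ib.start <= ia.end:
                return True
    return False


def _span_in_single_intron(t: TranscriptModel, ref: TranscriptModel) -> bool:
    if ref.exon_count < 2:
        return False
    return any(
        iv.start <= t.start and t.end <= iv.end for iv in intron_chain(ref)
    )


def _code_against(t: TranscriptModel, ref: TranscriptModel) -> str | None:
    """Best code *t* can earn against one reference transcript, or None."""
    strand_known = t.strand != STRAND_UNKNOWN
    if strand_known:
        same = t.strand == ref.strand
        opposite = not same
    else:
        # unknown-strand transfrags match either strand for overlap codes
        # but cannot share junctions or chains
        same, opposite = True, False

    if same:
        chain_t = _chain_coords(t)
        chain_r = _chain_coords(ref)
        if strand_known and chain_t and chain_t == chain_r:
            return "="
        if t.exon_count >= 2:
            if (
                _is_contiguous_subchain(chain_t, chain_r)
                and ref.start <= t.start
                and t.end <= ref.end
            ):
                return "c"
        else:
            if any(
                e.start <= t.start and t.end <= e.end for e in ref.exons
            ):
                return "c"
        if strand_known and splice_junctions(t) & splice_junctions(ref):
            return "j"
        if _exonic_overlap(t, ref):
            return "o"
        if _span_in_single_intron(t, ref):
            return "i"
        return None
    if opposite:
        if _exonic_overlap(t, ref):
            return "x"
        if _intronic_overlap(t, ref) and not _exonic_overlap(t, ref):
            return "s"
    return None


def classify_transcript(t: TranscriptModel, ref: AnnotationSet) -> ClassificationResult:
    """Assign *t* its class code against the reference annotation."""
    strand_unknown = t.strand == STRAND_UNKNOWN
    best: tuple[int, tuple, TranscriptModel, str] | None = None
    for r in ref.overlapping(t.chrom, t.start, t.end):
        code = _code_against(t, r)
        if code is None:
            continue
        key = (_PRIORITY[code], (r.chrom, r.start, r.transcript_id))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], r, code)
    if best is None:
        return ClassificationResult(t.transcript_id, "u", strand_unknown=strand_unknown)
    _, _, r, code = best
    return ClassificationResult(
        t.transcript_id,
        code,
        ref_transcript_id=r.transcript_id,
        ref_gene_id=r.gene_id,
        strand_unknown=strand_unknown,
    )


def classify(
    transcripts: Iterable[TranscriptModel], ref: AnnotationSet
) -> list[tuple[TranscriptModel, ClassificationResult]]:
    """Classify every transcript; convenience wrapper pairing inputs with results."""
    return [(t, classify_transcript(t, ref)) for t in transcripts]


def structure_key(t: TranscriptModel) -> tuple:
    """Structural identity: intron chain for multi-exon, exact exon for single-exon."""
    if t.exon_count >= 2:
        return ("chain", t.chrom, t.strand, _chain_coords(t))
    e = t.exons[0]
    return ("exon", t.chrom, t.strand, e.start, e.end)


def merge_annotations(sets: Sequence[Iterable[TranscriptModel]]) -> AnnotationSet:
    """Union of annotation sets, deduplicated by transcript structure.

    Multi-exon transcripts are identical when their (chrom, strand, intron
    chain) agree — exon-end padding differences collapse; single-exon
    transcripts require the exact exon interval.  The first-seen source's
    ids are kept.
    """
    if not sets:
        raise ValueError("merge_annotations requires at least one input set")
    seen: set[tuple] = set()
    merged: list[TranscriptModel] = []
    for annotation in sets:
        for t in annotation:
            key = structure_key(t)
            if key in seen:
                continue
            seen.add(key)
            merged.append(t)
    return AnnotationSet(merged)


def extract_category(
    classified: Iterable[tuple[TranscriptModel, ClassificationResult]],
    wanted: frozenset[str] | set[str] = CANDIDATE_CODES,
) -> list[TranscriptModel]:
    """Pipeline step 1: keep transcripts whose class code is in *wanted*."""
    return [t for t, res in classified if res.code in wanted]


def categorize_summary(
    classified: Iterable[ClassificationResult | tuple[TranscriptModel, ClassificationResult]],
) -> pd.DataFrame:
    """Per-code counts and percentages (the Table-style category summary)."""
    codes = []
    for item in classified:
        res = item[1] if isinstance(item, tuple) else item
        codes.append(res.code)
    total = len(codes)
    rows = []
    counts = pd.Series(codes).value_counts() if codes else pd.Series(dtype=int)
    for code in CLASS_CODES:
        if code in counts:
            n = int(counts[code])
            rows.append({"code": code, "count": n, "percentage": 100.0 * n / total})
    return pd.DataFrame(rows, columns=["code", "count", "percentage"])
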