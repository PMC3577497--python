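"""Spliced-sequence extraction and the longest-putative-ORF statistic.

A real non-coding RNA has no open reading frame, so candidates are scored
by a proxy: the longest ATG-anchored in-frame codon run on the sense
strand, extending to the base before the first in-frame stop (TAA/TAG/TGA)
or, when no stop occurs, to the last complete codon.  The reported ORF
length excludes the stop codon, so 300 nt corresponds exactly to 100 aa.
Candidates whose longest putative ORF reaches 300 nt are treated as
protein-coding-like and removed; transcripts of exonic length <= 200 nt
fail the lncRNA length definition and are removed earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .transcript_model import (
    STRAND_REVERSE,
    STRAND_UNKNOWN,
    TranscriptModel,
    exonic_length,
)

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class SplicedSequence:
    """A transcript's nucleotide sequence, 5'->3' on its sense strand."""

    transcript_id: str
    bases: str


@dataclass(frozen=True)
class OrfResult:
    """Longest putative ORF in transcript coordinates.

    ``start_offset`` is the 0-based offset of the ATG (-1 when no
    ATG-anchored ORF exists); ``nt_length`` excludes the stop codon and is
    always divisible by 3; ``has_stop`` is False for ORFs running off the
    3' end.
    """

    start_offset: int
    nt_length: int
    aa_length: int
    has_stop: bool
    frame: int

    def __post_init__(self) -> None:
        if self.nt_length % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.aa_length * 3 != self.nt_length:
            raise ValueError("aa_length must equal nt_length / 3")


_NO_ORF = OrfResult(start_offset=-1, nt_length=0, aa_length=0, has_stop=False, frame=-1)


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta or plain dict of strings."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise ValueError(f"chromosome {chrom!r} absent from genome FASTA") from exc
    if end > len(record):
        raise ValueError(
            f"exon {start}-{end} extends beyond end of {chrom} (length {len(record)})"
        )
    piece = record[start - 1 : end]
    seq = getattr(piece, "seq", piece)
    return str(seq)


def spliced_sequence(
    t: TranscriptModel, genome: Mapping[str, object]
) -> SplicedSequence:
    """Concatenate exon sequences in genomic order; reverse-complement the
    whole for '-' strand transcripts.  Output is uppercase with N preserved."""
    if t.strand == STRAND_UNKNOWN:
        raise ValueError(
            f"transcript {t.transcript_id}: strand unknown, cannot orient sequence"
        )
    parts = [_fetch(genome, t.chrom, e.start, e.end) for e in t.exons]
    seq = "".join(parts).upper()
    if t.strand == STRAND_REVERSE:
        seq = str(Seq(seq).reverse_complement())
    return SplicedSequence(transcript_id=t.transcript_id, bases=seq)


def longest_orf(seq: SplicedSequence | str) -> OrfResult:
    """Longest ATG-anchored ORF over the three sense-strand frames.

    Ties break to the smallest start offset.  Codons containing N never
    match ATG or a stop codon.
    """
    s = (seq.bases if isinstance(seq, SplicedSequence) else seq).upper()
    n = len(s)
    best = _NO_ORF
    for frame in range(3):
        open_start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = s[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOP_CODONS:
                length = i - open_start
                if length > best.nt_length or (
                    length == best.nt_length and open_start < best.start_offset
                ):
                    best = OrfResult(open_start, length, length // 3, True, frame)
                open_start = None
            i += 3
        if open_start is not None:
            length = ((n - open_start) // 3) * 3
            if length > best.nt_length or (
                length == best.nt_length
                and (best.nt_length == 0 or open_start < best.start_offset)
            ):
                best = OrfResult(open_start, length, length // 3, False, frame)
    return best


def translate(orf: OrfResult, seq: SplicedSequence) -> str:
    """Standard-genetic-code translation of the ORF codons (no stop symbol).

    Codons containing N translate to 'X'.
    """
    if orf.nt_length == 0:
        raise ValueError("cannot translate a zero-length ORF")
    region = seq.bases[orf.start_offset : orf.start_offset + orf.nt_length]
    return str(Seq(region).translate())


def extract_length(
    transcripts: Iterable[TranscriptModel], min_length_nt: int = 200
) -> list[TranscriptModel]:
    """Pipeline step 2: keep transcripts with exonic length > min (strict)."""
    return [t for t in transcripts if exonic_length(t) > min_length_nt]


def extract_orf(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, object],
    max_orf_nt: int = 300,
) -> tuple[list[TranscriptModel], dict[str, OrfResult]]:
    """Pipeline step 3: keep transcripts whose longest putative ORF is
    strictly below *max_orf_nt*.  Returns (retained, per-transcript ORF
    results for all inputs)."""
    retained = []
    results: dict[str, OrfResult] = {}
    for t in transcripts:
        orf = longest_orf(spliced_sequence(t, genome))
        results[t.transcript_id] = orf
        if orf.nt_length < max_orf_nt:
            retained.append(t)
    return retained, results
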