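"""Domain types for genomic transcripts plus GTF readers/writers.

Coordinates are 1-based and inclusive at every file interface, following the
GTF convention.  A transcript is an ordered chain of disjoint exons on a
single chromosome and strand; everything downstream (classification against
a reference annotation, length/ORF filters, expression filters) operates on
these objects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

STRAND_FORWARD = "+"
STRAND_REVERSE = "-"
STRAND_UNKNOWN = "."

_VALID_STRANDS = (STRAND_FORWARD, STRAND_REVERSE, STRAND_UNKNOWN)


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one chromosome.

    ``start`` and ``end`` are 1-based inclusive; ``strand`` is '+', '-' or
    '.' (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) < start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded multi- (or single-) exon transcript.

    ``exons`` are sorted by start, pairwise disjoint, separated by at least
    one intronic base, and share one chromosome and strand.  ``fpkm`` holds
    the expression estimate attached by the assembler (``None`` when the
    source GTF carries no FPKM attribute).  ``attributes`` preserves any
    further GTF attributes as opaque text so files round-trip.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    fpkm: float | None = None
    source_label: str = "lncrscan"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        exons = tuple(sorted(exons, key=lambda e: e.start))
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end + 1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping or abutting exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
        object.__setattr__(self, "exons", exons)
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError(f"{self.transcript_id}: negative FPKM {self.fpkm}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def exonic_length(t: TranscriptModel) -> int:
    """Total exonic length in nucleotides (the 'transcript length')."""
    return sum(e.end - e.start + 1 for e in t.exons)


def intron_chain(t: TranscriptModel) -> tuple[GenomicInterval, ...]:
    """Ordered introns between consecutive exons.

    Each intron runs from the base after one exon to the base before the
    next; its boundary pair is a splice junction.  Raises on single-exon
    input, which has no chain.
    """
    if t.exon_count < 2:
        raise ValueError(
            f"{t.transcript_id}: intron chain undefined for single-exon transcript"
        )
    return tuple(
        GenomicInterval(t.chrom, prev.end + 1, nxt.start - 1, t.strand)
        for prev, nxt in zip(t.exons, t.exons[1:])
    )


def splice_junctions(t: TranscriptModel) -> frozenset[tuple[int, int]]:
    """Splice junctions as (donor, acceptor) intron boundary coordinate pairs."""
    if t.exon_count < 2:
        return frozenset()
    return frozenset((iv.start, iv.end) for iv in intron_chain(t))


class AnnotationSet:
    """A collection of transcripts with a per-chromosome span interval index.

    ``overlapping`` returns exactly the transcripts whose genomic span
    intersects a query interval (strand-agnostic; callers apply strand
    policy).  Results are ordered by (start, transcript_id) so queries are
    deterministic.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: list[TranscriptModel] = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for idx, t in enumerate(self._transcripts):
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            # interval tree uses half-open coordinates
            tree.addi(t.start, t.end + 1, idx)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts)

    def __len__(self) -> int:
        return len(self._transcripts)

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return list(self._transcripts)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self._transcripts[iv.data] for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))


# --- GTF I/O -----------------------------------------------------------------

_ATTR_RE = re.compile(r'\s*([^\s;]+)\s+("[^"]*"|[^;]*?)\s*;')
_CORE_ATTRS = ("transcript_id", "gene_id", "FPKM")


def _parse_attribute_field(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(raw):
        key, value = m.group(1), m.group(2)
        if key not in attrs:
            attrs[key] = value
    if "transcript_id" not in attrs:
        raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
    return attrs


def _unquote(value: str) -> str:
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1]
    return value


def read_gtf(
    path: str | Path,
    attribute_names: frozenset[str] | set[str] = frozenset({"FPKM"}),
) -> list[TranscriptModel]:
    """Read a Cufflinks-dialect GTF into transcript models.

    Exon features define structure; ``transcript`` features contribute
    attributes only.  The ``FPKM`` attribute is parsed as a float when
    listed in *attribute_names* and present; all other attributes are kept
    as opaque text for round-tripping.  Malformed lines raise
    :class:`GtfParseError` naming the line number.
    """
    path = Path(path)
    # per transcript id: (gene_id, strand, chrom, exons, extra attrs, fpkm)
    order: list[str] = []
    exons: dict[str, list[GenomicInterval]] = {}
    gene_ids: dict[str, str] = {}
    sources: dict[str, str] = {}
    extras: dict[str, dict[str, str]] = {}
    fpkms: dict[str, float] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr_raw = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-numeric coordinates") from exc
            if end < start:
                raise GtfParseError(f"line {lineno}: end ({end}) < start ({start})")
            if strand not in _VALID_STRANDS:
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attribute_field(attr_raw, lineno)
            tid = _unquote(attrs["transcript_id"])
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
                extras[tid] = {}
            gene_ids.setdefault(tid, _unquote(attrs.get("gene_id", '""')))
            sources.setdefault(tid, source)
            for key, value in attrs.items():
                if key in _CORE_ATTRS:
                    continue
                extras[tid].setdefault(key, value)
            if "FPKM" in attrs and "FPKM" in attribute_names and tid not in fpkms:
                try:
                    fpkms[tid] = float(_unquote(attrs["FPKM"]))
                except ValueError as exc:
                    raise GtfParseError(f"line {lineno}: unparsable FPKM value") from exc
            if feature != "exon":
                continue
            interval = GenomicInterval(chrom, start, end, strand)
            if interval in exons[tid]:
                raise GtfParseError(
                    f"line {lineno}: duplicate exon {start}-{end} for transcript {tid}"
                )
            exons[tid].append(interval)

    transcripts = []
    for tid in order:
        if not exons[tid]:
            # transcript feature without exon lines: skip structure-less records
            continue
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_ids[tid],
                    exons=tuple(exons[tid]),
                    fpkm=fpkms.get(tid),
                    source_label=sources[tid],
                    attributes=extras[tid],
                )
            )
        except ValueError as exc:
            raise GtfParseError(str(exc)) from exc
    return transcripts


def _format_attributes(t: TranscriptModel) -> str:
    parts = [f'transcript_id "{t.transcript_id}";', f'gene_id "{t.gene_id}";']
    if t.fpkm is not None:
        parts.append(f'FPKM "{t.fpkm}";')
    for key, value in t.attributes.items():
        parts.append(f"{key} {value};")
    return " ".join(parts)


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as Cufflinks-style GTF (transcript + exon features).

    ``read_gtf(write_gtf(X))`` reproduces structures, FPKM and extra
    attributes exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = _format_attributes(t)
            fh.write(
                f"{t.chrom}\t{t.source_label}\ttranscript\t{t.start}\t{t.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{t.source_label}\texon\t{e.start}\t{e.end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
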