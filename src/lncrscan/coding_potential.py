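"""Coding-potential filters driven by external-tool evidence.

Steps 4 and 5 of the scan remove candidates with protein-coding signal:

* PhyloCSF — a phylogenetic codon-substitution-frequency score in
  decibans; positive values indicate coding-like evolution.  Candidates
  are retained when the score is strictly negative, or when the test could
  not run because the called ORF was shorter than 25 aa.  A tool failure
  for any other reason is missing evidence, not evidence of
  non-coding-ness, and drops the transcript by default.
* Pfam — HMMER3 per-domain table ("domtblout") hits against protein
  domain families; any hit with independent (per-domain) E-value at or
  below the cutoff counts as a significant domain and excludes the
  transcript.

Neither tool is run here; their output files are parsed and applied.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .transcript_model import TranscriptModel

PhyloCsfStatus = Literal["scored", "orf_too_short", "failed"]

_ORF_TOO_SHORT_RE = re.compile(r"orf[^a-z]*(too[ _]short|<\s*25)", re.IGNORECASE)


@dataclass(frozen=True)
class PhyloCsfRecord:
    transcript_id: str
    score: float | None
    status: PhyloCsfStatus

    def __post_init__(self) -> None:
        if (self.status == "scored") != (self.score is not None):
            raise ValueError("score must be present iff status is 'scored'")


@dataclass(frozen=True)
class PfamHit:
    transcript_id: str
    domain_accession: str
    domain_name: str
    independent_evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.independent_evalue <= 0:
            raise ValueError("E-value must be > 0")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_phylocsf(path: str | Path) -> dict[str, PhyloCsfRecord]:
    """Read a per-transcript PhyloCSF score table.

    Tab-separated: transcript id, then either a numeric score (decibans)
    or a textual failure message.  Messages mentioning a too-short ORF map
    to status ``orf_too_short``; any other message to ``failed``.
    """
    records: dict[str, PhyloCsfRecord] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 tab-separated columns")
            tid, payload = fields[0].strip(), fields[1].strip()
            if tid in records:
                raise ValueError(f"line {lineno}: duplicate transcript id {tid!r}")
            try:
                score = float(payload)
                records[tid] = PhyloCsfRecord(tid, score, "scored")
            except ValueError:
                status: PhyloCsfStatus = (
                    "orf_too_short" if _ORF_TOO_SHORT_RE.search(payload) else "failed"
                )
                records[tid] = PhyloCsfRecord(tid, None, status)
    return records


def phylocsf_filter(
    transcripts: Iterable[TranscriptModel],
    records: dict[str, PhyloCsfRecord],
    score_cutoff: float = 0.0,
    keep_missing: bool = False,
) -> list[TranscriptModel]:
    """Pipeline step 4: keep candidates with PhyloCSF score strictly below
    *score_cutoff*, or whose test failed because the ORF was < 25 aa.

    Transcripts absent from *records* (or with status ``failed``) are
    dropped unless *keep_missing* is set.
    """
    retained = []
    for t in transcripts:
        rec = records.get(t.transcript_id)
        if rec is None or rec.status == "failed":
            if keep_missing:
                retained.append(t)
            continue
        if rec.status == "orf_too_short":
            retained.append(t)
        elif rec.score is not None and rec.score < score_cutoff:
            retained.append(t)
    return retained


def read_domtblout(path: str | Path) -> list[PfamHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    Whitespace-delimited, 23+ columns, '#' comment lines skipped.  The
    query name column holds the transcript id; the i-Evalue column the
    independent per-domain E-value.
    """
    hits: list[PfamHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ValueError(
                    f"line {lineno}: expected >= 23 whitespace-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    PfamHit(
                        transcript_id=fields[3],
                        domain_accession=fields[1],
                        domain_name=fields[0],
                        independent_evalue=float(fields[12]),
                        bit_score=float(fields[13]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def pfam_filter(
    transcripts: Iterable[TranscriptModel],
    hits: Iterable[PfamHit],
    evalue_cutoff: float = 1e-3,
) -> list[TranscriptModel]:
    """Pipeline step 5: drop candidates with any significant domain hit
    (independent E-value <= cutoff); transcripts without hits are kept."""
    if evalue_cutoff <= 0:
        raise ValueError("E-value cutoff must be > 0")
    flagged = {
        h.transcript_id for h in hits if h.independent_evalue <= evalue_cutoff
    }
    return [t for t in transcripts if t.transcript_id not in flagged]
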