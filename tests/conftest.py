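"""Shared fixtures: a session-scoped synthetic dataset and random
classification scenarios with all eight class codes reachable."""

from __future__ import annotations

import numpy as np
import pytest

from lncrscan.fixtures import FixtureSpec, generate_fixture
from lncrscan.transcript_model import GenomicInterval, TranscriptModel


def _exons(chrom, strand, coords):
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in coords)


def make_transcript(tid, chrom, strand, coords, gene=None, fpkm=None):
    return TranscriptModel(tid, gene or f"g_{tid}", _exons(chrom, strand, coords), fpkm=fpkm)


def random_multi_exon(rng, chrom, strand, start, n_exons=None, tid="t"):
    n = n_exons or int(rng.integers(2, 6))
    coords = []
    cur = start
    for k in range(n):
        end = cur + int(rng.integers(50, 301))
        coords.append((cur, end))
        cur = end + 1 + int(rng.integers(100, 1001))
    return make_transcript(tid, chrom, strand, coords)


def random_classification_scenario(rng, n_refs=120, n_queries=400):
    """Random reference genes plus queries derived by structured
    perturbations, reaching every class code including 's'."""
    chroms = ("chr1", "chr2")
    refs = []
    for i in range(n_refs):
        chrom = chroms[i % 2]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, 400_000))
        refs.append(random_multi_exon(rng, chrom, strand, start, tid=f"ref{i:04d}"))
        # occasionally nest a gene inside the previous gene's first intron
        if rng.random() < 0.15 and refs[-1].exon_count >= 2:
            outer = refs[-1]
            intron = (outer.exons[0].end + 1, outer.exons[1].start - 1)
            if intron[1] - intron[0] > 400:
                inner_strand = "+" if rng.random() < 0.5 else "-"
                a0 = intron[0] + 20
                refs.append(
                    make_transcript(
                        f"ref{i:04d}n", chrom, inner_strand,
                        [(a0, a0 + 80), (a0 + 200, a0 + 280)],
                    )
                )
    modes = ["copy", "sub", "junction", "overlap", "intron", "anti",
             "anti_intron", "intergenic", "random", "single", "nostrand"]
    queries = []
    for i in range(n_queries):
        mode = modes[i % len(modes)]
        r = refs[int(rng.integers(0, len(refs)))]
        tid = f"q{i:04d}"
        flip = {"+": "-", "-": "+"}
        try:
            if mode == "copy":
                coords = [(e.start, e.end) for e in r.exons]
                coords[0] = (max(1, coords[0][0] - int(rng.integers(0, 30))), coords[0][1])
                coords[-1] = (coords[-1][0], coords[-1][1] + int(rng.integers(0, 30)))
                q = make_transcript(tid, r.chrom, r.strand, coords)
            elif mode == "sub" and r.exon_count >= 3:
                coords = [(e.start, e.end) for e in r.exons[1:3]]
                coords[0] = (coords[0][0] + 10, coords[0][1])
                coords[-1] = (coords[-1][0], coords[-1][1] - 10)
                q = make_transcript(tid, r.chrom, r.strand, coords)
            elif mode == "junction":
                e_last, e_prev = r.exons[-1], r.exons[-2]
                a = (max(1, e_prev.end - int(rng.integers(30, 80))), e_prev.end)
                b = (e_last.start, r.end + 60)
                q = make_transcript(tid, r.chrom, r.strand, [a, b])
            elif mode in ("overlap", "anti"):
                e0, e1 = r.exons[0], r.exons[1]
                gap = e1.start - e0.end
                a = (max(1, e0.end - int(rng.integers(20, 60))),
                     e0.end + min(40, max(2, gap // 4)))
                b = (e1.start - min(40, max(2, gap // 4)),
                     e1.start + int(rng.integers(20, 49)))
                strand = r.strand if mode == "overlap" else flip[r.strand]
                q = make_transcript(tid, r.chrom, strand, [a, b])
            elif mode in ("intron", "anti_intron"):
                intron = (r.exons[0].end + 1, r.exons[1].start - 1)
                if intron[1] - intron[0] < 320:
                    raise ValueError("intron too small")
                a0 = intron[0] + 10
                strand = r.strand if mode == "intron" else flip[r.strand]
                q = make_transcript(
                    tid, r.chrom, strand, [(a0, a0 + 60), (a0 + 160, a0 + 240)]
                )
            elif mode == "intergenic":
                start = int(rng.integers(600_000, 900_000))
                q = random_multi_exon(rng, r.chrom, r.strand, start, tid=tid)
            elif mode == "single":
                e0 = r.exons[0]
                q = make_transcript(tid, r.chrom, r.strand,
                                    [(e0.start + 5, max(e0.start + 6, e0.end - 5))])
            elif mode == "nostrand":
                e0, e1 = r.exons[0], r.exons[1]
                q = make_transcript(tid, r.chrom, ".",
                                    [(e0.start, e0.end), (e1.start, e1.end)])
            else:
                start = int(rng.integers(1, 500_000))
                q = random_multi_exon(rng, r.chrom,
                                      "+" if rng.random() < 0.5 else "-",
                                      start, tid=tid)
        except ValueError:
            start = int(rng.integers(1, 500_000))
            q = random_multi_exon(rng, r.chrom,
                                  "+" if rng.random() < 0.5 else "-", start, tid=tid)
        queries.append(q)
    return refs, queries


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default planted dataset, generated once per test session."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=42), out)


@pytest.fixture(scope="session")
def pipeline_result(default_fixture):
    from lncrscan.pipeline import PipelineConfig, run_pipeline

    m = default_fixture
    return run_pipeline(
        PipelineConfig(),
        m.files["query"],
        [m.files["reference_a"], m.files["reference_b"]],
        m.files["genome"],
        m.files["phylocsf"],
        m.files["domtbl"],
    )
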