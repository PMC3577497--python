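"""Self-contained synthetic datasets with planted ground truth.

Generates everything the pipeline consumes — genome FASTA, two reference
annotation GTFs (with planted structural duplicates to exercise merging),
an assembled-transcript GTF with FPKM attributes, a PhyloCSF score table
and a HMMER domtblout file — plus a truth table recording each
transcript's intended class code and final label.  Every plant is
self-verified after generation: class codes are re-derived with the
classifier and planted ORF lengths re-measured from the written genome,
so the fixture is a trustworthy oracle for end-to-end tests.

Planted populations mirror the study conditions: complete ('=') and
partial ('c') assemblies carry log-normal FPKM with natural-scale means
near 29.67 and 4.86 (the observed complete/partial contrast); novel
candidates span the five candidate class codes; mRNA-like decoys carry a
long ORF, a positive PhyloCSF score, or a significant Pfam hit; low-FPKM
artifacts sit well below the derived expression threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import expression_filter
from .annotation_compare import classify_transcript, merge_annotations
from .orf_sequence import longest_orf, spliced_sequence
from .transcript_model import GenomicInterval, TranscriptModel, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes and distributions of the planted populations.

    Defaults give >= 200 assembled transcripts across every plant class.
    Identical spec + seed reproduce byte-identical files.
    """

    seed: int = 0
    n_chromosomes: int = 2
    locus_stride: int = 6000
    n_complete: int = 60
    n_partial: int = 60
    n_mrna_like: int = 30
    n_lncrna_per_code: Mapping[str, int] = field(
        default_factory=lambda: {"i": 4, "j": 4, "o": 4, "u": 4, "x": 4}
    )
    n_low_fpkm: int = 30
    complete_fpkm_mean: float = 29.67
    partial_fpkm_mean: float = 4.86
    fpkm_sigma: float = 1.0

    def total_queries(self) -> int:
        return (
            self.n_complete
            + self.n_partial
            + self.n_mrna_like
            + sum(self.n_lncrna_per_code.values())
            + self.n_low_fpkm
        )


@dataclass
class FixtureManifest:
    files: dict[str, str]
    counts: dict[str, int]
    fpkm_threshold: float | None
    truth: pd.DataFrame


# --- sequence planting -------------------------------------------------------


def _random_bases(n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return ""
    return rng.choice(_BASES, size=n).tobytes().decode()


def _strip_atg(s: str) -> str:
    # removing the T cannot create a new ATG (no inserted G/T adjacency)
    while "ATG" in s:
        s = s.replace("ATG", "ACG")
    return s


def plant_orf(
    sequence_length: int, orf_nt_length: int, seed: int | np.random.Generator
) -> str:
    """Random sequence whose longest ATG-anchored ORF is exactly the request.

    ``orf_nt_length`` must be divisible by 3 and leave room for a stop
    codon; 0 requests a sequence with no ATG-anchored ORF at all.  The
    result is self-verified with :func:`longest_orf` before being
    returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if orf_nt_length % 3 != 0 or orf_nt_length < 0:
        raise ValueError("ORF length must be a non-negative multiple of 3")
    if orf_nt_length == 0:
        seq = _strip_atg(_random_bases(sequence_length, rng))
    else:
        if orf_nt_length + 3 > sequence_length:
            raise ValueError(
                f"cannot fit a {orf_nt_length} nt ORF plus stop codon in "
                f"{sequence_length} nt"
            )
        bg = _strip_atg(_random_bases(sequence_length - orf_nt_length - 3, rng))
        p = int(rng.integers(0, len(bg) + 1))
        # interior codons over {C,G} contain no A/T, so no start or stop
        # codon can arise inside or across the ORF body in any frame
        interior = "".join(
            rng.choice(np.frombuffer(b"CG", dtype="S1"), size=orf_nt_length - 3)
            .tobytes()
            .decode()
        )
        seq = bg[:p] + "ATG" + interior + "TAA" + bg[p:]
        # seal any ATG arising at a junction with the background
        while True:
            stray = [
                i
                for i in _find_all(seq, "ATG")
                if i != p
            ]
            if not stray:
                break
            chars = list(seq)
            for i in stray:
                chars[i + 2] = "C"
            seq = "".join(chars)
    got = longest_orf(seq).nt_length
    if got != orf_nt_length:
        raise AssertionError(
            f"ORF planting failed: requested {orf_nt_length} nt, measured {got} nt"
        )
    return seq


def _find_all(s: str, pattern: str) -> list[int]:
    out, i = [], s.find(pattern)
    while i != -1:
        out.append(i)
        i = s.find(pattern, i + 1)
    return out


# --- transcript geometry -----------------------------------------------------


def _exons(chrom: str, strand: str, coords: list[tuple[int, int]]) -> tuple:
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in coords)


def _make_ref(
    ref_id: str, chrom: str, origin: int, strand: str, rng: np.random.Generator
) -> TranscriptModel:
    exon_lens = rng.integers(150, 301, size=4)
    intron_lens = rng.integers(700, 901, size=3)
    coords = []
    cur = origin
    for k in range(4):
        coords.append((cur, cur + int(exon_lens[k]) - 1))
        if k < 3:
            cur = coords[-1][1] + 1 + int(intron_lens[k])
    return TranscriptModel(
        ref_id, ref_id.replace("REF", "RGENE"), _exons(chrom, strand, coords)
    )


def _build_query_coords(
    code: str, ref: TranscriptModel | None, origin: int, strand: str,
    rng: np.random.Generator, long_profile: bool,
) -> tuple[list[tuple[int, int]], str]:
    """Exon coordinates (and strand) for a query transcript of class *code*."""
    if code == "=":
        assert ref is not None
        coords = [(e.start, e.end) for e in ref.exons]
        coords[0] = (coords[0][0] - int(rng.integers(1, 41)), coords[0][1])
        coords[-1] = (coords[-1][0], coords[-1][1] + int(rng.integers(1, 41)))
        return coords, ref.strand
    if code == "c":
        assert ref is not None
        e1, e2 = ref.exons[1], ref.exons[2]
        return [
            (e1.start + int(rng.integers(10, 51)), e1.end),
            (e2.start, e2.end - int(rng.integers(10, 51))),
        ], ref.strand
    if code == "i":
        assert ref is not None
        intron_start = ref.exons[0].end + 1
        a0 = intron_start + int(rng.integers(5, 41))
        a1 = a0 + int(rng.integers(110, 171))
        b0 = a1 + 1 + int(rng.integers(60, 121))
        b1 = b0 + int(rng.integers(110, 171))
        assert b1 <= ref.exons[1].start - 6
        return [(a0, a1), (b0, b1)], ref.strand
    if code == "j":
        assert ref is not None
        e0, e1, e2 = ref.exons[0], ref.exons[1], ref.exons[2]
        a_len = int(rng.integers(120, 261))
        a = (e0.end - a_len + 1, e0.end)
        b = (e1.start, e1.end + int(rng.integers(20, 121)))
        c0 = b[1] + 1 + int(rng.integers(60, 121))
        c = (c0, c0 + int(rng.integers(100, 201)))
        assert c[1] <= e2.start - 6
        return [a, b, c], ref.strand
    if code in ("o", "x"):
        assert ref is not None
        e0, e1 = ref.exons[0], ref.exons[1]
        if long_profile:
            back, fwd = int(rng.integers(50, 101)), int(rng.integers(50, 101))
            ext_a, ext_b = int(rng.integers(220, 301)), int(rng.integers(220, 301))
        else:
            back, fwd = int(rng.integers(40, 121)), int(rng.integers(40, 121))
            ext_a, ext_b = int(rng.integers(80, 201)), int(rng.integers(80, 201))
        a = (e0.end - back, e0.end + ext_a)
        b = (e1.start - ext_b, e1.start + fwd)
        out_strand = ref.strand if code == "o" else _flip(ref.strand)
        return [a, b], out_strand
    if code == "u":
        lo, hi = (250, 421) if long_profile else (110, 261)
        a0 = origin + int(rng.integers(0, 101))
        a1 = a0 + int(rng.integers(lo, hi))
        b0 = a1 + 1 + int(rng.integers(80, 201))
        b1 = b0 + int(rng.integers(lo, hi))
        return [(a0, a1), (b0, b1)], strand
    raise ValueError(f"unsupported plant code {code!r}")


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# --- fixture assembly --------------------------------------------------------

_MRNA_STAGES = ("orf", "phylocsf", "pfam")
_MRNA_CODES = ("u", "o", "j")
_ARTIFACT_CODES = ("u", "i")


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write the full fixture into *out_dir* and return its manifest.

    Raises if any plant fails self-verification (class code or ORF length
    not as intended).
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    plants: list[dict] = []
    for i in range(spec.n_complete):
        plants.append({"label": "complete", "code": "="})
    for i in range(spec.n_partial):
        plants.append({"label": "partial", "code": "c"})
    for code in sorted(spec.n_lncrna_per_code):
        for i in range(spec.n_lncrna_per_code[code]):
            plants.append({"label": "novel_lncRNA", "code": code})
    for i in range(spec.n_mrna_like):
        plants.append(
            {
                "label": "mRNA_like",
                "code": _MRNA_CODES[(i // len(_MRNA_STAGES)) % len(_MRNA_CODES)],
                "stage": _MRNA_STAGES[i % len(_MRNA_STAGES)],
            }
        )
    for i in range(spec.n_low_fpkm):
        plants.append(
            {"label": "low_fpkm_artifact", "code": _ARTIFACT_CODES[i % 2]}
        )

    n_loci = max(len(plants), 1)
    chroms = [f"chr{k + 1}" for k in range(spec.n_chromosomes)]
    loci_per_chrom = math.ceil(n_loci / spec.n_chromosomes)
    chrom_length = 500 + spec.locus_stride * loci_per_chrom + 1000

    refs: list[TranscriptModel] = []
    queries: list[TranscriptModel] = []
    for k, plant in enumerate(plants):
        chrom = chroms[k % spec.n_chromosomes]
        origin = (k // spec.n_chromosomes) * spec.locus_stride + 500
        strand = "+" if (k // spec.n_chromosomes) % 2 == 0 else "-"
        code = plant["code"]
        needs_ref = code != "u"
        ref = None
        if needs_ref:
            ref_strand = _flip(strand) if code == "x" else strand
            ref = _make_ref(f"REF_{k:04d}", chrom, origin, ref_strand, rng)
            refs.append(ref)
        long_profile = plant["label"] == "mRNA_like"
        coords, q_strand = _build_query_coords(
            code, ref, origin, strand, rng, long_profile
        )
        t = TranscriptModel(
            transcript_id=f"TCONS_{k:05d}",
            gene_id=f"XLOC_{k:05d}",
            exons=_exons(chrom, q_strand, coords),
        )
        plant["transcript"] = t
        plant["ref"] = ref
        queries.append(t)

    # genome: random background, planted spliced sequences for candidates
    genome_arrays = {
        c: bytearray(
            np.random.default_rng(spec.seed + 1 + j).choice(
                _BASES, size=chrom_length
            ).tobytes()
        )
        for j, c in enumerate(chroms)
    }

    for plant in plants:
        t: TranscriptModel = plant["transcript"]
        label = plant["label"]
        if label in ("complete", "partial"):
            plant["orf_nt"] = None
            continue
        length = sum(e.length for e in t.exons)
        if label == "mRNA_like" and plant["stage"] == "orf":
            choices = [o for o in (300, 330, 360, 399) if o + 3 <= length]
        elif label == "mRNA_like":
            choices = [240]
        else:
            choices = [o for o in (0, 90, 150, 297) if o == 0 or o + 3 <= length]
        orf_nt = int(rng.choice(choices))
        seq = plant_orf(length, orf_nt, rng)
        plant["orf_nt"] = orf_nt
        _write_spliced(genome_arrays[t.chrom], t, seq)

    # FPKM: complete/partial drawn log-normal; candidates anchored to the
    # threshold those two groups induce, so ground-truth retention is exact
    sigma = spec.fpkm_sigma
    mu_c = math.log(spec.complete_fpkm_mean) - sigma**2 / 2
    mu_p = math.log(spec.partial_fpkm_mean) - sigma**2 / 2
    complete_fpkm = rng.lognormal(mu_c, sigma, size=spec.n_complete)
    partial_fpkm = rng.lognormal(mu_p, sigma, size=spec.n_partial)
    t_star: float | None = None
    if spec.n_complete and spec.n_partial:
        roc = expression_filter.build_roc(complete_fpkm, partial_fpkm)
        t_star = expression_filter.optimal_threshold(roc).optimum_threshold
    anchor = t_star if t_star is not None else 1.0

    ci = pi = 0
    for plant in plants:
        label = plant["label"]
        if label == "complete":
            fpkm = float(complete_fpkm[ci]); ci += 1
        elif label == "partial":
            fpkm = float(partial_fpkm[pi]); pi += 1
        elif label == "low_fpkm_artifact":
            fpkm = float(anchor * rng.uniform(0.05, 0.6))
        else:
            fpkm = float(anchor * rng.uniform(1.5, 12.0))
        plant["transcript"] = _with_fpkm(plant["transcript"], fpkm)

    queries = [p["transcript"] for p in plants]

    # duplicate every 5th reference structure (padded ends, new ids) into a
    # second annotation file to exercise merge-by-structure deduplication
    refs_b = []
    for r in refs[::5]:
        coords = [(e.start, e.end) for e in r.exons]
        coords[0] = (max(1, coords[0][0] - 5), coords[0][1])
        coords[-1] = (coords[-1][0], coords[-1][1] + 5)
        refs_b.append(
            TranscriptModel(
                "ALT_" + r.transcript_id,
                "ALT_" + r.gene_id,
                _exons(r.chrom, r.strand, coords),
            )
        )

    # self-verification: re-derive every class code and ORF length
    merged = merge_annotations([refs, refs_b])
    genome_str = {c: bytes(a).decode() for c, a in genome_arrays.items()}
    for plant in plants:
        t = plant["transcript"]
        res = classify_transcript(t, merged)
        if res.code != plant["code"]:
            raise AssertionError(
                f"plant {t.transcript_id}: intended code {plant['code']!r}, "
                f"classified {res.code!r}"
            )
        if plant["orf_nt"] is not None:
            measured = longest_orf(spliced_sequence(t, genome_str)).nt_length
            if measured != plant["orf_nt"]:
                raise AssertionError(
                    f"plant {t.transcript_id}: intended ORF {plant['orf_nt']} nt, "
                    f"measured {measured} nt"
                )

    # write files
    files = {
        "genome": str(out_dir / "genome.fa"),
        "reference_a": str(out_dir / "reference_a.gtf"),
        "reference_b": str(out_dir / "reference_b.gtf"),
        "query": str(out_dir / "assembled.gtf"),
        "phylocsf": str(out_dir / "phylocsf.tsv"),
        "domtbl": str(out_dir / "pfam.domtblout"),
        "truth": str(out_dir / "truth.tsv"),
        "manifest": str(out_dir / "manifest.json"),
    }
    _write_fasta(genome_str, files["genome"])
    write_gtf(refs, files["reference_a"])
    write_gtf(refs_b, files["reference_b"])
    write_gtf(queries, files["query"])
    _write_phylocsf(plants, files["phylocsf"], rng)
    _write_domtbl(plants, files["domtbl"], rng)

    truth = pd.DataFrame(
        {
            "transcript_id": [p["transcript"].transcript_id for p in plants],
            "intended_class_code": [p["code"] for p in plants],
            "intended_final_label": [p["label"] for p in plants],
            "planted_orf_nt": [
                -1 if p["orf_nt"] is None else p["orf_nt"] for p in plants
            ],
            "fpkm": [p["transcript"].fpkm for p in plants],
        }
    )
    truth.to_csv(files["truth"], sep="\t", index=False)

    counts = {
        "queries": len(queries),
        "references": len(refs) + len(refs_b),
        "novel_lncRNA": sum(p["label"] == "novel_lncRNA" for p in plants),
        "mRNA_like": spec.n_mrna_like,
        "low_fpkm_artifact": spec.n_low_fpkm,
        "complete": spec.n_complete,
        "partial": spec.n_partial,
    }
    with open(files["manifest"], "w") as fh:
        json.dump(
            {"files": files, "counts": counts, "fpkm_threshold": t_star},
            fh,
            indent=2,
        )
    return FixtureManifest(
        files=files, counts=counts, fpkm_threshold=t_star, truth=truth
    )


def _with_fpkm(t: TranscriptModel, fpkm: float) -> TranscriptModel:
    return TranscriptModel(
        t.transcript_id, t.gene_id, t.exons, fpkm=fpkm,
        source_label=t.source_label, attributes=dict(t.attributes),
    )


def _write_spliced(arr: bytearray, t: TranscriptModel, seq: str) -> None:
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    pos = 0
    for e in t.exons:
        n = e.length
        arr[e.start - 1 : e.end] = seq[pos : pos + n].encode()
        pos += n


def _write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _write_phylocsf(plants: list[dict], path: str, rng: np.random.Generator) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript_id\tscore_or_status\n")
        for p in plants:
            tid = p["transcript"].transcript_id
            label = p["label"]
            if label == "novel_lncRNA" and p["orf_nt"] is not None and p["orf_nt"] < 75:
                fh.write(f"{tid}\tfailure: ORF too short (< 25 aa)\n")
            elif label == "mRNA_like" and p["stage"] in ("orf", "phylocsf"):
                fh.write(f"{tid}\t{rng.uniform(5.0, 80.0):.4f}\n")
            else:
                fh.write(f"{tid}\t{-rng.uniform(2.0, 60.0):.4f}\n")


def _write_domtbl(plants: list[dict], path: str, rng: np.random.Generator) -> None:
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain --------------\n"
        "# target name        accession   tlen query name           accession"
        "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score"
        "  bias  from    to  from    to  from    to  acc description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        dom_idx = 0
        for p in plants:
            tid = p["transcript"].transcript_id
            label = p["label"]
            if label == "mRNA_like" and p["stage"] in ("orf", "pfam"):
                evalue = 10.0 ** rng.uniform(-30.0, -6.0)
            elif label == "novel_lncRNA" and dom_idx % 3 == 0:
                # weak, insignificant hit: exercises the cutoff
                evalue = float(rng.uniform(0.05, 5.0))
            else:
                dom_idx += 1
                continue
            dom_idx += 1
            score = float(rng.uniform(20.0, 300.0))
            fh.write(
                f"FakeDom{dom_idx:03d}  PF{dom_idx:05d}.1  120 {tid}  -  200 "
                f"{evalue:.2e} {score:.1f} 0.1 1 1 {evalue:.2e} {evalue:.2e} "
                f"{score:.1f} 0.1 1 120 10 130 5 140 0.95 synthetic domain\n"
            )
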