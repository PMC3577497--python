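"""End-to-end novel-lncRNA detection and downstream reporting.

The pipeline takes assembled transcripts (GTF with FPKM attributes), one
or more reference annotations, a genome FASTA, and per-transcript
PhyloCSF / Pfam evidence files, and runs:

  multi-exon filter -> class-code classification against the merged
  reference -> high-quality selection ('=' plus novel transcripts above
  the ROC-optimal FPKM threshold) -> step 1 candidate categories
  {i,j,o,u,x} -> step 2 exonic length > 200 nt -> step 3 longest putative
  ORF < 300 nt -> step 4 PhyloCSF -> step 5 Pfam.

Survivors are the predicted novel lncRNAs.  Per-step retention accounting
telescopes: each step's input count equals the previous step's retained
count.  Downstream helpers cover the reporting layer: log2 fold changes,
Benjamini-Hochberg q-values, Welch two-sample feature comparisons, and
structural overlap against an external lncRNA catalogue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from . import annotation_compare, coding_potential, expression_filter, orf_sequence
from .annotation_compare import CANDIDATE_CODES, ClassificationResult
from .coding_potential import PfamHit, PhyloCsfRecord
from .expression_filter import ThresholdResult
from .orf_sequence import OrfResult
from .transcript_model import (
    AnnotationSet,
    TranscriptModel,
    exonic_length,
    read_gtf,
    write_gtf,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the scan; defaults are the published ones."""

    candidate_codes: frozenset[str] = CANDIDATE_CODES
    min_length_nt: int = 200          # exonic length must exceed this (strict)
    max_orf_nt: int = 300             # longest putative ORF must stay below (strict)
    phylocsf_cutoff: float = 0.0      # retain when score < cutoff (strict)
    phylocsf_min_aa: int = 25         # ORFs below this abort PhyloCSF -> retained
    pfam_evalue: float = 1e-3         # independent E-value significance cutoff
    fpkm_cutoff: float | Literal["auto"] = "auto"
    multi_exon_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length_nt <= 0 or self.max_orf_nt <= 0 or self.pfam_evalue <= 0:
            raise ValueError("thresholds must be positive")
        if not self.candidate_codes <= frozenset("ijouxs"):
            raise ValueError("candidate codes must come from {i,j,o,u,x,s}")


@dataclass(frozen=True)
class StepRecord:
    name: str
    input_count: int
    retained_count: int

    @property
    def filtered_count(self) -> int:
        return self.input_count - self.retained_count

    @property
    def retained_fraction(self) -> float:
        return self.retained_count / self.input_count if self.input_count else 0.0


@dataclass
class PipelineResult:
    novel: list[TranscriptModel]
    classifications: dict[str, ClassificationResult]
    accounting: list[StepRecord]
    category_table: pd.DataFrame
    threshold: ThresholdResult | None
    fpkm_cutoff: float
    orf_results: dict[str, OrfResult]

    def accounting_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [r.name for r in self.accounting],
                "input": [r.input_count for r in self.accounting],
                "retained": [r.retained_count for r in self.accounting],
                "filtered": [r.filtered_count for r in self.accounting],
                "retained_fraction": [r.retained_fraction for r in self.accounting],
            }
        )


def run_pipeline(
    config: PipelineConfig,
    query_gtf: str | Path,
    reference_gtfs: Sequence[str | Path],
    genome_fasta: str | Path | Mapping[str, object],
    phylocsf_file: str | Path | None,
    domtbl_file: str | Path | None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full scan; see the module docstring for the stage order.

    ``phylocsf_file`` / ``domtbl_file`` may be ``None`` to skip those
    steps (useful before the external tools have been run).  When
    ``out_dir`` is given, ``novel_lncrna.gtf``, ``accounting.tsv`` and
    ``categories.tsv`` are written there.
    """
    query = read_gtf(query_gtf)
    refs = annotation_compare.merge_annotations(
        [read_gtf(p) for p in reference_gtfs]
    )
    if isinstance(genome_fasta, (str, Path)):
        genome: Mapping[str, object] = Fasta(str(genome_fasta))
    else:
        genome = genome_fasta

    accounting: list[StepRecord] = []
    current = query
    if config.multi_exon_only:
        retained = [t for t in current if t.exon_count >= 2]
        accounting.append(StepRecord("multi_exon", len(current), len(retained)))
        current = retained

    classified = annotation_compare.classify(current, refs)
    classifications = {res.transcript_id: res for _, res in classified}

    threshold_result: ThresholdResult | None = None
    if config.fpkm_cutoff == "auto":
        pos = [t.fpkm for t, r in classified if r.code == "=" and t.fpkm is not None]
        neg = [t.fpkm for t, r in classified if r.code == "c" and t.fpkm is not None]
        if not pos or not neg:
            raise ValueError(
                "cannot derive FPKM threshold: need both '=' and 'c' transcripts "
                "with FPKM values"
            )
        roc = expression_filter.build_roc(pos, neg)
        threshold_result = expression_filter.optimal_threshold(roc)
        cutoff = threshold_result.optimum_threshold
    else:
        cutoff = float(config.fpkm_cutoff)

    hq = expression_filter.select_high_quality(classified, cutoff)
    accounting.append(StepRecord("high_quality", len(classified), len(hq)))

    candidates = annotation_compare.extract_category(hq, config.candidate_codes)
    accounting.append(StepRecord("extract_category", len(hq), len(candidates)))

    step2 = orf_sequence.extract_length(candidates, config.min_length_nt)
    accounting.append(StepRecord("extract_length", len(candidates), len(step2)))

    step3, orf_results = orf_sequence.extract_orf(step2, genome, config.max_orf_nt)
    accounting.append(StepRecord("extract_ORF", len(step2), len(step3)))

    current = step3
    if phylocsf_file is not None:
        records = coding_potential.read_phylocsf(phylocsf_file)
        step4 = coding_potential.phylocsf_filter(
            current, records, config.phylocsf_cutoff
        )
        accounting.append(StepRecord("extract_PhyloCSF", len(current), len(step4)))
        current = step4
    if domtbl_file is not None:
        hits = coding_potential.read_domtblout(domtbl_file)
        step5 = coding_potential.pfam_filter(current, hits, config.pfam_evalue)
        accounting.append(StepRecord("extract_Pfam", len(current), len(step5)))
        current = step5

    novel = [
        replace(
            t,
            attributes={
                **t.attributes,
                "class_code": f'"{classifications[t.transcript_id].code}"',
            },
        )
        for t in current
    ]
    category_table = annotation_compare.categorize_summary(
        [classifications[t.transcript_id] for t in novel]
    )

    result = PipelineResult(
        novel=novel,
        classifications=classifications,
        accounting=accounting,
        category_table=category_table,
        threshold=threshold_result,
        fpkm_cutoff=cutoff,
        orf_results=orf_results,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gtf(novel, out_dir / "novel_lncrna.gtf")
        result.accounting_frame().to_csv(
            out_dir / "accounting.tsv", sep="\t", index=False
        )
        category_table.to_csv(out_dir / "categories.tsv", sep="\t", index=False)
    return result


# --- downstream statistics ---------------------------------------------------


def fold_change(fpkm_a: float, fpkm_b: float, pseudocount: float = 1e-6) -> float:
    """log2((a + eps) / (b + eps)); the pseudocount keeps zero FPKM finite."""
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValueError("FPKM values must be non-negative")
    return math.log2((fpkm_a + pseudocount) / (fpkm_b + pseudocount))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1; ties and unsorted input are handled by rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class DiffExpressionRecord:
    transcript_id: str
    fpkm_a: float
    fpkm_b: float
    log2_fold_change: float
    p_value: float
    q_value: float
    significant: bool


def differential_expression(
    table: pd.DataFrame,
    q_cutoff: float = 0.05,
    pseudocount: float = 1e-6,
) -> list[DiffExpressionRecord]:
    """Fold-change / BH layer over externally produced per-transcript tests.

    *table* needs columns transcript_id, fpkm_a, fpkm_b, p_value.  A
    record is significant when its BH q-value is strictly below
    *q_cutoff*.
    """
    q = bh_adjust(table["p_value"].to_numpy())
    records = []
    for (_, row), q_val in zip(table.iterrows(), q):
        records.append(
            DiffExpressionRecord(
                transcript_id=str(row["transcript_id"]),
                fpkm_a=float(row["fpkm_a"]),
                fpkm_b=float(row["fpkm_b"]),
                log2_fold_change=fold_change(
                    float(row["fpkm_a"]), float(row["fpkm_b"]), pseudocount
                ),
                p_value=float(row["p_value"]),
                q_value=float(q_val),
                significant=bool(q_val < q_cutoff),
            )
        )
    return records


_FEATURES = ("length", "exon_count", "orf_length", "fpkm")


def _feature_values(
    transcripts: Sequence[TranscriptModel],
    feature: str,
    orf_results: Mapping[str, OrfResult] | None,
) -> np.ndarray:
    if feature == "length":
        return np.array([exonic_length(t) for t in transcripts], dtype=float)
    if feature == "exon_count":
        return np.array([t.exon_count for t in transcripts], dtype=float)
    if feature == "fpkm":
        vals = []
        for t in transcripts:
            if t.fpkm is None:
                raise ValueError(f"transcript {t.transcript_id} has no FPKM value")
            vals.append(t.fpkm)
        return np.array(vals, dtype=float)
    if feature == "orf_length":
        if orf_results is None:
            raise ValueError("orf_length comparison requires ORF results")
        return np.array(
            [orf_results[t.transcript_id].nt_length for t in transcripts], dtype=float
        )
    raise ValueError(f"unknown feature {feature!r}; choose from {_FEATURES}")


def compare_features(
    set_a: Sequence[TranscriptModel],
    set_b: Sequence[TranscriptModel],
    feature: str,
    orf_a: Mapping[str, OrfResult] | None = None,
    orf_b: Mapping[str, OrfResult] | None = None,
) -> tuple[float, float, float, float]:
    """Welch unequal-variance two-sample comparison of a transcript feature.

    Returns (mean_a, mean_b, t_statistic, two_sided_p).  Degrees of
    freedom follow Welch-Satterthwaite.
    """
    a = _feature_values(set_a, feature, orf_a)
    b = _feature_values(set_b, feature, orf_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return float(np.mean(a)), float(np.mean(b)), float(t_stat), float(p_value)


def structure_overlap(
    set_a: Sequence[TranscriptModel], set_b: Sequence[TranscriptModel]
) -> dict[str, int]:
    """Partition *set_a* by structural agreement with *set_b*.

    exact: identical (chrom, strand, intron chain) — exact exon interval
    for single-exon transcripts; partial: >= 1 bp exonic overlap
    (strand-agnostic) without an exact match; no_overlap: the rest.
    """
    b_keys = {annotation_compare.structure_key(t) for t in set_b}
    b_index = AnnotationSet(set_b)
    exact = partial = none = 0
    for t in set_a:
        if annotation_compare.structure_key(t) in b_keys:
            exact += 1
            continue
        overlapping = b_index.overlapping(t.chrom, t.start, t.end)
        if any(annotation_compare._exonic_overlap(t, other) for other in overlapping):
            partial += 1
        else:
            none += 1
    return {
        "exact_match_count": exact,
        "partial_overlap_count": partial,
        "no_overlap_count": none,
    }
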