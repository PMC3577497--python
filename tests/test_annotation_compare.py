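"""Class-code assignment: ladder semantics, merge dedup, summaries."""

import numpy as np
import pytest

from lncrscan.annotation_compare import (
    CANDIDATE_CODES,
    ClassificationResult,
    categorize_summary,
    classify_transcript,
    extract_category,
    merge_annotations,
)
from lncrscan.transcript_model import AnnotationSet

from conftest import make_transcript, random_classification_scenario
from oracles import NaiveTranscript, brute_force_classify


def _ref_set(*transcripts):
    return AnnotationSet(transcripts)


class TestLadderSemantics:
    """Hand-constructed cases for each class code."""

    ref = staticmethod(
        lambda strand="+": make_transcript(
            "r1", "chr1", strand, [(1000, 1200), (2000, 2200), (3000, 3200)], gene="rg1"
        )
    )

    def test_complete_intron_chain_match_allows_padded_ends(self):
        t = make_transcript("t", "chr1", "+", [(950, 1200), (2000, 2200), (3000, 3350)])
        res = classify_transcript(t, _ref_set(self.ref()))
        assert res.code == "=" and res.ref_transcript_id == "r1"

    def test_contained_subchain_within_span(self):
        t = make_transcript("t", "chr1", "+", [(1050, 1200), (2000, 2150)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "c"

    def test_shared_junction_with_different_chain(self):
        # shares the first junction, second exon runs past the reference end
        t = make_transcript("t", "chr1", "+", [(1100, 1200), (2000, 3500)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "j"

    def test_generic_exonic_overlap(self):
        t = make_transcript("t", "chr1", "+", [(1100, 1300), (1500, 1600)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "o"

    def test_intronic_containment_same_strand(self):
        t = make_transcript("t", "chr1", "+", [(1300, 1400), (1600, 1700)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "i"

    def test_opposite_strand_exonic_overlap(self):
        t = make_transcript("t", "chr1", "-", [(1100, 1300), (1500, 1600)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "x"

    def test_opposite_strand_intron_overlap_without_exon_overlap(self):
        t = make_transcript("t", "chr1", "-", [(1300, 1400), (1600, 1700)])
        assert classify_transcript(t, _ref_set(self.ref())).code == "s"

    def test_intergenic_is_u_with_no_reference_ids(self):
        t = make_transcript("t", "chr1", "+", [(50_000, 50_100), (51_000, 51_100)])
        res = classify_transcript(t, _ref_set(self.ref()))
        assert res.code == "u"
        assert res.ref_transcript_id is None and res.ref_gene_id is None

    def test_empty_reference_codes_everything_u(self):
        t = make_transcript("t", "chr1", "+", [(1, 100), (201, 300)])
        assert classify_transcript(t, AnnotationSet([])).code == "u"

    def test_unknown_strand_ineligible_for_chain_codes(self):
        t = make_transcript("t", "chr1", ".", [(1000, 1200), (2000, 2200), (3000, 3200)])
        res = classify_transcript(t, _ref_set(self.ref()))
        assert res.code == "c"  # chain match degrades to containment
        assert res.strand_unknown

    def test_equality_code_is_structurally_symmetric(self):
        t = make_transcript("t", "chr1", "+", [(900, 1200), (2000, 2200), (3000, 3400)])
        r = self.ref()
        assert classify_transcript(t, _ref_set(r)).code == "="
        assert classify_transcript(r, _ref_set(t)).code == "="


class TestOracleEquivalence:
    def test_indexed_classifier_matches_brute_force(self):
        """Indexed ladder equals the naive all-pairs per-base classifier."""
        rng = np.random.default_rng(19)
        refs, queries = random_classification_scenario(rng, n_refs=80, n_queries=250)
        ref_set = AnnotationSet(refs)
        naive_refs = [NaiveTranscript(r) for r in refs]
        seen = set()
        for q in queries:
            res = classify_transcript(q, ref_set)
            code, ref_id = brute_force_classify(NaiveTranscript(q), naive_refs)
            assert (res.code, res.ref_transcript_id) == (code, ref_id), q.transcript_id
            seen.add(res.code)
        assert seen >= {"=", "c", "j", "o", "i", "x", "s", "u"}

    def test_u_transcripts_never_share_exonic_sequence_with_reference(self):
        """'u' transcripts have no exon-level overlap with any reference;
        rare boundary-straddling cases may still touch a reference span
        with purely intronic placement, which the ladder leaves unknown."""
        rng = np.random.default_rng(23)
        refs, queries = random_classification_scenario(rng, n_refs=60, n_queries=150)
        ref_set = AnnotationSet(refs)
        found_u = 0
        for q in queries:
            if classify_transcript(q, ref_set).code != "u":
                continue
            found_u += 1
            nq = NaiveTranscript(q)
            for r in ref_set.overlapping(q.chrom, q.start, q.end):
                assert not nq.exon_positions & NaiveTranscript(r).exon_positions
        assert found_u > 0


class TestMerge:
    def test_duplicate_chain_with_padded_ends_collapses(self):
        a = make_transcript("a", "chr1", "+", [(100, 200), (300, 400)], gene="ga")
        b = make_transcript("b", "chr1", "+", [(90, 200), (300, 420)], gene="gb")
        merged = merge_annotations([[a], [b]])
        assert len(merged) == 1
        assert next(iter(merged)).transcript_id == "a"  # first-seen ids kept

    def test_disjoint_sets_concatenate(self):
        a = [make_transcript(f"a{i}", "chr1", "+", [(i * 1000 + 1, i * 1000 + 100),
                                                    (i * 1000 + 300, i * 1000 + 400)])
             for i in range(3)]
        b = [make_transcript(f"b{i}", "chr2", "+", [(i * 1000 + 1, i * 1000 + 100),
                                                    (i * 1000 + 300, i * 1000 + 400)])
             for i in range(4)]
        assert len(merge_annotations([a, b])) == 7

    def test_planted_duplicates_match_pairwise_dedup_oracle(self):
        rng = np.random.default_rng(5)
        from conftest import random_multi_exon

        base = [random_multi_exon(rng, "chr1", "+", int(rng.integers(1, 500_000)),
                                  tid=f"t{i}") for i in range(40)]
        dups = []
        for i, t in enumerate(base[::3]):
            coords = [(e.start, e.end) for e in t.exons]
            coords[0] = (max(1, coords[0][0] - 7), coords[0][1])
            dups.append(make_transcript(f"d{i}", t.chrom, t.strand, coords))
        merged = merge_annotations([base, dups])

        def key(t):
            return (t.chrom, t.strand,
                    tuple((a.end + 1, b.start - 1)
                          for a, b in zip(t.exons, t.exons[1:])))

        expected = len({key(t) for t in base + dups})
        assert len(merged) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_annotations([])


class TestCategoryExtraction:
    def _mixture(self):
        pairs = []
        codes = ["="] * 3 + ["c"] + ["j"] * 2 + ["u"]
        for i, code in enumerate(codes):
            t = make_transcript(f"t{i}", "chr1", "+", [(1, 100), (201, 300)])
            ref = None if code == "u" else "r"
            pairs.append(
                (t, ClassificationResult(f"t{i}", code, ref, ref and "g"))
            )
        return pairs

    def test_default_candidate_codes(self):
        got = extract_category(self._mixture())
        assert len(got) == 3  # j:2 + u:1

    def test_empty_wanted_set(self):
        assert extract_category(self._mixture(), set()) == []

    def test_summary_counts_and_percentages(self):
        # the published per-code composition of the 308 novel lncRNAs
        codes = ["j"] * 180 + ["i"] * 26 + ["o"] * 44 + ["u"] * 52 + ["x"] * 6
        results = [
            ClassificationResult(f"t{i}", c, None if c == "u" else "r",
                                 None if c == "u" else "g")
            for i, c in enumerate(codes)
        ]
        table = categorize_summary(results)
        by_code = dict(zip(table.code, table.percentage))
        assert table["count"].sum() == 308
        assert by_code["j"] == pytest.approx(58.44, abs=0.005)
        assert by_code["i"] == pytest.approx(8.44, abs=0.005)
        assert by_code["o"] == pytest.approx(14.29, abs=0.005)
        assert by_code["u"] == pytest.approx(16.88, abs=0.005)
        assert by_code["x"] == pytest.approx(1.95, abs=0.005)
        assert table.percentage.sum() == pytest.approx(100.0)

    def test_single_transcript_is_100_percent(self):
        table = categorize_summary([ClassificationResult("t", "u")])
        assert list(table.percentage) == [100.0]
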