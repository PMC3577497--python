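"""Spliced-sequence extraction, longest putative ORF and translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncrscan.fixtures import plant_orf
from lncrscan.orf_sequence import (
    SplicedSequence,
    extract_length,
    extract_orf,
    longest_orf,
    spliced_sequence,
    translate,
)

from conftest import make_transcript
from oracles import exhaustive_orf

_dna = st.text(alphabet="ACGTN", min_size=0, max_size=120)


class TestSplicedSequence:
    genome = {"chr1": "NNNNATGCCCGGGTAANNNN"}  # 1-based: ATG at 5-7, TAA at 14-16

    def test_forward_strand_concatenation(self):
        t = make_transcript("t", "chr1", "+", [(5, 7), (14, 16)])
        assert spliced_sequence(t, self.genome).bases == "ATGTAA"

    def test_reverse_strand_is_reverse_complement(self):
        t = make_transcript("t", "chr1", "-", [(5, 7), (14, 16)])
        assert spliced_sequence(t, self.genome).bases == "TTACAT"

    def test_missing_chromosome(self):
        t = make_transcript("t", "chrX", "+", [(1, 3)])
        with pytest.raises(ValueError, match="chrX"):
            spliced_sequence(t, self.genome)

    def test_exon_beyond_contig_end(self):
        t = make_transcript("t", "chr1", "+", [(15, 30)])
        with pytest.raises(ValueError, match="beyond"):
            spliced_sequence(t, self.genome)

    def test_unknown_strand_rejected(self):
        t = make_transcript("t", "chr1", ".", [(5, 7)])
        with pytest.raises(ValueError, match="strand"):
            spliced_sequence(t, self.genome)

    def test_per_base_oracle_extraction(self):
        rng = np.random.default_rng(31)
        contig = "".join(rng.choice(list("ACGT"), size=5000))
        genome = {"c": contig}
        for i in range(30):
            a = int(rng.integers(1, 4000))
            coords = [(a, a + 50), (a + 120, a + 200), (a + 300, a + 330)]
            strand = "+-"[i % 2]
            t = make_transcript("t", "c", strand, coords)
            per_base = "".join(contig[p - 1] for s, e in coords for p in range(s, e + 1))
            if strand == "-":
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                per_base = "".join(comp[b] for b in reversed(per_base))
            assert spliced_sequence(t, genome).bases == per_base


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,nt,stop",
        [
            ("ATGAAATAG", 6, True),
            ("ATG", 3, False),            # stop-less ORF runs to the end
            ("CCCCCC", 0, False),         # no start codon
            ("ATGNNNTAA", 6, True),       # N codon is not a stop
            ("NTGAAATAG", 0, False),      # N codon is not a start
        ],
    )
    def test_examples(self, seq, nt, stop):
        orf = longest_orf(seq)
        assert orf.nt_length == nt
        if nt:
            assert orf.has_stop is stop
            assert orf.aa_length == nt // 3

    def test_matches_exhaustive_enumeration_on_random_sequences(self):
        """500 seeded random sequences, 50-2,000 nt, vs span enumeration."""
        rng = np.random.default_rng(37)
        for _ in range(500):
            n = int(rng.integers(50, 2001))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            orf = longest_orf(seq)
            exp_len, exp_start = exhaustive_orf(seq)
            assert orf.nt_length == exp_len
            assert orf.start_offset == exp_start
            assert orf.nt_length % 3 == 0
            assert orf.nt_length <= 3 * (n // 3)

    def test_invariant_to_bases_after_stop(self):
        base = "ATGAAACCCTAG"
        for suffix in ("", "A", "ATGAA", "GGGTTT"):
            assert longest_orf(base + suffix).nt_length == 9

    def test_reverse_complement_fixture_property(self):
        """A '-' transcript's ORF equals the '+' ORF of the revcomp fixture."""
        rng = np.random.default_rng(41)
        seq = plant_orf(400, 120, rng)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(seq))
        genome = {"c": rc}
        t_minus = make_transcript("t", "c", "-", [(1, 400)])
        assert longest_orf(spliced_sequence(t_minus, genome)).nt_length == 120


class TestTranslate:
    def test_code_table_examples(self):
        seq = SplicedSequence("t", "ATGTTTTAA")
        orf = longest_orf(seq)
        assert translate(orf, seq) == "MF"
        seq2 = SplicedSequence("t", "ATGAAACAT")
        assert translate(longest_orf(seq2), seq2) == "MKH"

    def test_n_codon_translates_to_x(self):
        seq = SplicedSequence("t", "ATGANATAA")
        assert translate(longest_orf(seq), seq) == "MX"

    def test_zero_length_orf_rejected(self):
        seq = SplicedSequence("t", "CCCCCC")
        with pytest.raises(ValueError):
            translate(longest_orf(seq), seq)

    def test_matches_codon_table_oracle(self):
        table = {
            "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L",
            "CTC": "L", "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I",
            "ATA": "I", "ATG": "M", "GTT": "V", "GTC": "V", "GTA": "V",
            "GTG": "V", "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
            "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P", "ACT": "T",
            "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
            "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H",
            "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
            "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E",
            "GAG": "E", "TGT": "C", "TGC": "C", "TGG": "W", "CGT": "R",
            "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S",
            "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
            "GGG": "G",
        }
        rng = np.random.default_rng(43)
        for _ in range(50):
            n_codons = int(rng.integers(1, 40))
            codons = ["ATG"]
            choices = [c for c in table if c not in ("TAA", "TAG", "TGA")]
            codons += list(rng.choice(choices, size=n_codons))
            seq = SplicedSequence("t", "".join(codons) + "TAA")
            orf = longest_orf(seq)
            assert orf.nt_length == 3 * (n_codons + 1)
            expected = "".join(table[c] for c in codons)
            assert translate(orf, seq) == expected


class TestStepFilters:
    def test_length_boundary_is_strict(self):
        t200 = make_transcript("a", "chr1", "+", [(1, 100), (201, 300)])       # 200 nt
        t201 = make_transcript("b", "chr1", "+", [(1, 100), (201, 301)])       # 201 nt
        kept = extract_length([t200, t201])
        assert [t.transcript_id for t in kept] == ["b"]
        assert extract_length([]) == []

    def test_orf_boundary_297_vs_300(self):
        rng = np.random.default_rng(47)
        genome = {
            "c1": plant_orf(400, 297, rng),
            "c2": plant_orf(400, 300, rng),
        }
        t_keep = make_transcript("keep", "c1", "+", [(1, 400)])
        t_drop = make_transcript("drop", "c2", "+", [(1, 400)])
        retained, results = extract_orf([t_keep, t_drop], genome)
        assert [t.transcript_id for t in retained] == ["keep"]
        assert results["keep"].nt_length == 297
        assert results["drop"].nt_length == 300

    def test_mrna_vs_ncrna_plants_partition_exactly(self):
        rng = np.random.default_rng(53)
        genome, transcripts, expect_kept = {}, [], set()
        for i in range(30):
            orf = int(rng.choice([0, 90, 150, 297, 300, 360, 450]))
            chrom = f"c{i}"
            genome[chrom] = plant_orf(600, orf, rng)
            tid = f"t{i}"
            transcripts.append(make_transcript(tid, chrom, "+", [(1, 600)]))
            if orf < 300:
                expect_kept.add(tid)
        retained, _ = extract_orf(transcripts, genome)
        assert {t.transcript_id for t in retained} == expect_kept


@settings(max_examples=60, derandomize=True)
@given(_dna)
def test_orf_properties_hold_on_arbitrary_sequences(seq):
    """Divisibility, bounds and oracle agreement on arbitrary DNA with N."""
    orf = longest_orf(seq)
    assert orf.nt_length % 3 == 0
    assert 0 <= orf.nt_length <= 3 * (len(seq) // 3)
    exp_len, _ = exhaustive_orf(seq)
    assert orf.nt_length == exp_len
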