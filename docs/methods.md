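# Methods

## Problem and model

Given transcripts assembled from RNA-Seq read alignments (transfrags, each
carrying an assembler FPKM estimate), the package predicts which of them are
novel long non-coding RNAs relative to a reference gene annotation. The
operational lncRNA definition is structural and sequence-based: a spliced
transcript longer than 200 nt, not matching or contained in any annotated
gene, whose longest putative ORF stays below 300 nt, and which shows no
protein-coding signal in a phylogenetic codon-substitution test (PhyloCSF)
or a protein-domain search (Pfam via HMMER). The package authors the
classification, thresholding and filtering machinery; PhyloCSF and HMMER
themselves are external tools whose per-transcript output files are parsed
and applied, never re-implemented.

## Class-code classification

Each query transcript is compared with every reference transcript whose
genomic span it overlaps (an interval tree per chromosome makes this
sub-linear; a brute-force all-pairs classifier in the test suite checks
equivalence). Per reference transcript the first matching rung of a fixed
precedence ladder wins, and the best rung across the reference set is the
transcript's code:

1. `=` identical intron chain, same strand (exon end padding ignored);
2. `c` intron chain is a contiguous sub-chain of the reference's and all
   exons lie within the reference span (single-exon: exon inside a reference
   exon), same strand;
3. `j` at least one identical splice junction (both donor and acceptor
   coordinates), same strand;
4. `o` ≥ 1 bp exon–exon overlap, same strand;
5. `i` span entirely inside a single same-strand reference intron;
6. `x` ≥ 1 bp exon–exon overlap, opposite strand;
7. `s` intron–intron overlap on the opposite strand without exonic overlap;
8. `u` otherwise.

Ties between reference transcripts yielding the same code break on
(chromosome, start, transcript id), making output deterministic. Design
choices where conventions genuinely diverge: unknown-strand queries may take
the overlap codes (`c`, `o`, `i`) against either strand but never the
junction-based codes (`=`, `j`) and never `x`/`s`; `i` is same-strand only,
so opposite-strand intronic containment falls through to `s` or `u`;
single-exon transcripts are classifiable (the pipeline normally drops them
first, but the classifier stays reusable). One consequence of the
eight-code vocabulary: a transcript straddling a reference boundary with
exons placed only in intronic space earns no rung and is coded `u` even
though its span touches the reference; the suite therefore checks the
precise invariant that `u` transcripts share no exonic sequence with any
reference.

Reference annotations from several sources are merged by structure before
classification: transcripts are identical when chromosome, strand and
intron chain agree (exact exon interval for single-exon records), and the
first-seen record's identifiers are kept.

## Expression threshold

With complete (`=`) assemblies as positives and partial (`c`) assemblies as
negatives, FPKM is scored on an ROC curve. Candidate thresholds are −∞, the
midpoints between consecutive distinct pooled values, and +∞. The
classification rule is strict (positive when FPKM > t), giving sensitivity
non-increasing and specificity non-decreasing in t; the area under the
curve equals the Mann–Whitney probability on the two samples. The optimum
t* minimises (1 − sens)² + (1 − spec)², i.e. the squared distance to the
perfect corner; ties resolve to the lowest threshold, the choice that
retains the most transcripts. The downstream filter is inclusive
(keep FPKM ≥ t*) while the ROC rule is strict — both kept exactly as
stated by their respective conventions, and both configurable. `=`
transcripts bypass the expression filter entirely; `c` transcripts are
always excluded from the high-quality set.

## Putative ORF

Sequences are spliced from the genome exon by exon in genomic order and
reverse-complemented as a whole on the minus strand. The putative ORF is
the longest ATG-anchored in-frame codon run over the three sense-strand
frames, ending at the base before the first in-frame stop or, failing a
stop, at the last complete codon (reported with `has_stop = False`; counting
such runs is the conservative choice, since it inflates ORF length and
makes the lncRNA call more stringent). The reported length excludes the
stop codon so that 300 nt ⇔ 100 aa exactly. Codons containing N never match
ATG or a stop and translate to X. Ties break to the smallest start offset.
Only the sense strand is scanned: assembled multi-exon transcripts are
stranded.

## Coding-evidence filters

PhyloCSF scores arrive as a two-column table (id, score in decibans or a
failure message). Retention requires score < 0 (strict) or a failure caused
by an ORF shorter than 25 aa; any other failure — and any transcript absent
from the file — is missing evidence and drops the transcript by default
(configurable). Pfam evidence arrives as HMMER3 `--domtblout`; a transcript
is dropped when any domain's independent E-value is ≤ 1e-3 (the tool's
output does not define "significant", so the cutoff is explicit and
configurable). Both readers accept gzipped files.

## Pipeline

Stage order is fixed: multi-exon filter → classification → high-quality
selection (FPKM threshold, `auto` derives t* from the run's own `=`/`c`
values) → candidate categories {i, j, o, u, x} → length > 200 nt → ORF
< 300 nt → PhyloCSF → Pfam. The ORF step sits before the evidence steps
because it removes most mRNA-like transcripts cheaply. Accounting
telescopes (each step's input equals the previous step's retained count)
and outputs are byte-deterministic given identical inputs.

Parameters, defaults and units: `min_length_nt` 200 (exclusive),
`max_orf_nt` 300 (exclusive), `phylocsf_cutoff` 0 decibans (strict),
`phylocsf_min_aa` 25, `pfam_evalue` 1e-3, `fpkm_cutoff` `"auto"`,
`candidate_codes` {i, j, o, u, x} (`s` is admissible but excluded by
default), `multi_exon_only` true.

The differential-expression layer is deliberately thin: log2 fold change
with a 1e-6 pseudocount (keeps zero FPKM finite), Benjamini–Hochberg
step-up q-values (q_(i) = min_{j≥i} m·p_(j)/j, capped at 1) with
significance at q < 0.05 strict, and Welch unequal-variance t-tests
(Welch–Satterthwaite degrees of freedom, via scipy) for feature contrasts.
Per-transcript p-values are inputs — the count-model testing that produces
them belongs to dedicated DE tools. Structural overlap against an external
catalogue partitions a query set into exact (identical structure), partial
(≥ 1 bp exonic overlap, strand-agnostic) and none.

## Synthetic fixtures

The generator emulates the full input bundle at desk scale. Each planted
transcript occupies its own locus (6 kb stride over 2 chromosomes,
alternating strands) with, where needed, a private 4-exon reference gene
(exons 150–300 bp, introns 700–900 bp). The default population of 200
queries: 60 complete (`=`), 60 partial (`c`), 20 lncRNA-like novels (4 per
candidate code), 30 mRNA-like novels (cycling the decoy mechanism: long ORF
≥ 300 nt, positive PhyloCSF, or significant Pfam hit), 30 low-FPKM
artifacts. Complete/partial FPKM are log-normal with natural-scale means
29.67 and 4.86 (σ = 1), the magnitudes of a well-separated real
complete/partial contrast. Candidate and artifact FPKM are anchored to the
threshold the complete/partial populations induce (uniform 1.5–12× t* and
0.05–0.6× t* respectively) so that planted retention labels are exact by
construction rather than probabilistic.

ORF planting writes an ATG + {C,G}-only codon body + TAA into an
ATG-stripped random background: with no A/T inside the body, no start or
stop codon can arise in any frame across the insert, and junction-born ATGs
are sealed after assembly. Every plant is re-measured with the package's
own ORF finder, and every class code re-derived with the classifier,
before the generator returns — a failed plant raises instead of producing a
corrupt fixture. A second reference GTF duplicates every fifth reference
structure under new identifiers with padded terminal exons to exercise
merge deduplication.

What the fixtures do not emulate: overlapping gene neighbourhoods and
nested loci (covered separately by the randomised classification scenarios
in the test suite), realistic mammalian exon/intron length distributions,
sequencing noise in FPKM estimates, alternative isoform families, and any
correlation structure between expression and coding status. Passing the
end-to-end test therefore demonstrates that the machinery implements its
stated rules exactly, not that those rules achieve any particular
sensitivity on real tissue data.

## Numerical choices and edge cases

- Coordinates are 1-based inclusive at all interfaces (GTF convention).
- Overlapping or abutting exons within one transcript are an error, not
  silently merged: assemblers emit disjoint exons, so this surfaces
  upstream corruption.
- FPKM is serialised with Python's shortest round-trip float representation,
  so GTF write→read preserves it bit-exactly.
- ROC ties in the corner objective resolve to the smallest index; argmin is
  exact, no tolerance.
- An empty reference set codes everything `u`; zero pipeline survivors is a
  valid outcome (empty GTF, complete accounting).
- Problem sizes in the test and acceptance runs — 1,000-transcript
  classification scenarios, 500 random ORF sequences, 200 threshold
  replicates, the 200-transcript default fixture — were chosen as the
  smallest scales at which every plant class and class code is exercised
  multiple times.

## Known limitations

- The classifier implements eight codes; assembler-comparison tools
  distinguish further categories (pre-mRNA fragments, polymerase run-on)
  that fold into `o`/`u` here.
- FPKM estimation itself, read mapping and assembly are out of scope; FPKM
  values are trusted inputs.
- PhyloCSF scores are consumed per transcript id; whether a score was
  computed on the whole transcript or its called ORF is up to the caller's
  external PhyloCSF run.
- The DE layer adjusts externally supplied p-values; it does not model
  counts.
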