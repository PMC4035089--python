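# Methods

This note documents the models and conventions behind `nmcompare`: what
each detector assumes, what the synthetic-data generator emulates, the
numerical choices that matter, and the limits of what passing tests
demonstrate about real data.

## Coordinates, sequences, formats

All internal coordinates are 0-based, half-open; GFF3 I/O converts
to/from that format's 1-based inclusive convention, so interval
arithmetic never carries off-by-one corrections. GC content always
excludes ambiguity characters from both numerator and denominator, which
keeps measurements unbiased on degenerate synthetic sequence. Gene
category labels (`eukaryotic-conserved`, `plastid-associated`, `nORFan`,
`spliceosomal`, `other`) travel in a `category=` GFF3 attribute and are
taken as given — similarity-based annotation is out of scope, as is the
homology inference behind the ortholog family table, which is an input
(TSV) rather than a computation. Minus-strand proteins are obtained by
reverse-complement followed by standard-code translation (table 1).

## Terminal repeat detection

Reduced genomes of this kind carry long, nearly identical repeats on
every chromosome end, kept homogeneous by recombination and gene
conversion. The detector orients each end telomere-inward (right ends
reverse-complemented — the repeats are symmetric about the telomere) and
reports, per end, the longest terminal prefix whose identity to *every*
other end stays at or above `min_identity` (default 0.995, matching a
handful of substitutions over tens of kilobases) and reaches
`min_length` (default 1,000 bp). Identity is computed from cumulative
mismatch counts, so the scan is linear per end pair. The reported
boundary overshoots the true repeat edge only until the mismatch budget
is exhausted; at 99.5% identity this is a few tens of bases, which is
why recovery tests use a ±50 bp convention for boundary agreement —
a convention of this package, since repeat edges have no canonical
definition at single-base resolution.

## Boundary tandem arrays

The tandem detector scores each candidate unit length k by the number of
positions i with s[i] = s[i+k] and keeps the best-scoring k, ties going
to the smallest (the primitive period; a period's multiples score
strictly fewer matches). An array qualifies when the winning k supports
`min_copies` full copies at a match fraction of at least 0.8 — random
sequence sits near 0.25, so the gap is wide. The per-column consensus
uses the smallest IUPAC code covering every base observed at ≥ 20%
column frequency: a 50/50 A/G column yields R, reproducing two-state
degeneracies without promoting sequencing-noise-level minorities into
codes. Output is rotation-invariant up to a cyclic shift of the
consensus.

## Intron machinery

An intron is an inter-exon gap; its record carries length, phase
(spliced-CDS length upstream, mod 3), and donor/acceptor dinucleotides
read in transcript orientation. Gaps under 4 bp are flagged invalid and
excluded from distributions. Junction calling from gapped alignments
normalizes placement ambiguity — a gap whose flanking bases repeat can
shift — by preferring a placement whose boundary is in the requested set
(GT-AG by default, checked on both strands), else leftmost, the standard
splice-caller convention; junctions below `min_support` are dropped.

Cross-genome position comparison pairs one protein per family per genome
(the longest, if a family is multicopy, with a warning) and aligns them
globally under BLOSUM62 with affine gap costs: 10 for the first gap
residue, 0.5 per additional residue, terminal gaps penalized. The
alignment is delegated to Biopython's `PairwiseAligner`; its optimal
score is cross-checked in the test suite against an independent Gotoh
dynamic program on short peptides. Each intron maps to the alignment
column of the residue whose codon contains it (phase 1/2) or of the
preceding residue (phase 0 — a between-codon intron has no containing
codon, so the upstream residue anchors it). An intron is *comparable*
when the 15 alignment columns on each side of that column are gap-free
in both sequences and each window exceeds 50% identical residues,
counted window-locally (identical residues / window length); two
comparable introns are *shared* when they occupy the same column with
the same phase. Unshared introns can be polarized against an outgroup
presence table built under the same filter (the looser 40%-identity
variant is the conventional choice for distant outgroups): presence in
an outgroup implies loss in the genome lacking the intron, otherwise the
direction stays ambiguous.

## Synteny

Gene orders are family sequences sorted by start coordinate, optionally
restricted to families shared with the partner genome (original
coordinate ranks are retained so gap allowances still apply). A block is
a maximal run of families consecutive — up to `max_gap` intervening
genes, default 0, i.e. strict "same order" — and order-conserved in both
genomes; inverted runs are reported when enabled. Overlapping candidates
are resolved greedily by length then leftmost position, and each gene
placement joins at most one block, preventing double counting of
multicopy families. The published block criterion ("more than three
homologous genes in the same order") is ambiguous between ≥ 3 and ≥ 4,
so `min_genes` is an explicit parameter (default 3) and the synthetic
fixtures plant blocks of ≥ 4 genes, detectable under either reading.

## Gene statistics

Spacers are gaps between transcriptional-unit extents of adjacent genes
sorted by start, strand ignored; overlapping genes contribute 0 and are
flagged (whether to zero-count or exclude overlaps is not standardized;
the flag lets users do either). Spacers spanning an excluded region
(e.g. a masked boundary array) are dropped. Protein lengths exclude the
terminal stop. Redundancy collapse clusters proteins by single linkage
when global-alignment identity ≥ 0.98 over ≥ 0.95 of the longer
sequence — tight enough to merge conversion-homogenized repeat copies
(a few mismatches over tens of kilobases) without merging diverged
paralogs; byte-identical sequences short-circuit the aligner. The Welch
unequal-variance *t*-test (SciPy, Welch–Satterthwaite degrees of
freedom) backs the spacer and protein-length contrasts; only the
unpaired test is exposed since only unpaired contrasts are reported.

## Expression and copy number

Per-gene depth is summed per-base coverage over the gene divided by gene
length, with an optional exonic-only mode and a zero-coverage flag.
Group contrasts are ratios of group mean depths. Copy number is the mean
depth of a region over a baseline, defaulting to the *median* per-base
depth across designated single-copy regions — the median resists other
repeat peaks, where a mean would not. bedGraph intervals are 0-based
half-open; overlapping intervals are rejected as an input error.

## The synthetic-data generator

The generator is the package's study-condition definition, not a tuning
surface. Defaults (desk scale): three 20 kb linear chromosomes with
3.5 kb terminal repeats at 49.4% GC — drawn with an *exact* GC base
count, since the repeat's composition is a property of the data rather
than a sampling mean, and a 3.5 kb binomial draw would wander by nearly
a percentage point — against 24% internal GC; exactly 3 substitutions
distributed across the six repeat copies; a boundary tandem array of
5–29 copies of the degenerate 36-mer, IUPAC positions resolved uniformly
per copy while the planted consensus keeps the degenerate letters; ten
internal protein genes per chromosome (mean 170 codons — scaled down
from the few-hundred-codon proteins of real reduced genomes so the desk
chromosomes stay packable; the full-scale preset uses 247); intergenic
spacers geometric with mean 147.4 bp (the mean is stated by the
reference data, the variance is not; geometric is the maximum-entropy
choice on positive integers and is tunable); introns Poisson(2) per gene
with lengths on 18–23 nt (19 nt modal), GT-AG boundaries with
configurable GC-AG/GA-AG counts, 58.3% phase 0, and an A bias at the
exonic −2 position; five intronless sub-telomeric ORFs plus an rRNA
placeholder per repeat copy (rRNA identification itself is out of
scope); an internally collapsed region emulating a tandem expansion at
5× depth; and a 2,500-fold mean-depth contrast between internal genes
and sub-telomeric ORFs at 100× internal depth.

Genome B is derived from genome A's shared families (85% of singleton
families, all block members) by codon-wise mutation at rate 0.08 with
length preserved — so ortholog alignments are gapless and planted intron
columns are exact, which is what lets recovery tests demand *perfect*
confusion matrices. Planted introns sit at least 15 codons from either
protein end, making every planted intron comparable by construction.
Shared intron positions are retained at 90%; extra genome-B introns
avoid genome-A residues entirely so no spurious "shared" position can
arise. Genome B's unit order is reshuffled under the constraint that no
two units adjacent in A (in either orientation) stay adjacent in B, so
the planted blocks are exactly the maximal conserved runs. Coverage is
per-base Poisson at the class mean — independent sites, no
read-placement model — which suffices for the mean-depth statistics the
pipeline computes but understates the long-range correlation of real
read pileups, and at default depth it cannot reproduce the fully
zero-covered ORFs that shallow real libraries show (the zero-coverage
flag is exercised at low simulated depth instead). Junction evidence is
generated as reads whose gap exactly spans each planted intron; real
spliced alignments carry mismatches, soft-clips and spurious gaps that
the generator does not model.

Consequently, passing recovery tests shows the detectors are *correct*
on data obeying the stated architecture; it does not show robustness to
assembly error, annotation noise, alignment artifacts or
composition-varying mutation processes, none of which the generator
emulates. All randomness derives from one seed through named
`numpy` `SeedSequence` substreams; fixed (config, seed) reproduces
byte-identical output, and the end-to-end report writer is byte-stable.

## Degenerate inputs and edge conventions

Empty genomes summarize to zeros rather than erroring; a window larger
than its sequence yields one whole-sequence window; the final partial
window of a profile is included and flagged; empty region sets report GC
as not-available; a protein gene whose CDS length is not divisible by
three is downgraded to a pseudogene with a warning; ORFs shorter than
the 50-codon validation floor are flagged, not dropped. Genome summaries
report both raw and non-redundant protein counts, since reduced genomes
are routinely described with both and the two can legitimately differ in
published tables.
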