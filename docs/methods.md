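# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind each module. Coordinates are 0-based, half-open
everywhere internally; 1-based only in VCF output.

## Amplicon indel calling

**Procedure.** Reads are sorted into amplicons by the presence of the exact
primer sequences at the beginning of both mates (no mismatches allowed;
both mate orientations accepted, since sequencer orientation is not fixed
by the protocol). Mates are merged into the sequenced fragment, identical
fragments are combined, fragments occurring fewer than 100 times are
removed (a count of exactly 100 is retained), and within each (amplicon,
fragment length) group only the most frequent sequence is kept as the
predominant sequence (ties broken towards the lexicographically smallest
sequence, for determinism). Non-reference fragments are globally aligned
to the amplicon reference and every maximal gap run becomes one indel;
a deletion run immediately adjacent to an insertion run merges into a
single replacement event. Indels are identified across amplicons by their
left-aligned `(ref_start, ref_span, alt_seq)` in locus coordinates and
called when supported at ≥ 0.5 % of merged reads in ≥ 2 amplicons.

**Pair merging.** The external merger the protocol refers to is replaced
by a self-contained overlap merger: among all overlaps `o ≥ 10` with
mismatch fraction ≤ 0.1, the one maximising the number of matching bases
wins (ties to the longer overlap); at disagreeing positions the base with
the higher quality is kept, the forward base on a quality tie. Match
counts over all offsets are computed exactly by cross-correlation of
one-hot base encodings. The statistical overlap test of the external tool
is intentionally out of scope; the deterministic maximiser is easier to
reason about and to test against a brute-force offset search.

**Alignment scoring.** Global end-to-end alignment with affine gaps:
match +2, mismatch −4, gap open −6, gap extend −1 (a gap of length *L*
costs `open + (L−1)·extend`). These scores favour one consolidated gap
over several scattered ones, which matches the single-deletion repair
outcomes the assay is designed to detect. All scores are configurable via
`AlignScoring`. The implementation delegates the DP to Biopython's
`PairwiseAligner`; the test suite checks it against an independent Gotoh
implementation with traceback on fragments ≤ 60 nt.

**Read-fraction denominator.** "Fraction of the reads" is interpreted as
the fraction of successfully merged reads of that amplicon, computed
*before* the < 100-count fragment filter (the filter removes sequences,
not reads). A `denominator="post"` switch uses post-filter totals instead.
Likewise, the ≥ 0.5 % support requirement applies per supporting amplicon
by default (`fraction_mode="per_amplicon"`); `"overall"` pools counts
across amplicons before thresholding.

**What the caller's fraction estimates.** Because support is counted from
exact collapsed fragment sequences, a clone's measured fraction is its
sequencing fraction times the probability that a merged fragment survives
with no residual substitution error. Conditioned on demultiplexing (both
primer prefixes error-free), a merged position is wrong iff the read whose
base the consensus keeps carried an error there, giving survival
`(1−e)^k` with `k = min(read_len, L) − |fwd primer| + max(0, L − |rev
primer| − read_len)` for a product of length *L*. The simulator's truth
tables record both the sampling fraction (`expected_frac_*`) and this
calibrated expectation (`expected_called_frac_*`); recovery tests compare
the caller to the latter, which is the estimator's true expectation. At
the default error rate (0.1 %) and ~400 bp products the factor is ≈ 0.70.

**Clonality.** `n_distinct_indels` counts called indels with |length|
strictly greater than 1 bp; `top_k_read_share` ranks all called indels by
their mean-across-amplicon fraction and reports cumulative shares of the
total called mass. An empty call list reports not-applicable (None), not
zero.

## WGS deletion calling

**Evidence.** Both mate ends are treated independently. CIGAR evidence:
every D run between two M runs yields a deletion (I runs are extracted to
a side channel; the filter cascade is deletion-centric). Split evidence:
two alignment segments of one read end on the same chromosome and strand,
in consistent query order, with a positive reference gap, yield a deletion
spanning the gap. Read-level filters: every mapped stretch ≥ 25 bp and
≥ 95 bp mapped in total (both inclusive). PCR duplicates are defined by
identical outer template coordinates on both ends; support counts distinct
templates.

**Filter cascade.** Fixed order so drop tallies are reproducible:
size ∈ [4, 100 000] bp → breakpoints not within ± 5 bp of any pooled
control-event breakpoint → no > 0.80 reciprocal overlap with a known
polymorphic indel interval → breakpoints (± 5 bp) clear of simple-repeat
intervals → breakpoints not in positions with combined control coverage
> 250 (strict; 250 passes). Each dropped event is attributed to the first
failing filter. The polymorphic criterion is interval-typed (reciprocal
overlap) because BED tracks carry no allele sequence; sequence-level
identity against an indel catalogue would be a drop-in replacement where
alleles are available. Control coverage is M-base depth per position
computed from the control alignments.

**Frameshift and allele fractions.** For a deletion and an exon, the
exonic loss *d* classifies as no-coding-overlap (*d* = 0), in-frame
(*d* ≡ 0 mod 3) or frameshift (otherwise). Reads over the cut position
(± 10 bp flank by default) are assigned to exactly one class: a called
locus deletion (the read's own deletion observation matches it exactly),
wild type (a contiguous mapped stretch across the cut), or unassigned;
fractions are over all considered reads, so they sum to ≤ 1. This
assignment replaces the re-alignment of reads to an indel-allele reference
set: with alignments as input, matching each read's own indel observation
to the called alleles is the same classification without invoking an
external aligner. Zero covering reads yield not-applicable, not zero.

## Off-target scanning and recurrence screens

Windows of length 20 on both strands within the mismatch budget are found
by exhaustive Hamming profiling (vectorised; verified against a
brute-force scan). N bases never match. The PAM (NGG) is *not* required by
default because the non-targeting-control analysis that motivates the scan
used the bare 20-mer; `require_pam` enables it. A deletion is
guide-matched when a hit starts within ± 30 bp of either breakpoint — the
window covers the guide length plus cut-site offset and modest resection,
and is exposed as a parameter since no canonical value exists. Loci are
defined by transitive merging of events padded by 5 bp (the same padding
convention as the control-breakpoint filter). The two screens return loci
with events from every tumour sample, and loci where one sample
contributes ≥ 2 distinct (start, end) deletions.

## SURVEYOR quantification

`fraction_cleaved = Σ cleaved / (Σ cleaved + parent)` after per-band
background subtraction floored at zero — the standard convention, as the
assay itself does not fix one. `% modified = (1 − √(1 − fc)) × 100`: with
modified-allele fraction *p*, a random re-hybridised duplex is cleavable
unless both strands are unmodified, so `fc = 1 − (1 − p)²`. No molar
correction for fragment length is applied to intensities. The function is
strictly increasing with exact endpoints 0 → 0 % and 1 → 100 %, and the
round trip through the inverse is accurate to 10⁻¹².

## Synthetic data generator

**What it emulates.** A 3 kb random surrogate locus with a real guide
protospacer + NGG PAM planted so the blunt cut falls 17 nt into the
protospacer; a polyclonal population of edited alleles whose edits all
straddle the cut: a few predominant clones (default relative frequencies
0.5/0.3/0.2 over an edited mass of 0.9) plus a 20-clone tail sharing 0.1,
deletion sizes mixing 1–30 bp, 31–500 bp and 0.5–2.5 kb, and insertions
of 1–9 bp; five staggered 400 bp amplicons (primers taken from the locus)
sequenced 251 bp paired-end at 50,000 pairs per amplicon by default; and
101 bp paired-end WGS at 23.3× mean coverage with ~320 bp inserts.
Amplicon alleles that lose a primer site yield no product, and the reads
of the surviving alleles are renormalised accordingly, exactly as PCR
would. WGS deletions ≤ 100 bp appear in one record as `xM nD yM`; larger
ones as primary + supplementary split segments, mirroring how a short-read
aligner represents them. Substitution errors are uniform at 0.1 % with
constant Q37 qualities. A fixed seed yields byte-identical FASTQ/SAM/BED.

**What it does not emulate.** Indel sequence context (microhomology), PCR
amplification bias, position-dependent quality/error profiles, chimeric
reads, mapping ambiguity in repeats, or alignment artefacts — the reads
are emitted pre-aligned because the deletion caller's contract starts from
alignments. Passing recovery tests therefore demonstrate the correctness
of the calling logic under a clean error model, not robustness to aligner
pathologies on real genomes.

**Scale choices.** Tests and the acceptance script use a 3 kb locus,
50,000 pairs/amplicon and 25–30× WGS: at these sizes every rate the tests
assert (binomial noise on a 0.5 % threshold at n = 50,000, ≥ 3 expected
spanning reads for a 4 bp+ deletion at 25×) is statistically resolvable,
and a full run completes in seconds. Genome-scale inputs go through the
same code paths via pysam/pyfaidx streaming.

## Known limitations

* Amplicon calling is indel-only (no SNV calling, no quality trimming, no
  UMI handling) and assumes products short enough for 251 bp mates to
  overlap by ≥ 10 bp.
* The per-amplicon fraction undercounts clones by the error-survival
  factor described above; comparisons across clones are unaffected (the
  factor nearly cancels), absolute fractions should be read with it in
  mind.
* The polymorphic-indel filter is interval-based, not sequence-identity
  based.
* Split-read pairing requires consistent order on the same chromosome and
  strand; inversions and translocations are out of scope, as are CNVs and
  insert-size (discordant-pair) evidence.
* Guide scanning is ungapped (no bulges) and reports no cutting-efficiency
  scores.
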