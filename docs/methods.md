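# Methods

## Model and assumptions

The package operates on one contig of a linear reference genome plus a
phased, diploid, multi-sample variant panel restricted to SNPs and small
indels whose reference spans do not overlap. All internal coordinates are
0-based half-open; VCF positions are converted on read and SAM POS on
write. Reads are short (tested at 100 bp) and unspliced; `N`-heavy spliced
alignments, CRAM, and long reads are out of scope.

The central assumption is that the reference-guided MSA of reference and
founder sequences need only be *consistent with each founder's pairwise
alignment to the reference*, not optimal. Founder sequences are built
site-wise from panel alleles, so the MSA can be constructed exactly: each
variant site contributes a column block as wide as the longest allele in
use, left-aligned and gap-padded, and inter-site reference stretches are
copied gap-free. Ungapping any row reproduces the corresponding sequence
bit-exactly, which the tests assert.

## Founder generation

Segmentation is a greedy left-to-right scan: the current segment is closed
at the earliest site where it already spans ≥ L sites and adding the next
site would push the number of distinct haplotype strings above F − 1
(F counts the reference, so the panel contributes at most F − 1 founders).
Two repairs keep the stated invariants under any input: a trailing segment
shorter than L is merged into its predecessor, and a segment forced over
capacity by L retains its F − 1 most frequent strings (frequency ties →
earlier first occurrence) and reassigns evicted haplotypes to the retained
string with minimum Hamming distance over the segment's allele indices
(ties → lower string index). The greedy scan is not provably minimum;
exhaustive search on panels of ≤ 8 sites bounds the gap at one segment in
the test suite, and in the randomized runs performed there the greedy
count never exceeded the optimum.

Chaining orders each segment's strings by descending support and matches
consecutive segments greedily by descending joint-support count
(ties → lexicographically smaller index pair). A matched pair never
jointly carried by any haplotype contributes one recombination.
Reference-allele fill slots (segments with fewer strings than founders)
have empty support, so chains through them count as recombinations; this
follows the literal definition and makes the count conservative.

L is measured in variant sites per segment, not reference bases. The
published parameterisations in this area are ambiguous on this point; a
site-based L is what the segmentation actually operates on and is the
documented, configurable choice here.

## Projection

The index stores, per ungapped founder position, the reference position
and an in-insertion flag; for insertion columns the stored value is the
number of reference bases strictly before the column, i.e. the position of
the next reference base. Construction is a single column walk.

Rewriting walks the read's ops once, flushing founder-gap reference bases
as deletions *in column order* (the stored positions of insertion entries
make this possible without re-touching the MSA). Deletions outside the
outermost aligned bases are dropped and the leftmost advanced, since SAM
cannot anchor an alignment on a deletion; terminal insertions likewise
become soft clips. Normalization pairs adjacent I/D runs base-for-base
into M (remainders kept in place, repeated to a fixpoint) and is
idempotent. This I/D pairing is a deliberate, deterministic stand-in for
a full re-alignment of the affected read segment: it produces a minimal
edit script without heuristic indel left-shifting. A randomized
equivalence test (10⁴ cases) checks the linear-time rewriter against a
brute-force per-column composition oracle; query-length conservation is
asserted unconditionally.

Alignments wholly inside a founder insertion have no reference anchor and
are returned flagged unmapped (not dropped), preserving read accounting.
NM/MD are recomputed when a reference is supplied and dropped otherwise;
AS is preserved. Mates are projected independently and mate fields
recomputed in a name-grouped pass.

## Scoring and MAPQ

The scoring scheme defaults to end-to-end short-read constants: match
bonus 0, mismatch penalty interpolating 2..6 with base quality (capped at
Q40), N penalty 1, gap open 5, gap extend 3, minimum score −0.6 − 0.6·len,
perfect score 0. All constants are configurable dataclass fields.

The MAPQ model is a data-driven piecewise table on (best, second-best,
minimum, perfect) scores with a 42 cap. It follows the shape of the
published end-to-end table of the aligner this scheme models, adjusted to
be monotone non-decreasing in the score gap for any fixed best score
(the verbatim table is not), with the zero-gap branch capped at MAPQ 3 and
unique alignments never below tied ones. Bit-exact reproduction of any
particular aligner release is explicitly not a goal; the table is swappable.

Partition keys include strand by default (same leftmost on opposite
strands is a different placement); `strand_in_key=False` is available.
Non-best partitions receive MAPQ 0 and the secondary flag, so MR mode
(no filtering) still emits them; MM mode keeps the maximum-MAPQ record
with ties broken by score, then lowest (target, position).

## Evaluation

Allele support is string-based over the expanded alignment: the read bases
covering the site's reference span (including insertions anchored strictly
inside the span's junctions) must reproduce the REF or ALT allele exactly;
reads matching neither count toward coverage (configurable) but toward
neither R nor A, a conservative choice. "Fully enclosed" requires at least
one aligned base strictly before the site and one match/mismatch operation
consuming reference at or after its end. Sites with coverage < 20 (default)
or R + A = 0 are dropped.

For precision/recall, a placement within 5 bases of the truth position on
the right contig is a TP; a placement elsewhere counts as both FP and FN;
unaligned or missing reads are FN only. This preserves the identity
TP + FN = number of reads, which is asserted on every run. Precision's
denominator is the aligned reads (TP + FP) — the accounting that keeps the
identity while still defining a precision.

## Synthetic data

The generator emulates a take-one-out diploid experiment: i.i.d. uniform
reference; SNPs at 1e-3/base and indels at 1e-4/base (lengths uniform in
[1, 10], insertions and deletions equiprobable, spans non-overlapping);
allele 0/1 drawn Bernoulli(0.5) per haplotype; a 32-haplotype panel with
the last sample held out as donor; 40× of 100 bp single-end forward-strand
reads drawn in equal numbers from the two donor haplotypes with 0.2%
substitution errors (Q40 bases, Q10 at injected errors, exercising
quality-weighted mismatch penalties deterministically). Truth positions
are the read origins mapped through the haplotype's variant set; the
oracle aligner places reads there with the variant-induced edit script and
MAPQ 42. One global seed streams into independent per-stage generators,
so each stage is individually reproducible.

What this does *not* emulate: realistic error and quality profiles,
paired-end inserts, reverse-strand reads, structural variants, population
linkage structure (alleles are drawn independently per site), or GC and
mappability biases. Passing tests therefore demonstrate the correctness
of the machinery — coordinate algebra, scoring, accounting, filters — not
the field performance of any aligner on real data.

## Problem sizes and numerical choices

The default verification sizes are a 100 kb contig at 40× (≈ 40 000 reads,
≈ 110 panel sites, ≈ 55 donor het sites) for the bias experiment, 10⁴
randomized cases for the projection and scoring oracles, and ≈ 120 random
panels (≤ 20 haplotypes × ≤ 200 sites) for the founder recombination
property — sizes chosen so the whole suite completes in well under a
minute while every property retains statistical teeth. The unbiased-
balance check uses a 3-sigma CLT interval with per-site binomial variance
0.25/depth. Ties everywhere break deterministically (first occurrence /
lower index / lower coordinate), so all outputs are exactly reproducible
under a fixed seed.

## Known limitations

- Greedy segmentation can exceed the true minimum segment count (bounded
  in tests, not in general).
- Over-capacity collapse breaks the exact-mosaic property for the evicted
  haplotypes by design; the recombination property is guaranteed only when
  no collapse occurs.
- The MAPQ table approximates a published model's shape but is not
  bit-exact with any aligner release.
- The I/D pairing normalization is a stand-in for local re-alignment and
  does not left-shift indels; callers that normalise indels themselves are
  unaffected.
- Paired-end handling recomputes mate fields but implements no
  concordance bonus in scoring.
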