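# panproject

Pangenomic read alignment without giving up the linear reference: build a
small set of **founder sequences** from a phased variant panel, align reads
to them with any standard aligner, then **project** the alignments back onto
the linear reference — rewriting positions and CIGAR strings through a
reference-guided multiple sequence alignment — and **recalculate mapping
qualities** so that duplicated founder content does not destroy MAPQ. The
package also ships the evaluation machinery for measuring what this buys
you: per-site allele balance at heterozygous sites (reference bias) and
alignment precision/recall against simulated truth positions.

It is aimed at people building short-read genotyping workflows who want the
reduced reference bias of a pangenomic index while keeping every downstream
tool (callers, viewers, QC) on ordinary reference-coordinate SAM/BAM.

## The method

**Founders.** Given a phased panel over one contig, a greedy left-to-right
segmentation partitions the variant sites into segments of at least *L*
sites with at most *F* − 1 distinct haplotype strings each (*F* counts the
reference sequence). Strings of consecutive segments are chained by
descending joint haplotype support; every panel haplotype is then a mosaic
of founders switching only at segment boundaries, and the number of
unsupported junctions (recombinations) is reported.

**Projection.** From the reference-guided MSA of reference + founders, a
coordinate index maps every ungapped founder position *f* to a reference
position, flagged when the column is an insertion to the reference. A
read-vs-founder edit script is rewritten to read-vs-reference in time
linear in its operation count: founder-insertion columns become `I`,
founder-gap reference bases become `D`, and the result is normalized
(adjacent I/D pairs collapse to `M`, terminal insertions become soft
clips). Alignments falling wholly inside a founder insertion are returned
unmapped rather than dropped.

**MAPQ.** Identical founder stretches give one read several equal-scoring
placements that project to the *same* reference coordinate. Alignments of
each read are partitioned by (target, projected leftmost, strand); the
best-scoring member represents each partition, and the best/second-best
representative scores enter a Bowtie2-style end-to-end mapping-quality
model (MAPQ = −10·log₁₀ *p*, capped at 42). Collapsed duplicates are
thereby treated as a single unique placement. `filter_max_mapq` implements
the MM mode (keep only the maximum-MAPQ alignment per read).

**Evaluation.** At each heterozygous site the balance is x = R/(R+A),
where R and A count reads supporting the reference and the correct
alternative allele among alignments that fully enclose the site, have an
aligned base after it, and reach coverage ≥ 20; bias is summarised as the
mean absolute error (1/n)·Σ|xᵢ − 0.5| overall and per allele-length
difference. Alignment accuracy counts a placement within 5 bases of its
simulated truth position as a true positive, so that TP + FN equals the
number of reads.

## Worked example

```sh
python examples/04_reference_bias.py
```

```
40000 reads placed at truth over 55 donor het sites
55 sites pass the enclosure + coverage filters
mean balance 0.5111  (0.5 = unbiased; truth placement carries no reference bias)
overall MAE  0.0649
```

A 100 kb diploid donor is held out of a 32-haplotype panel; 40× of 100 bp
reads are drawn equally from both donor haplotypes and placed at their true
reference positions. The mean balance of 0.511 over 55 filter-passing
heterozygous sites is statistically indistinguishable from the unbiased
0.5 (the residual MAE of 0.065 is the binomial sampling noise at ~40×
depth, not bias). The other examples show founder construction
(`01_founders_from_panel.py`), CIGAR rewriting through an MSA with an
insertion and a deletion (`02_project_alignments.py`, `8M` becomes
`2M2I2M1D2M`), and the MAPQ partition fix (`03_mapq_partition_fix.py`,
MAPQ 42 for collapsed placements vs ≤ 3 for genuinely ambiguous ones).

The same workflow is scriptable from a shell via the `panproject` CLI:
`sim-fixtures`, `founders`, `project`, `rescore-mapq`, `filter-mm`,
`bias-eval`, `align-eval` (read alignment itself is delegated to an
external aligner such as Bowtie 2; `project` consumes its SAM/BAM output).

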