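"""Deterministic synthetic data: reference, phased panel, donor, reads.

The generator emulates the ingredients of a take-one-out genotyping
experiment at desk scale: a random reference contig, a phased panel of
SNPs and small indels across many haplotypes, a held-out diploid donor
whose variants are removed from the panel, and error-bearing short reads
drawn in equal numbers from the donor's two haplotypes with their true
reference positions recorded. An oracle aligner places every read at its
true position, providing a perfect-alignment baseline for the projection
and evaluation machinery.

A single global seed streams into per-stage independent generators so each
stage is individually reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import VariantSite
from .msa import write_fasta_sequences
from .panel import HaplotypePanel, Site, apply_haplotype
from .projection import ProjectionIndex, normalize_projected, project_edit_script
from .records import AlignmentRecord

BASES = np.array(list("ACGT"))

CONTIG = "chrS"
DONOR = "DONOR"

QUAL_GOOD = 40
QUAL_ERROR = 10

# per-stage RNG stream ids
_STAGE_REFERENCE = 1
_STAGE_PANEL = 2
_STAGE_READS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic diploid fixture.

    Defaults are the desk-scale reference-bias conditions: a 100 kb
    contig, SNPs at 1e-3 and indels at 1e-4 per base (lengths uniform in
    [1, 10], insertions and deletions equiprobable), 40x coverage of
    100 bp single-end reads with 0.2% substitution errors, and a 32-
    haplotype panel plus a held-out donor.
    """

    seed: int = 0
    ref_length: int = 100_000
    n_haplotypes: int = 32
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    max_indel_len: int = 10
    read_length: int = 100
    coverage: float = 40.0
    substitution_error_rate: float = 0.002

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate", "substitution_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.ref_length, self.n_haplotypes, self.max_indel_len,
               self.read_length) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid samples)")


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def make_reference(cfg: SimulationConfig) -> str:
    """I.i.d. uniform A/C/G/T sequence of ``cfg.ref_length``."""
    rng = _rng(cfg, _STAGE_REFERENCE)
    return "".join(BASES[rng.integers(0, 4, size=cfg.ref_length)])


@dataclass
class PanelFixture:
    """Panel + held-out donor truth produced by :func:`make_panel`."""

    reference: str
    panel: HaplotypePanel          # donor excluded
    sample_names: list
    sites: list                    # all Site objects (shared by panel & donor)
    genotypes: np.ndarray          # (n_haplotypes + 2, n_sites), donor = last 2 rows
    donor_haplotypes: tuple        # two sequences
    donor_indexes: tuple           # two ProjectionIndex (haplotype -> reference)
    donor_het_sites: list          # VariantSite list (heterozygous in donor)

    @property
    def donor_alleles(self) -> np.ndarray:
        return self.genotypes[-2:, :]


def make_panel(cfg: SimulationConfig, reference: str) -> PanelFixture:
    """Place non-overlapping SNP/indel sites and draw phased genotypes.

    Sites are placed Bernoulli per base (``snp_rate`` for SNPs,
    ``indel_rate`` for indels; indel lengths uniform in
    [1, max_indel_len], insertions and deletions equiprobable). Alleles
    are Bernoulli(0.5) per haplotype. The last sample is the held-out
    donor: excluded from the emitted panel, with its two haplotype
    sequences, coordinate maps and heterozygous sites kept as truth.
    """
    rng = _rng(cfg, _STAGE_PANEL)
    n_total = cfg.n_haplotypes + 2  # panel haplotypes + donor's two
    sites = []
    p = 0
    n = len(reference)
    while p < n:
        u = rng.random()
        if u < cfg.snp_rate:
            ref_base = reference[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            sites.append(Site(p, ref_base, (alt,)))
            p += 1
        elif u < cfg.snp_rate + cfg.indel_rate:
            length = int(rng.integers(1, cfg.max_indel_len + 1))
            if rng.random() < 0.5 or p + length + 1 > n:  # insertion
                inserted = "".join(BASES[rng.integers(0, 4, size=length)])
                sites.append(Site(p, reference[p], (reference[p] + inserted,)))
                p += 1
            else:  # deletion of `length` bases anchored at p
                ref_allele = reference[p:p + length + 1]
                sites.append(Site(p, ref_allele, (ref_allele[0],)))
                p += length + 1
        else:
            p += 1
    genotypes = rng.integers(0, 2, size=(n_total, len(sites)), dtype=np.int32)

    panel_names = [f"S{i:03d}" for i in range(cfg.n_haplotypes // 2)]
    hap_names = [f"{s}/{ph}" for s in panel_names for ph in (1, 2)]
    panel = HaplotypePanel(CONTIG, sites, genotypes[:-2], hap_names)

    donor_haps = []
    donor_indexes = []
    for row in genotypes[-2:]:
        seq, ref_map, ins_map = apply_haplotype(reference, sites, row, with_map=True)
        donor_haps.append(seq)
        donor_indexes.append(
            ProjectionIndex(
                founder_name=DONOR,
                reference_name=CONTIG,
                ref_pos=ref_map,
                in_insertion=ins_map,
                ref_length=len(reference),
            )
        )
    het_sites = [
        VariantSite(CONTIG, site.ref_position, site.ref_allele, site.alt_alleles[0])
        for site, (a, b) in zip(sites, genotypes[-2:].T)
        if a != b
    ]
    return PanelFixture(
        reference=reference,
        panel=panel,
        sample_names=panel_names,
        sites=sites,
        genotypes=genotypes,
        donor_haplotypes=tuple(donor_haps),
        donor_indexes=tuple(donor_indexes),
        donor_het_sites=het_sites,
    )


@dataclass
class ReadSet:
    reads: list       # (read_id, sequence, quality tuple, hap_index, start_in_hap)
    truth: pd.DataFrame  # read_id, contig, pos0, strand


def simulate_reads(cfg: SimulationConfig, fixture: PanelFixture) -> ReadSet:
    """Equal numbers of single-end reads from each donor haplotype.

    Start positions are uniform; substitution errors occur per base at
    ``substitution_error_rate`` (quality 10 at errored bases, 40
    elsewhere). The true leftmost is the read's origin projected to
    reference coordinates through the haplotype's variants.
    """
    rng = _rng(cfg, _STAGE_READS)
    n_reads = int(round(cfg.coverage * cfg.ref_length / cfg.read_length))
    n_reads += n_reads % 2  # force even: equal amounts per haplotype
    per_hap = n_reads // 2
    reads = []
    truth_rows = []
    for hap_idx in (0, 1):
        hap = fixture.donor_haplotypes[hap_idx]
        index = fixture.donor_indexes[hap_idx]
        if cfg.read_length > len(hap):
            raise ValueError("read_length exceeds donor haplotype length")
        starts = rng.integers(0, len(hap) - cfg.read_length + 1, size=per_hap)
        for i, start in enumerate(starts):
            read_id = f"read-{hap_idx + 1}-{i:06d}"
            seq = list(hap[start:start + cfg.read_length])
            quals = [QUAL_GOOD] * cfg.read_length
            errs = np.flatnonzero(rng.random(cfg.read_length)
                                  < cfg.substitution_error_rate)
            for e in errs:
                seq[e] = str(rng.choice([b for b in "ACGT" if b != seq[e]]))
                quals[e] = QUAL_ERROR
            reads.append((read_id, "".join(seq), tuple(quals), hap_idx, int(start)))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "contig": CONTIG,
                    "pos0": int(index.ref_pos[start]),
                    "strand": "+",
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "contig", "pos0", "strand"])
    return ReadSet(reads=reads, truth=truth)


def oracle_align(read_set: ReadSet, fixture: PanelFixture) -> list:
    """Place every read at its true reference position (MAPQ 42).

    The edit script is the one induced by the haplotype's variants over the
    read span: the all-match read-vs-haplotype script composed with the
    haplotype-vs-reference gap structure.
    """
    records = []
    rl = None
    for read_id, seq, quals, hap_idx, start in read_set.reads:
        index = fixture.donor_indexes[hap_idx]
        rl = len(seq)
        # fast path: read span is variant-free (contiguous, no insertions)
        rp = index.ref_pos[start:start + rl]
        if not index.in_insertion[start:start + rl].any() and rp[-1] - rp[0] == rl - 1:
            left, cigar = int(rp[0]), [("M", rl)]
        else:
            left, raw = project_edit_script([("M", rl)], index, start)
            if left is None:
                raise ValueError(f"truth missing for read {read_id}")
            cigar = normalize_projected(raw)
        records.append(
            AlignmentRecord(
                read_id=read_id,
                target_name=CONTIG,
                leftmost=left,
                cigar=cigar,
                mapq=42,
                seq=seq,
                quals=quals,
            )
        )
    return records


# ---------------------------------------------------------------------------
# plain-text writers for CLI / external-tool interop


def write_reference_fasta(reference: str, path) -> None:
    write_fasta_sequences([(CONTIG, reference)], path)


def _vcf_header(sample_names, contig_length: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names),
    ]
    return "\n".join(lines) + "\n"


def _write_vcf(path, sites, genotype_rows, sample_names, contig_length,
               het_only: bool = False) -> None:
    with open(path, "w") as handle:
        handle.write(_vcf_header(sample_names, contig_length))
        for j, site in enumerate(sites):
            gts = [
                f"{genotype_rows[2 * s][j]}|{genotype_rows[2 * s + 1][j]}"
                for s in range(len(sample_names))
            ]
            if all(gt == "0|0" for gt in gts):
                continue
            if het_only and all(gt[0] == gt[2] for gt in gts):
                continue
            handle.write(
                f"{CONTIG}\t{site.ref_position + 1}\t.\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles)}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_panel_vcf(fixture: PanelFixture, path) -> None:
    _write_vcf(path, fixture.sites, fixture.genotypes[:-2],
               fixture.sample_names, len(fixture.reference))


def write_donor_vcf(fixture: PanelFixture, path, het_only: bool = False) -> None:
    _write_vcf(path, fixture.sites, fixture.donor_alleles, [DONOR],
               len(fixture.reference), het_only=het_only)


def write_reads_fastq(read_set: ReadSet, path) -> None:
    with open(path, "w") as handle:
        for read_id, seq, quals, _, _ in read_set.reads:
            qual_str = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")


def write_truth_tsv(read_set: ReadSet, path) -> None:
    read_set.truth.to_csv(path, sep="\t", index=False)


def write_fixture(cfg: SimulationConfig, out_dir) -> dict:
    """Generate and write the complete fixture; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    reference = make_reference(cfg)
    fixture = make_panel(cfg, reference)
    read_set = simulate_reads(cfg, fixture)
    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "panel_vcf": os.path.join(out_dir, "panel.vcf"),
        "donor_vcf": os.path.join(out_dir, "donor.vcf"),
        "donor_hap1": os.path.join(out_dir, "donor_hap1.fa"),
        "donor_hap2": os.path.join(out_dir, "donor_hap2.fa"),
        "reads": os.path.join(out_dir, "reads.fq"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_reference_fasta(reference, paths["reference"])
    write_panel_vcf(fixture, paths["panel_vcf"])
    write_donor_vcf(fixture, paths["donor_vcf"])
    write_fasta_sequences([(f"{DONOR}/1", fixture.donor_haplotypes[0])],
                          paths["donor_hap1"])
    write_fasta_sequences([(f"{DONOR}/2", fixture.donor_haplotypes[1])],
                          paths["donor_hap2"])
    write_reads_fastq(read_set, paths["reads"])
    write_truth_tsv(read_set, paths["truth"])
    return paths
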