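"""Phased haplotype panels read from multi-sample VCF.

A panel is the matrix view of a phased VCF restricted to one contig: an
ordered list of variant sites (position, REF, ALTs) and one row of allele
indices per haplotype (sample x phase). Site reference spans never overlap;
when records overlap, the first accepted record wins and later ones are
skipped with a warning, so downstream segmentation and MSA construction can
treat sites independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Site:
    """One variant site; ``ref_position`` is a 0-based base index."""

    ref_position: int
    ref_allele: str
    alt_alleles: tuple

    @property
    def ref_end(self) -> int:
        return self.ref_position + len(self.ref_allele)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    def allele(self, index: int) -> str:
        if index == 0:
            return self.ref_allele
        return self.alt_alleles[index - 1]


@dataclass
class HaplotypePanel:
    contig_name: str
    sites: list
    matrix: np.ndarray  # shape (n_haplotypes, n_sites), allele indices
    haplotype_names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        if self.matrix.ndim != 2:
            raise ValueError("panel matrix must be 2-D")
        if self.matrix.shape != (len(self.haplotype_names), len(self.sites)):
            raise ValueError(
                f"panel matrix shape {self.matrix.shape} does not match "
                f"{len(self.haplotype_names)} haplotypes x {len(self.sites)} sites"
            )
        last_end = -1
        for site in self.sites:
            if site.ref_position < last_end:
                raise ValueError(
                    f"site at {site.ref_position} overlaps the previous site span"
                )
            last_end = site.ref_end
        for j, site in enumerate(self.sites):
            col = self.matrix[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= site.n_alleles:
                raise ValueError(f"allele index out of range at site {site.ref_position}")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def load_panel(
    vcf_source,
    reference: str,
    contig: str,
    interval: Optional[tuple] = None,
    samples_exclude: Sequence = (),
) -> HaplotypePanel:
    """Read a phased multi-sample VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    vcf_source:
        Path to a VCF (optionally bgzipped) readable by pysam.
    reference:
        Full sequence of *contig* (used to verify REF alleles).
    interval:
        Optional 0-based half-open ``(start, end)`` restriction.
    samples_exclude:
        Sample names to drop (e.g. the held-out donor).

    Unphased non-missing genotypes are a hard error; fully missing calls
    become the reference allele; records whose REF span overlaps an already
    accepted site are skipped with a warning.
    """
    exclude = set(samples_exclude)
    start, end = interval if interval is not None else (0, len(reference))
    with pysam.VariantFile(str(vcf_source)) as vcf:
        samples = [s for s in vcf.header.samples if s not in exclude]
        if not samples:
            raise ValueError("no samples left in panel after exclusions")
        sites = []
        columns = []
        last_end = -1
        for rec in vcf:
            if rec.chrom != contig:
                continue
            pos0 = rec.pos - 1  # VCF is 1-based
            if pos0 < start or pos0 >= end:
                continue
            ref_allele = rec.ref.upper()
            if pos0 < last_end:
                logger.warning(
                    "skipping %s:%d whose REF span overlaps a previous site",
                    contig, rec.pos,
                )
                continue
            expected = reference[pos0:pos0 + len(ref_allele)].upper()
            if expected != ref_allele:
                raise ValueError(
                    f"REF allele mismatch at {contig}:{rec.pos}: "
                    f"VCF has {ref_allele!r}, reference has {expected!r}"
                )
            alts = tuple(a.upper() for a in (rec.alts or ()))
            site = Site(pos0, ref_allele, alts)
            column = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    column.extend([0, 0])  # missing call -> reference
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"non-diploid genotype for sample {sample} at {contig}:{rec.pos}"
                    )
                if not call.phased:
                    raise ValueError(
                        f"unphased genotype for sample {sample} at {contig}:{rec.pos}"
                    )
                column.extend(0 if a is None else int(a) for a in gt)
            sites.append(site)
            columns.append(column)
            last_end = site.ref_end
    hap_names = [f"{s}/{p}" for s in samples for p in (1, 2)]
    if columns:
        matrix = np.array(columns, dtype=np.int32).T
    else:
        matrix = np.zeros((len(hap_names), 0), dtype=np.int32)
    return HaplotypePanel(contig, sites, matrix, hap_names)


def apply_haplotype(reference: str, sites, alleles, with_map: bool = False):
    """Materialise one haplotype by applying site alleles to the reference.

    Returns the haplotype sequence, and when *with_map* is true also two
    arrays over haplotype positions: the reference position each base maps
    to and an in-insertion flag (for inserted bases the stored position is
    the number of reference bases strictly before them, i.e. the position
    of the next reference base).
    """
    parts = []
    ref_map = [] if with_map else None
    ins_map = [] if with_map else None
    cursor = 0
    for site, a in zip(sites, alleles):
        p = site.ref_position
        parts.append(reference[cursor:p])
        if with_map:
            ref_map.extend(range(cursor, p))
            ins_map.extend([False] * (p - cursor))
        allele = site.allele(int(a))
        ref_len = len(site.ref_allele)
        parts.append(allele)
        if with_map:
            for k in range(len(allele)):
                if k < ref_len:
                    ref_map.append(p + k)
                    ins_map.append(False)
                else:
                    ref_map.append(p + ref_len)
                    ins_map.append(True)
        cursor = p + ref_len
    parts.append(reference[cursor:])
    if with_map:
        ref_map.extend(range(cursor, len(reference)))
        ins_map.extend([False] * (len(reference) - cursor))
    seq = "".join(parts)
    if with_map:
        return seq, np.asarray(ref_map, dtype=np.int64), np.asarray(ins_map, dtype=bool)
    return seq
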