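import textwrap

import numpy as np
import pytest

from panproject.panel import HaplotypePanel, Site


@pytest.fixture
def write_vcf(tmp_path):
    """Write a minimal VCF from (pos1, ref, alts, genotypes) tuples."""

    def _write(records, samples=("S0",), contig="chrS", contig_len=1000,
               name="test.vcf"):
        path = tmp_path / name
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={contig},length={contig_len}>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples),
        ]
        for pos1, ref, alts, gts in records:
            lines.append(
                f"{contig}\t{pos1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def make_panel_from_rows(rows, n_alleles=2, contig="chrS", spacing=10):
    """Panel with synthetic SNP sites from a list of allele-index rows."""
    rows = np.asarray(rows, dtype=np.int32)
    n_sites = rows.shape[1]
    alts = tuple("CGT"[:n_alleles - 1])
    sites = [Site(spacing * (j + 1), "A", alts) for j in range(n_sites)]
    names = [f"h{i}" for i in range(rows.shape[0])]
    return HaplotypePanel(contig, sites, rows, names)
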