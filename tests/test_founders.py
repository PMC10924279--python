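"""Segmentation, founder reconstruction, MSA construction and serialization."""

import numpy as np
import pytest

from _oracles import haplotype_is_recombination, min_segment_count
from conftest import make_panel_from_rows
from panproject.founders import (
    founders_to_msa,
    minimum_segmentation,
    reconstruct_founders,
    write_founders,
)
from panproject.msa import read_aligned_fasta
from panproject.panel import HaplotypePanel, Site, apply_haplotype


class TestMinimumSegmentation:
    def test_identical_haplotypes_give_one_segment(self):
        panel = make_panel_from_rows([[0] * 6] * 4)
        seg = minimum_segmentation(panel, F=3, L=1)
        assert seg.boundaries == [0, 6]
        assert len(seg.segments[0].strings) == 1

    def test_capacity_forces_two_segments(self):
        # rows 00, 01, 11 over 2 sites: no single segment has <= 2 strings
        panel = make_panel_from_rows([[0, 0], [0, 1], [1, 1]])
        seg = minimum_segmentation(panel, F=3, L=1)
        assert seg.boundaries == [0, 1, 2]
        assert all(len(s.strings) == 2 for s in seg.segments)
        assert min_segment_count(panel.matrix, F=3, L=1) == 2

    def test_min_length_forces_collapse(self):
        panel = make_panel_from_rows([[0, 0], [0, 1], [1, 1]])
        seg = minimum_segmentation(panel, F=3, L=2)
        assert seg.boundaries == [0, 2]
        segment = seg.segments[0]
        # 3 distinct strings collapsed to the 2 most frequent (all tie at 1,
        # keep first occurrences 00 and 01); row 11 reassigned to 01 by
        # Hamming distance (1 vs 2)
        assert segment.strings == [(0, 0), (0, 1)]
        assert segment.assignment.tolist() == [0, 1, 1]

    def test_f_below_two_is_error(self):
        panel = make_panel_from_rows([[0, 1]])
        with pytest.raises(ValueError, match="F must be"):
            minimum_segmentation(panel, F=1, L=1)

    def test_short_trailing_segment_merges_into_predecessor(self):
        # 5 sites with L=2: greedy may not leave a 1-site tail
        rows = [[0, 0, 0, 0, 0], [1, 1, 0, 1, 1], [0, 1, 1, 1, 0]]
        panel = make_panel_from_rows(rows)
        seg = minimum_segmentation(panel, F=3, L=2)
        lengths = [hi - lo for lo, hi in zip(seg.boundaries, seg.boundaries[1:])]
        assert all(ln >= 2 for ln in lengths)

    @pytest.mark.parametrize("case", range(40))
    def test_greedy_within_one_segment_of_exhaustive_optimum(self, case):
        rng = np.random.default_rng(1000 + case)
        n_hap = int(rng.integers(2, 7))
        n_sites = int(rng.integers(2, 9))
        rows = rng.integers(0, 2, size=(n_hap, n_sites))
        F = int(rng.integers(2, 5))
        L = int(rng.integers(1, 3))
        panel = make_panel_from_rows(rows)
        seg = minimum_segmentation(panel, F=F, L=L)
        optimum = min_segment_count(panel.matrix, F, L)
        collapsed = any(
            len(set(map(tuple, rows[:, s.start:s.end]))) > len(s.strings)
            for s in seg.segments
        )
        if optimum is not None and not collapsed:
            assert len(seg.segments) <= optimum + 1


class TestReconstructFounders:
    def test_single_segment_keeps_strings_no_recombination(self):
        panel = make_panel_from_rows([[0, 0], [1, 1], [1, 1]])
        fs = reconstruct_founders(minimum_segmentation(panel, F=3, L=1))
        # ordered by support: 11 (2 haplotypes) before 00
        assert fs.allele_matrix.tolist() == [[1, 1], [0, 0]]
        assert fs.recombination_count == 0

    def test_joint_support_chains_across_boundary(self):
        # h1,h2 carry A1B1; h3 carries A2B2 -> chains with no recombination
        panel = make_panel_from_rows([[0, 0], [0, 0], [1, 1]])
        seg = minimum_segmentation(panel, F=3, L=1)
        fs = reconstruct_founders(seg)
        assert fs.recombination_count == 0
        assert fs.allele_matrix.tolist() == [[0, 0], [1, 1]]

    def test_crossing_supports_prefer_supported_pairs(self):
        # h1: A1B2, h2: A2B1 -- matching by joint support chains 0->1, 1->0
        panel = make_panel_from_rows([[0, 1], [1, 0]])
        seg = minimum_segmentation(panel, F=3, L=1)
        fs = reconstruct_founders(seg)
        assert fs.recombination_count == 0
        founders = {tuple(row) for row in fs.allele_matrix.tolist()}
        assert founders == {(0, 1), (1, 0)}

    def test_reference_fill_when_segment_has_fewer_strings(self):
        rows = [[0, 0], [1, 0]]  # second site is monomorphic
        panel = make_panel_from_rows(rows)
        seg = minimum_segmentation(panel, F=4, L=1)
        fs = reconstruct_founders(seg)
        assert fs.n_founders == 2
        for hap in rows:
            assert haplotype_is_recombination(hap, fs)

    @pytest.mark.parametrize("case", range(30))
    def test_recombination_property_random_panels(self, case):
        rng = np.random.default_rng(2000 + case)
        n_hap = int(rng.integers(2, 9))
        n_sites = int(rng.integers(1, 40))
        rows = rng.integers(0, 2, size=(n_hap, n_sites))
        panel = make_panel_from_rows(rows)
        F = int(rng.integers(3, 6))
        seg = minimum_segmentation(panel, F=F, L=1)
        fs = reconstruct_founders(seg)
        assert fs.n_founders <= F - 1
        for hap in rows:
            assert haplotype_is_recombination(hap, fs)


REF = "AAAAACAAAAGAAAAT" * 2  # 32 bp scratch reference


class TestFoundersToMsa:
    def _fs(self, sites, rows, F=3, L=1):
        panel = HaplotypePanel("chrS", sites, np.asarray(rows, dtype=np.int32),
                               [f"h{i}" for i in range(len(rows))])
        seg = minimum_segmentation(panel, F=F, L=L)
        return panel, reconstruct_founders(seg)

    def test_snp_only_msa_is_gap_free(self):
        sites = [Site(5, "C", ("G",)), Site(10, "G", ("T",))]
        panel, fs = self._fs(sites, [[0, 0], [1, 1]])
        msa = founders_to_msa(fs, panel, REF)
        assert all("-" not in row for row in msa.rows.values())
        assert all(len(row) == len(REF) for row in msa.rows.values())
        assert msa.ungapped("chrS") == REF

    def test_insertion_pads_reference_row(self):
        sites = [Site(5, "C", ("CTT",))]
        panel, fs = self._fs(sites, [[0], [1]])
        msa = founders_to_msa(fs, panel, REF)
        ref_row = msa.rows["chrS"]
        assert "C--" in ref_row
        assert msa.ungapped("chrS") == REF
        carrier = next(
            name for name in msa.founder_names() if "CTT" in msa.rows[name]
        )
        assert msa.ungapped(carrier) == REF[:5] + "CTT" + REF[6:]

    def test_deletion_pads_founder_row(self):
        sites = [Site(10, "GAA", ("G",))]
        panel, fs = self._fs(sites, [[0], [1]])
        msa = founders_to_msa(fs, panel, REF)
        assert msa.ungapped("chrS") == REF
        carrier = next(
            name for name in msa.founder_names() if "G--" in msa.rows[name]
        )
        assert msa.ungapped(carrier) == REF[:11] + REF[13:]

    def test_founder_rows_ungap_to_founder_sequences(self):
        sites = [Site(2, "A", ("T",)), Site(5, "C", ("CTT",)), Site(10, "GAA", ("G",))]
        rows = [[0, 1, 0], [1, 0, 1], [1, 1, 1], [0, 0, 0]]
        panel, fs = self._fs(sites, rows, F=5)
        msa = founders_to_msa(fs, panel, REF)
        for k, name in enumerate(fs.founder_names()):
            expected = apply_haplotype(REF, sites, fs.allele_matrix[k])
            assert msa.ungapped(name) == expected


class TestWriteFounders:
    def test_round_trip_and_record_names(self, tmp_path):
        sites = [Site(5, "C", ("CT",)), Site(10, "G", ("T",))]
        panel = HaplotypePanel("chrS", sites, np.array([[0, 0], [1, 1]]),
                               ["h0", "h1"])
        seg = minimum_segmentation(panel, F=3, L=1)
        fs = reconstruct_founders(seg)
        msa = founders_to_msa(fs, panel, REF)
        paths = write_founders(fs, msa, tmp_path / "out")
        again = read_aligned_fasta(paths["msa_fasta"], "chrS")
        assert again.rows == msa.rows
        text = open(paths["founders_fasta"]).read()
        assert ">founder-1" in text and ">chrS" in text
        provenance = open(paths["provenance"]).read()
        assert "founder-1" in provenance

    def test_unequal_rows_refuse_to_write(self, tmp_path):
        from panproject.msa import ReferenceGuidedMSA

        msa = ReferenceGuidedMSA(reference_name="r", rows={"r": "ACGT", "f": "ACGT"})
        msa.rows["f"] = "ACG"  # corrupt after construction
        panel = HaplotypePanel("chrS", [Site(5, "C", ("T",))],
                               np.array([[0], [1]]), ["h0", "h1"])
        fs = reconstruct_founders(minimum_segmentation(panel, F=3, L=1))
        with pytest.raises(ValueError, match="unequal"):
            write_founders(fs, msa, tmp_path / "bad")
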