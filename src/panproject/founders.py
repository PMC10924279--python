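"""Founder sequence generation from a phased haplotype panel.

Founder sequences compress a haplotype panel into a handful of mosaic
sequences such that every panel haplotype can be read as a recombination of
founders, switching only at segment boundaries. Reads are then aligned to
the founders (plus the reference) instead of to every haplotype, keeping
the aligner index small while still representing the known variation.

The pipeline is: greedy minimum segmentation of the site matrix under a
founder budget ``F`` (which counts the reference, so the panel contributes
at most ``F - 1`` founders) and a minimum segment length ``L`` (in variant
sites) -> chaining of per-segment haplotype strings across boundaries by
joint support, minimising discontinuation positions -> materialisation as
ungapped FASTA plus a reference-guided MSA for coordinate projection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .msa import GAP, ReferenceGuidedMSA, write_aligned_fasta, write_fasta_sequences
from .panel import HaplotypePanel, apply_haplotype


@dataclass
class Segment:
    """Half-open site range with its retained distinct allele strings.

    ``strings`` are tuples of allele indices over the segment's sites,
    ordered by first occurrence; ``support`` holds the haplotype indices
    assigned to each string (including haplotypes reassigned during an
    over-capacity collapse); ``assignment`` maps haplotype -> string index.
    """

    start: int
    end: int
    strings: list
    support: list
    assignment: np.ndarray


@dataclass
class Segmentation:
    panel: HaplotypePanel
    boundaries: list  # site indices, [0, b1, ..., n_sites]
    segments: list
    F: int
    L: int

    def validate(self) -> None:
        n = self.panel.n_sites
        if self.boundaries[0] != 0 or self.boundaries[-1] != n:
            raise ValueError("segment boundaries must partition all sites")
        for seg, lo, hi in zip(self.segments, self.boundaries, self.boundaries[1:]):
            if (seg.start, seg.end) != (lo, hi):
                raise ValueError("segment ranges inconsistent with boundaries")
            if len(seg.strings) > self.F - 1:
                raise ValueError("segment exceeds founder capacity")
        for seg in self.segments[:-1]:
            if seg.end - seg.start < self.L:
                raise ValueError("non-terminal segment shorter than L")


@dataclass
class FounderSet:
    """Founders as allele strings over the panel's sites, with provenance.

    ``allele_matrix`` has one row per founder; ``sources`` gives, per
    founder and segment, the retained-string index it was chained from
    (``None`` for reference-filled slots) and the supporting haplotypes.
    ``recombination_count`` is the number of (founder, boundary) pairs whose
    consecutive segment strings were never jointly carried by a haplotype.
    """

    segmentation: Segmentation
    allele_matrix: np.ndarray  # (n_founders, n_sites)
    sources: list  # per founder: list over segments of (string_idx | None, frozenset)
    recombination_count: int
    F: int
    L: int

    @property
    def n_founders(self) -> int:
        return self.allele_matrix.shape[0]

    def founder_names(self):
        return [f"founder-{k + 1}" for k in range(self.n_founders)]

    def founder_sequence(self, k: int, reference: str) -> str:
        """Ungapped sequence of founder *k* over the panel's contig."""
        return apply_haplotype(reference, self.segmentation.panel.sites,
                               self.allele_matrix[k])


def _distinct_strings(matrix: np.ndarray, start: int, end: int):
    """Distinct haplotype strings over sites [start, end), first-occurrence order."""
    strings = []
    index = {}
    assignment = np.empty(matrix.shape[0], dtype=np.int32)
    for h in range(matrix.shape[0]):
        s = tuple(int(a) for a in matrix[h, start:end])
        if s not in index:
            index[s] = len(strings)
            strings.append(s)
        assignment[h] = index[s]
    return strings, assignment


def _collapse(strings, assignment, capacity: int) -> Segment:
    """Retain the ``capacity`` most frequent strings; reassign the rest.

    Frequency ties break toward the lower (earlier-occurring) string index;
    evicted haplotypes move to the retained string with minimum Hamming
    distance over the segment's allele indices (ties -> lower string index).
    """
    counts = np.bincount(assignment, minlength=len(strings))
    order = sorted(range(len(strings)), key=lambda i: (-counts[i], i))
    retained_old = sorted(order[:capacity])  # keep first-occurrence order
    remap = {old: new for new, old in enumerate(retained_old)}
    new_assignment = np.empty_like(assignment)
    for h, old in enumerate(assignment):
        if old in remap:
            new_assignment[h] = remap[old]
        else:
            dists = [
                sum(a != b for a, b in zip(strings[old], strings[r]))
                for r in retained_old
            ]
            new_assignment[h] = int(np.argmin(dists))  # ties -> lower index
    new_strings = [strings[old] for old in retained_old]
    support = [set(np.flatnonzero(new_assignment == i)) for i in range(len(new_strings))]
    return new_strings, new_assignment, support


def _make_segment(matrix, start, end, capacity) -> Segment:
    strings, assignment = _distinct_strings(matrix, start, end)
    if len(strings) > capacity:
        strings, assignment, support = _collapse(strings, assignment, capacity)
    else:
        support = [set(np.flatnonzero(assignment == i)) for i in range(len(strings))]
    return Segment(start, end, strings, support, assignment)


def minimum_segmentation(panel: HaplotypePanel, F: int, L: int) -> Segmentation:
    """Greedy left-to-right segmentation of the panel under capacity F-1.

    Each segment is extended site by site and closed at the earliest
    position where it spans >= L sites and taking the next site would push
    the number of distinct haplotype strings above ``F - 1``. Segments that
    are forced above capacity by ``L`` are collapsed (frequency + Hamming
    reassignment); a trailing segment shorter than ``L`` is merged into its
    predecessor when one exists.
    """
    if F < 2:
        raise ValueError("F must be >= 2 (it counts the reference sequence)")
    if L < 1:
        raise ValueError("L must be >= 1")
    if panel.n_sites == 0 or panel.n_haplotypes == 0:
        raise ValueError("panel must contain at least one site and one haplotype")
    capacity = F - 1
    matrix = panel.matrix
    n = panel.n_sites
    boundaries = [0]
    start = 0
    while start < n:
        # per-haplotype allele prefixes over [start, i)
        prefixes = [tuple() for _ in range(matrix.shape[0])]
        i = start
        while True:
            prefixes = [p + (int(matrix[h, i]),) for h, p in enumerate(prefixes)]
            i += 1
            if i == n:
                break
            if i - start >= L:
                count = len(set(prefixes))
                if count > capacity:
                    break  # forced over capacity by L; close and collapse
                extended = {p + (int(matrix[h, i]),) for h, p in enumerate(prefixes)}
                if len(extended) > capacity:
                    break
        boundaries.append(i)
        start = i
    # merge a short trailing segment into its predecessor
    if len(boundaries) > 2 and boundaries[-1] - boundaries[-2] < L:
        del boundaries[-2]
    segments = [
        _make_segment(matrix, lo, hi, capacity)
        for lo, hi in zip(boundaries, boundaries[1:])
    ]
    seg = Segmentation(panel, boundaries, segments, F, L)
    seg.validate()
    return seg


def _order_by_support(segment: Segment):
    """String indices ordered by descending support, ties -> first occurrence."""
    return sorted(range(len(segment.strings)),
                  key=lambda i: (-len(segment.support[i]), i))


def reconstruct_founders(seg: Segmentation) -> FounderSet:
    """Chain per-segment strings across boundaries into founder sequences.

    Within each segment strings are ordered by descending support; across
    each consecutive pair of segments, strings are matched greedily by
    descending joint-support count (ties -> lexicographically lower index
    pair). Matched pairs with zero joint support each contribute one
    discontinuation position to ``recombination_count``. Segments with
    fewer distinct strings than founders are padded with reference-allele
    slots (empty support).
    """
    panel = seg.panel
    n_founders = max(len(s.strings) for s in seg.segments)
    ref_fill = object()  # sentinel slot

    # slots per segment: ordered retained string indices, then fills
    slot_lists = []
    for segment in seg.segments:
        slots = _order_by_support(segment)
        slots += [ref_fill] * (n_founders - len(slots))
        slot_lists.append(slots)

    def slot_support(segment, slot):
        if slot is ref_fill:
            return frozenset()
        return frozenset(segment.support[slot])

    # chains[k] = list of slots, one per segment
    chains = [[slot] for slot in slot_lists[0]]
    recombinations = 0
    for s in range(1, len(seg.segments)):
        left_seg, right_seg = seg.segments[s - 1], seg.segments[s]
        left_slots = [chain[-1] for chain in chains]
        right_slots = slot_lists[s]
        pairs = []
        for i, ls in enumerate(left_slots):
            lsup = slot_support(left_seg, ls)
            for j, rs in enumerate(right_slots):
                joint = len(lsup & slot_support(right_seg, rs))
                pairs.append((-joint, i, j))
        pairs.sort()
        used_left, used_right = set(), set()
        for neg_joint, i, j in pairs:
            if i in used_left or j in used_right:
                continue
            used_left.add(i)
            used_right.add(j)
            chains[i].append(right_slots[j])
            if -neg_joint == 0:
                recombinations += 1

    allele_matrix = np.zeros((n_founders, panel.n_sites), dtype=np.int32)
    sources = []
    for k, chain in enumerate(chains):
        founder_sources = []
        for segment, slot in zip(seg.segments, chain):
            if slot is ref_fill:
                founder_sources.append((None, frozenset()))
                continue  # allele_matrix already 0 (reference)
            allele_matrix[k, segment.start:segment.end] = segment.strings[slot]
            founder_sources.append((slot, frozenset(segment.support[slot])))
        sources.append(founder_sources)

    return FounderSet(seg, allele_matrix, sources, recombinations, seg.F, seg.L)


def founders_to_msa(
    fs: FounderSet,
    panel: HaplotypePanel,
    reference: str,
    reference_name: Optional[str] = None,
) -> ReferenceGuidedMSA:
    """Build the reference-guided MSA of reference + founder sequences.

    Each variant site contributes a column block as wide as the longest
    allele among the REF allele and the alleles any founder uses there;
    alleles are left-aligned and right-padded with gaps. Reference
    stretches between sites are copied gap-free into every row.
    """
    if reference_name is None:
        reference_name = panel.contig_name
    n_founders = fs.n_founders
    rows = [[] for _ in range(n_founders + 1)]  # 0 = reference
    cursor = 0
    for j, site in enumerate(panel.sites):
        p = site.ref_position
        between = reference[cursor:p].upper()
        for row in rows:
            row.append(between)
        used = {site.ref_allele} | {
            site.allele(int(fs.allele_matrix[k, j])) for k in range(n_founders)
        }
        width = max(len(a) for a in used)
        rows[0].append(site.ref_allele.ljust(width, GAP))
        for k in range(n_founders):
            allele = site.allele(int(fs.allele_matrix[k, j]))
            rows[k + 1].append(allele.ljust(width, GAP))
        cursor = site.ref_end
    tail = reference[cursor:].upper()
    for row in rows:
        row.append(tail)
    names = [reference_name] + fs.founder_names()
    return ReferenceGuidedMSA(
        reference_name=reference_name,
        rows={name: "".join(row) for name, row in zip(names, rows)},
    )


def write_founders(fs: FounderSet, msa: ReferenceGuidedMSA, out_prefix) -> dict:
    """Write the founder artefacts; returns a name -> path mapping.

    ``<prefix>.founders.fa``   unaligned reference + founders (for indexing)
    ``<prefix>.msa.fa``        the aligned FASTA of the MSA
    ``<prefix>.provenance.tsv`` founder, segment, source haplotypes
    """
    msa.validate()
    prefix = str(out_prefix)
    paths = {
        "founders_fasta": prefix + ".founders.fa",
        "msa_fasta": prefix + ".msa.fa",
        "provenance": prefix + ".provenance.tsv",
    }
    write_fasta_sequences(
        [(name, msa.ungapped(name)) for name in msa.rows], paths["founders_fasta"]
    )
    write_aligned_fasta(msa, paths["msa_fasta"])
    hap_names = fs.segmentation.panel.haplotype_names
    try:
        with open(paths["provenance"], "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["founder", "segment", "site_start", "site_end", "source_haplotypes"]
            )
            for k, founder_sources in enumerate(fs.sources):
                for s, (slot, support) in enumerate(founder_sources):
                    segment = fs.segmentation.segments[s]
                    names = (
                        ",".join(sorted(hap_names[h] for h in support))
                        if support else "reference"
                    )
                    writer.writerow(
                        [fs.founder_names()[k], s, segment.start, segment.end, names]
                    )
    except OSError as exc:
        raise OSError(f"failed writing {paths['provenance']}: {exc}") from exc
    return paths
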