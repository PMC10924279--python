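"""SAM/BAM plumbing via pysam: record conversion, grouping, mate fix-up."""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import pysam

from .records import (
    AlignmentRecord,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    cigar_to_string,
    parse_cigar,
)

# pysam cigar op codes -> characters
_OP_CHARS = "MIDNSHP=XB"


def from_pysam(aln: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = []
    if aln.cigartuples:
        cigar = [(_OP_CHARS[code], ln) for code, ln in aln.cigartuples]
    return AlignmentRecord(
        read_id=aln.query_name,
        target_name=aln.reference_name if not aln.is_unmapped else None,
        leftmost=aln.reference_start if not aln.is_unmapped else -1,
        cigar=cigar,
        mapq=aln.mapping_quality,
        flag=aln.flag,
        seq=aln.query_sequence or "",
        quals=tuple(aln.query_qualities) if aln.query_qualities is not None else None,
        tags=dict(aln.get_tags()),
        next_target_name=(
            aln.next_reference_name if aln.next_reference_id >= 0 else None
        ),
        next_leftmost=aln.next_reference_start,
        tlen=aln.template_length,
    )


def to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment(header)
    aln.query_name = rec.read_id
    aln.flag = rec.flag
    if not rec.is_unmapped and rec.target_name is not None:
        aln.reference_id = header.get_tid(rec.target_name)
        aln.reference_start = rec.leftmost
        aln.cigarstring = cigar_to_string(rec.cigar) if rec.cigar else None
    else:
        aln.reference_id = -1
        aln.reference_start = -1
    aln.mapping_quality = rec.mapq
    if rec.next_target_name is not None:
        aln.next_reference_id = header.get_tid(rec.next_target_name)
        aln.next_reference_start = rec.next_leftmost
    aln.template_length = rec.tlen
    aln.query_sequence = rec.seq or None
    if rec.quals is not None:
        aln.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in rec.quals)
        )
    for key, value in rec.tags.items():
        aln.set_tag(key, value)
    return aln


def read_alignments(path):
    """Read SAM/BAM into (header, list of AlignmentRecord)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        header = fh.header.to_dict()
        records = [from_pysam(aln) for aln in fh.fetch(until_eof=True)]
    return header, records


def make_header(reference_names, reference_lengths, program_args: Optional[str] = None):
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in zip(reference_names, reference_lengths)
        ],
    }
    if program_args is not None:
        header["PG"] = [{"ID": "panproject", "PN": "panproject", "CL": program_args}]
    return header


def write_alignments(path, records: Iterable, header: dict) -> None:
    mode = "wb" if str(path).endswith(".bam") else "w"
    pysam_header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(str(path), mode, header=pysam_header) as fh:
        for rec in records:
            fh.write(to_pysam(rec, pysam_header))


def group_by_read(records: Iterable) -> Iterator:
    """Yield lists of consecutive records sharing a read id.

    Requires name-grouped (collated or name-sorted) input: a read id
    reappearing after a different one is a hard error, since grouping a
    coordinate-sorted file this way would silently split reads.
    """
    seen = set()
    group = []
    for rec in records:
        if group and rec.read_id != group[0].read_id:
            if rec.read_id in seen:
                raise ValueError(
                    f"read {rec.read_id} reappears after other reads; input "
                    "must be name-grouped (collate or sort by name first)"
                )
            seen.add(group[0].read_id)
            yield group
            group = []
        group.append(rec)
    if group:
        yield group


def fix_mate_info(group) -> None:
    """Recompute mate position fields for one read's projected records.

    Applies to the primary records of a proper pair; mates were projected
    independently, so RNEXT/PNEXT/TLEN are recomputed here.
    """
    primaries = [r for r in group if r.is_paired and not r.is_secondary
                 and not r.is_supplementary]
    if len(primaries) != 2:
        return
    a, b = primaries
    for rec, mate in ((a, b), (b, a)):
        rec.tags.pop("MC", None)
        rec.set_flag(FLAG_MATE_UNMAPPED, mate.is_unmapped)
        rec.set_flag(FLAG_MATE_REVERSE, mate.is_reverse)
        rec.next_target_name = mate.target_name
        rec.next_leftmost = mate.leftmost
    if (not a.is_unmapped and not b.is_unmapped
            and a.target_name == b.target_name):
        left = min(a.leftmost, b.leftmost)
        right = max(a.reference_end, b.reference_end)
        tlen = right - left
        a.tlen = tlen if a.leftmost <= b.leftmost else -tlen
        b.tlen = -a.tlen
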