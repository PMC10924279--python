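"""Coordinate projection of alignments from founder to reference space.

A :class:`ProjectionIndex` is built from the reference-guided MSA with a
single left-to-right column walk: for every ungapped founder position it
stores the corresponding 0-based reference position and whether the column
is an insertion relative to the reference (in which case the stored
position is the number of reference bases strictly before the column).

``project_edit_script`` rewrites a read-vs-founder edit script into a
read-vs-reference script by composing it with the founder-vs-reference gap
structure, in time linear in the operation count plus the columns spanned:

* founder bases aligned by M/=/X that fall in insertion columns become I;
* reference bases skipped by gaps in the founder row become D;
* read insertions stay I; read deletions over insertion columns are elided
  (they consume neither read nor reference), over reference-mapped founder
  bases they stay D;
* soft/hard clips are preserved at the ends.

``normalize_projected`` then pairs adjacent I/D runs into M, merges runs,
and converts terminal insertions into soft clips (SAM cannot anchor an
alignment on an insertion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .msa import GAP, ReferenceGuidedMSA
from .records import (
    ALIGN_OPS,
    AlignmentRecord,
    Cigar,
    FLAG_UNMAPPED,
    compute_nm_md,
    merge_runs,
    query_length,
)


@dataclass
class ProjectionIndex:
    """Per-founder map from ungapped founder position to reference position."""

    founder_name: str
    reference_name: str
    ref_pos: np.ndarray      # int64, one entry per founder base
    in_insertion: np.ndarray  # bool, same length
    ref_length: int

    def __post_init__(self):
        self.ref_pos = np.asarray(self.ref_pos, dtype=np.int64)
        self.in_insertion = np.asarray(self.in_insertion, dtype=bool)
        if self.ref_pos.shape != self.in_insertion.shape:
            raise ValueError("ref_pos and in_insertion must have equal length")
        if len(self.ref_pos) and (
            np.any(np.diff(self.ref_pos) < 0)
            or self.ref_pos[0] < 0
            or self.ref_pos[-1] > self.ref_length
        ):
            raise ValueError("projection entries must be non-decreasing within range")

    @property
    def founder_length(self) -> int:
        return len(self.ref_pos)


def build_projection_index(msa: ReferenceGuidedMSA, founder_name: str) -> ProjectionIndex:
    """Single column walk over the MSA; O(number of columns)."""
    if founder_name not in msa.rows:
        raise KeyError(f"unknown founder row {founder_name!r}")
    if founder_name == msa.reference_name:
        raise ValueError("founder_name must be a non-reference row")
    ref_row = msa.rows[msa.reference_name]
    founder_row = msa.rows[founder_name]
    ref_pos = []
    in_ins = []
    ref_count = 0
    for rc, fc in zip(ref_row, founder_row):
        if fc != GAP:
            ref_pos.append(ref_count)
            in_ins.append(rc == GAP)
        if rc != GAP:
            ref_count += 1
    return ProjectionIndex(
        founder_name=founder_name,
        reference_name=msa.reference_name,
        ref_pos=np.array(ref_pos, dtype=np.int64),
        in_insertion=np.array(in_ins, dtype=bool),
        ref_length=ref_count,
    )


def identity_index(name: str, reference_name: str, length: int) -> ProjectionIndex:
    """Index for a founder identical to the reference (gap-free rows)."""
    return ProjectionIndex(
        founder_name=name,
        reference_name=reference_name,
        ref_pos=np.arange(length, dtype=np.int64),
        in_insertion=np.zeros(length, dtype=bool),
        ref_length=length,
    )


def project_position(index: ProjectionIndex, f_pos: int):
    """Constant-time lookup: founder position -> (ref_pos, in_insertion)."""
    if not 0 <= f_pos < index.founder_length:
        raise IndexError(
            f"founder position {f_pos} out of range [0, {index.founder_length})"
        )
    return int(index.ref_pos[f_pos]), bool(index.in_insertion[f_pos])


def project_edit_script(script: Cigar, index: ProjectionIndex, founder_leftmost: int):
    """Rewrite a read-vs-founder script into reference coordinates.

    Returns ``(ref_leftmost, projected_script)``; ``ref_leftmost`` is None
    when the alignment covers no reference base at all (it lies wholly
    within a founder insertion). The output is run-length merged but not
    yet normalized (see :func:`normalize_projected`).
    """
    if founder_leftmost < 0:
        raise ValueError("founder leftmost must be non-negative")
    ref_pos = index.ref_pos
    in_ins = index.in_insertion
    n = index.founder_length
    out = []
    f = founder_leftmost
    ref_left: Optional[int] = None
    last_ref_end: Optional[int] = None

    def emit(op, ln=1):
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])

    def flush_to(rp):
        # reference bases skipped by founder-row gaps, in column order
        nonlocal last_ref_end
        if last_ref_end is not None and rp > last_ref_end:
            emit("D", rp - last_ref_end)
            last_ref_end = rp

    for op, ln in script:
        if op in ("S", "H"):
            emit(op, ln)
        elif op == "I":
            emit("I", ln)
        elif op == "P":
            continue
        elif op in ALIGN_OPS:
            if f + ln > n:
                raise ValueError("alignment overruns the founder sequence")
            for _ in range(ln):
                rp = int(ref_pos[f])
                if in_ins[f]:
                    flush_to(rp)
                    emit("I")
                else:
                    if last_ref_end is None:
                        ref_left = rp
                    else:
                        flush_to(rp)
                    emit(op)
                    last_ref_end = rp + 1
                f += 1
        elif op in ("D", "N"):
            if f + ln > n:
                raise ValueError("alignment overruns the founder sequence")
            for _ in range(ln):
                rp = int(ref_pos[f])
                if in_ins[f]:
                    flush_to(rp)  # elide the inserted base itself
                elif last_ref_end is not None:
                    flush_to(rp)
                    emit(op if op == "N" else "D")
                    last_ref_end = rp + 1
                # a deletion before any anchored base just shifts leftmost
                f += 1
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")

    # deletions outside the outermost aligned bases carry no information
    # after projection (SAM cannot anchor on them): drop D/N runs after the
    # last M/=/X (those before the first are never emitted above)
    last_align = max(
        (i for i, (op, _) in enumerate(out) if op in ALIGN_OPS), default=-1
    )
    out = [x for i, x in enumerate(out) if not (i > last_align and x[0] in ("D", "N"))]
    return ref_left, merge_runs([tuple(x) for x in out])


def normalize_projected(
    script: Cigar,
    read: Optional[str] = None,
    reference: Optional[str] = None,
    ref_leftmost: Optional[int] = None,
    extended: bool = False,
) -> Cigar:
    """Normalize a projected edit script (idempotent).

    1. adjacent I/D (or D/I) runs are paired base-for-base into M up to the
       shorter length, remainders kept in place;
    2. adjacent same-type runs are merged;
    3. leading/trailing insertions become soft clips;
    4. optionally (``extended`` with *reference*), M runs are re-split into
       =/X by base comparison.
    """
    ops = merge_runs(script)
    changed = True
    while changed:
        changed = False
        out = []
        for op, ln in ops:
            if out and {out[-1][0], op} == {"I", "D"}:
                prev_op, prev_ln = out.pop()
                m = min(prev_ln, ln)
                if prev_ln > m:
                    out.append((prev_op, prev_ln - m))
                out.append(("M", m))
                if ln > m:
                    out.append((op, ln - m))
                changed = True
            else:
                out.append((op, ln))
        ops = merge_runs(out)

    # terminal insertions -> soft clips (merge into an existing clip)
    def soft_clip_end(ops, head: bool):
        seq = ops if head else ops[::-1]
        i = 0
        while i < len(seq) and seq[i][0] in ("H", "S"):
            i += 1
        if i < len(seq) and seq[i][0] == "I":
            seq[i] = ("S", seq[i][1])
        return merge_runs(seq if head else seq[::-1])

    ops = soft_clip_end(ops, head=True)
    ops = soft_clip_end(ops, head=False)

    if extended and reference is not None and read is not None and ref_leftmost is not None:
        ops = _split_matches(ops, read, reference, ref_leftmost)
    return ops


def _split_matches(ops: Cigar, read: str, reference: str, ref_leftmost: int) -> Cigar:
    out = []
    q = 0
    r = ref_leftmost
    for op, ln in ops:
        if op == "M":
            for _ in range(ln):
                sym = "=" if read[q].upper() == reference[r].upper() else "X"
                out.append((sym, 1))
                q += 1
                r += 1
        else:
            out.append((op, ln))
            if op in ("=", "X", "I", "S"):
                q += ln
            if op in ("=", "X", "D", "N"):
                r += ln
    return merge_runs(out)


def project_alignment(
    rec: AlignmentRecord,
    index: ProjectionIndex,
    reference: Optional[str] = None,
    extended: bool = False,
) -> AlignmentRecord:
    """Project one alignment record from founder to reference coordinates.

    The target is renamed to the reference; position and edit script are
    projected and normalized. An alignment lying wholly within a founder
    insertion is returned flagged unmapped (the read is kept, preserving
    read accounting). NM/MD are recomputed when *reference* is given,
    dropped otherwise; AS/XS are preserved.
    """
    if rec.is_unmapped:
        raise ValueError(f"record {rec.read_id} is unmapped")
    if rec.target_name != index.founder_name:
        raise ValueError(
            f"record targets {rec.target_name!r} but index is for {index.founder_name!r}"
        )
    ref_left, raw = project_edit_script(rec.cigar, index, rec.leftmost)
    out = rec.copy(target_name=index.reference_name)
    if ref_left is None:
        out.set_flag(FLAG_UNMAPPED, True)
        out.leftmost = -1
        out.cigar = []
        out.mapq = 0
        out.tags.pop("NM", None)
        out.tags.pop("MD", None)
        return out
    cigar = normalize_projected(raw, read=rec.seq, reference=reference,
                                ref_leftmost=ref_left, extended=extended)
    if rec.seq and query_length(cigar) != len(rec.seq):
        raise AssertionError(
            f"projection broke query-length conservation for {rec.read_id}"
        )
    out.leftmost = ref_left
    out.cigar = cigar
    if reference is not None:
        nm, md = compute_nm_md(cigar, rec.seq, reference, ref_left)
        out.tags["NM"] = nm
        out.tags["MD"] = md
    else:
        out.tags.pop("NM", None)
        out.tags.pop("MD", None)
    return out
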