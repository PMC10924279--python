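"""SAM-style alignment records and CIGAR (edit-script) utilities.

Edit scripts are run-length encoded lists of ``(op, length)`` pairs using the
SAM operation alphabet: ``M`` (align, match or mismatch), ``=`` (match),
``X`` (mismatch), ``I`` (insertion to the reference), ``D`` (deletion from
the reference), ``S``/``H`` (soft/hard clip), ``N`` (reference skip) and
``P`` (padding). All coordinates are 0-based half-open; conversion to SAM's
1-based POS happens only at serialisation time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

CIGAR_OPS = "M=XIDSHNP"
QUERY_CONSUMING = frozenset("M=XIS")
REF_CONSUMING = frozenset("M=XDN")
ALIGN_OPS = frozenset("M=X")

Cigar = list  # list[tuple[str, int]]

_CIGAR_RE = re.compile(r"(\d+)([M=XIDSHNP])")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


def parse_cigar(text: str) -> Cigar:
    """Parse a CIGAR string into ``[(op, length), ...]``."""
    if text in ("", "*"):
        return []
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR string: {text!r}")
        out.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed CIGAR string: {text!r}")
    return out


def cigar_to_string(cigar: Cigar) -> str:
    if not cigar:
        return "*"
    return "".join(f"{ln}{op}" for op, ln in cigar)


def query_length(cigar: Cigar) -> int:
    """Number of read bases consumed by the script (M,=,X,I,S)."""
    return sum(ln for op, ln in cigar if op in QUERY_CONSUMING)


def reference_length(cigar: Cigar) -> int:
    """Number of reference bases consumed by the script (M,=,X,D,N)."""
    return sum(ln for op, ln in cigar if op in REF_CONSUMING)


def merge_runs(cigar: Iterable) -> Cigar:
    """Drop zero-length runs and merge adjacent runs of the same operation."""
    out: Cigar = []
    for op, ln in cigar:
        if ln == 0:
            continue
        if ln < 0:
            raise ValueError(f"negative CIGAR run length: {ln}{op}")
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def validate_cigar(cigar: Cigar, read_length: Optional[int] = None) -> None:
    """Check the structural invariants of an edit script.

    Lengths positive; ``H`` only outermost, ``S`` inside ``H`` only; if
    *read_length* is given, query-consuming lengths must sum to it.
    """
    for op, ln in cigar:
        if op not in CIGAR_OPS:
            raise ValueError(f"unknown CIGAR op {op!r}")
        if ln < 1:
            raise ValueError(f"non-positive CIGAR run {ln}{op}")
    ops = [op for op, _ in cigar]
    for i, op in enumerate(ops):
        if op == "H" and i not in (0, len(ops) - 1):
            raise ValueError("H permitted only as the outermost operation")
        if op == "S":
            before = set(ops[:i]) - {"H"}
            after = set(ops[i + 1:]) - {"H"}
            if (before and not after) or (after and not before):
                continue  # terminal soft clip (possibly inside H)
            if before and after:
                raise ValueError("S permitted only adjacent to the ends")
    if read_length is not None and cigar:
        q = query_length(cigar)
        if q != read_length:
            raise ValueError(
                f"CIGAR consumes {q} query bases but read length is {read_length}"
            )


@dataclass
class AlignmentRecord:
    """One read alignment in (projected or unprojected) coordinates.

    ``leftmost`` is a 0-based reference coordinate (-1 when unmapped).
    ``quals`` are Phred scores; ``None`` means unavailable ('*' in SAM).
    """

    read_id: str
    target_name: Optional[str]
    leftmost: int
    cigar: Cigar
    mapq: int = 0
    flag: int = 0
    seq: str = ""
    quals: Optional[tuple] = None
    tags: dict = field(default_factory=dict)
    # mate fields (paired-end plumbing; recomputed after projection)
    next_target_name: Optional[str] = None
    next_leftmost: int = -1
    tlen: int = 0

    # -- flag accessors -------------------------------------------------
    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    def set_flag(self, bit: int, value: bool) -> None:
        if value:
            self.flag |= bit
        else:
            self.flag &= ~bit

    # -- geometry -------------------------------------------------------
    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the target."""
        return self.leftmost + reference_length(self.cigar)

    def validate(self) -> None:
        if not self.is_unmapped:
            if self.target_name is None or self.leftmost < 0:
                raise ValueError(f"mapped record {self.read_id} lacks coordinates")
            validate_cigar(self.cigar, len(self.seq) if self.seq else None)
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"MAPQ out of range: {self.mapq}")
        if self.quals is not None and self.seq and len(self.quals) != len(self.seq):
            raise ValueError("quality string length differs from sequence length")

    def copy(self, **changes) -> "AlignmentRecord":
        rec = replace(self, cigar=list(self.cigar), tags=dict(self.tags))
        for k, v in changes.items():
            setattr(rec, k, v)
        return rec


def compute_nm_md(cigar: Cigar, seq: str, reference: str, leftmost: int):
    """Recompute the ``NM`` edit distance and ``MD`` string from scratch.

    *reference* is the full target sequence; mismatch detection compares the
    read to it base by base over M/=/X runs.
    """
    nm = 0
    md_parts = []
    match_run = 0
    q = 0
    r = leftmost
    for op, ln in cigar:
        if op in ALIGN_OPS:
            for _ in range(ln):
                if seq[q].upper() == reference[r].upper():
                    match_run += 1
                else:
                    md_parts.append(str(match_run))
                    md_parts.append(reference[r].upper())
                    match_run = 0
                    nm += 1
                q += 1
                r += 1
        elif op == "I":
            nm += ln
            q += ln
        elif op == "D":
            md_parts.append(str(match_run))
            md_parts.append("^" + reference[r:r + ln].upper())
            match_run = 0
            nm += ln
            r += ln
        elif op == "N":
            r += ln
        elif op == "S":
            q += ln
        # H, P consume nothing
    md_parts.append(str(match_run))
    return nm, "".join(md_parts)
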