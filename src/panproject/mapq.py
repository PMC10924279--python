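"""Alignment rescoring and mapping-quality recalculation after projection.

When reads are aligned to founder sequences, identical founder stretches
yield multiple equally scored alignments that project to the *same*
reference coordinate; a conventional aligner, unaware of the projection,
would report a near-zero MAPQ for them. The fix implemented here partitions
each read's alignments by (target, projected leftmost, strand), takes the
best-scoring member of each partition as its representative, and feeds the
representative scores into a Bowtie2-style end-to-end mapping-quality model
(MAPQ = -10 log10 p, capped at 42). Alignments that collapse into a single
partition are thereby treated as one unique placement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import (
    ALIGN_OPS,
    AlignmentRecord,
    FLAG_SECONDARY,
)

MAX_MAPQ = 42

_MD_RE = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


@dataclass(frozen=True)
class ScoringScheme:
    """Bowtie2-style end-to-end scoring constants (all configurable).

    The per-mismatch penalty interpolates between ``mismatch_penalty_min``
    (MN) and ``mismatch_penalty_max`` (MX) with the base quality, capped at
    ``quality_cap``; each gap costs ``gap_open + length * gap_extend``; the
    minimum acceptable score is linear in read length.
    """

    match_bonus: int = 0
    mismatch_penalty_min: int = 2
    mismatch_penalty_max: int = 6
    n_penalty: int = 1
    gap_open: int = 5
    gap_extend: int = 3
    quality_cap: int = 40
    min_score_intercept: float = -0.6
    min_score_slope: float = -0.6

    def __post_init__(self):
        if not self.mismatch_penalty_max >= self.mismatch_penalty_min >= 0:
            raise ValueError("require MX >= MN >= 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.quality_cap <= 0:
            raise ValueError("quality cap must be positive")

    def mismatch_penalty(self, quality: int) -> int:
        q = min(quality, self.quality_cap)
        spread = self.mismatch_penalty_max - self.mismatch_penalty_min
        return self.mismatch_penalty_min + (spread * q) // self.quality_cap

    def min_score(self, read_length: int) -> float:
        return self.min_score_intercept + self.min_score_slope * read_length

    def perfect_score(self, read_length: int) -> float:
        return float(self.match_bonus * read_length)


# (best-over fraction of the score range, MAPQ) -- unique alignments
_UNIQUE_ROWS = ((0.8, 42), (0.7, 40), (0.6, 24), (0.5, 23), (0.4, 8), (0.3, 3), (0.0, 0))

# rows keyed by the score gap (best - second) as a fraction of the range;
# inner tables keyed by the best-over fraction. Chosen to be monotone
# non-decreasing in the gap for any fixed best score, with the zero-gap
# (tied) branch capped at 3 and a unique perfect alignment at 42.
_SECONDARY_ROWS = (
    (1.0, ((1.0, 42), (0.0, 40))),
    (0.5, ((1.0, 42), (0.84, 40), (0.68, 31), (0.0, 30))),
    (0.25, ((1.0, 42), (0.84, 37), (0.68, 25), (0.0, 10))),
    (0.1, ((1.0, 42), (0.84, 28), (0.68, 20), (0.0, 3))),
    (1e-12, ((1.0, 42), (0.84, 17), (0.68, 17), (0.0, 3))),
    (0.0, ((0.68, 3), (0.0, 0))),
)


@dataclass(frozen=True)
class MapqModel:
    """Piecewise table mapping score differences to MAPQ in [0, 42].

    Conceptually MAPQ = -10 log10(p) for p the misplacement probability;
    operationally a data-driven lookup on (best, second-best, minimum,
    perfect) scores, so alternative aligners' tables can be swapped in.
    """

    unique_rows: tuple = _UNIQUE_ROWS
    secondary_rows: tuple = _SECONDARY_ROWS
    max_mapq: int = MAX_MAPQ

    def mapq(self, best: float, second: Optional[float],
             min_score: float, perfect_score: float) -> int:
        span = max(perfect_score - min_score, 1.0)
        over = min(max((best - min_score) / span, 0.0), 1.0)
        if second is None:
            for threshold, value in self.unique_rows:
                if over >= threshold:
                    return min(value, self.max_mapq)
            return 0
        gap = max(best - second, 0.0) / span
        for g_threshold, table in self.secondary_rows:
            if gap >= g_threshold:
                for o_threshold, value in table:
                    if over >= o_threshold:
                        return min(value, self.max_mapq)
                return 0
        return 0


def _parse_md(md: str):
    """Expand an MD tag into the reference bases under each aligned read base."""
    ref_bases = []
    for m in _MD_RE.finditer(md):
        if m.group(1) is not None:
            ref_bases.extend([None] * int(m.group(1)))  # None = match
        elif m.group(2) is not None:
            pass  # deleted reference bases: no aligned read base
        else:
            ref_bases.append(m.group(3).upper())
    return ref_bases


def alignment_score(
    rec: AlignmentRecord,
    scheme: ScoringScheme = ScoringScheme(),
    reference: Optional[str] = None,
) -> int:
    """Score one alignment by penalizing mismatches, insertions and deletions.

    Mismatches are identified from *reference* when given, else from =/X
    operations, else from the record's MD tag; otherwise an error asks for
    a reference. Base qualities weight the mismatch penalty (absent
    qualities are treated as ``quality_cap``). Soft-clipped bases
    contribute nothing.
    """
    md_bases = None
    has_extended = any(op in ("=", "X") for op, _ in rec.cigar)
    if reference is None and not has_extended:
        md = rec.tags.get("MD")
        if md is None:
            raise ValueError(
                f"cannot identify mismatches for {rec.read_id}: supply a reference "
                "sequence (or an alignment with =/X operations or an MD tag)"
            )
        md_bases = _parse_md(str(md))
    score = 0
    q = 0  # read cursor
    r = rec.leftmost  # reference cursor
    a = 0  # aligned-base cursor (for MD)
    quals = rec.quals
    for op, ln in rec.cigar:
        if op in ALIGN_OPS:
            for _ in range(ln):
                base = rec.seq[q].upper() if rec.seq else "A"
                if reference is not None:
                    ref_base = reference[r].upper()
                elif op == "=":
                    ref_base = base
                elif op == "X":
                    ref_base = "N" if base == "N" else ("A" if base != "A" else "C")
                else:
                    ref_base = base if md_bases[a] is None else md_bases[a]
                quality = quals[q] if quals is not None else scheme.quality_cap
                if base == "N" or ref_base == "N":
                    score -= scheme.n_penalty
                elif base == ref_base:
                    score += scheme.match_bonus
                else:
                    score -= scheme.mismatch_penalty(quality)
                q += 1
                r += 1
                a += 1
        elif op == "I":
            score -= scheme.gap_open + ln * scheme.gap_extend
            q += ln
        elif op == "D":
            score -= scheme.gap_open + ln * scheme.gap_extend
            r += ln
        elif op == "S":
            q += ln
        elif op == "N":
            r += ln
        # H, P contribute nothing
    return score


@dataclass
class AlignmentPartition:
    """Alignments of one read sharing (target, projected leftmost, strand)."""

    key: tuple
    members: list
    representative: AlignmentRecord
    representative_score: int


def partition_alignments(
    records: Sequence,
    scores: Optional[Sequence] = None,
    strand_in_key: bool = True,
) -> list:
    """Group one read's projected alignments by placement.

    *scores* defaults to each record's AS tag. Partitions are ordered by
    representative score descending (ties keep input order); within a
    partition the representative is the max-score member (ties -> first).
    """
    if not records:
        return []
    read_ids = {rec.read_id for rec in records}
    if len(read_ids) > 1:
        raise ValueError(f"records of multiple reads passed: {sorted(read_ids)}")
    if scores is None:
        scores = []
        for rec in records:
            if "AS" not in rec.tags:
                raise ValueError(f"record {rec.read_id} lacks an AS tag; pass scores")
            scores.append(int(rec.tags["AS"]))
    groups: dict = {}
    order = []
    for rec, score in zip(records, scores):
        key = (rec.target_name, rec.leftmost)
        if strand_in_key:
            key = key + (rec.is_reverse,)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((rec, score))
    partitions = []
    for key in order:
        members = groups[key]
        rep, rep_score = members[0]  # ties keep the first in input order
        for cand, cand_score in members[1:]:
            if cand_score > rep_score:
                rep, rep_score = cand, cand_score
        partitions.append(
            AlignmentPartition(key, [m for m, _ in members], rep, rep_score)
        )
    partitions.sort(key=lambda p: -p.representative_score)
    return partitions


def recalculate_mapq(
    partitions: Sequence,
    scheme: ScoringScheme = ScoringScheme(),
    model: MapqModel = MapqModel(),
    read_length: Optional[int] = None,
) -> list:
    """Assign recalculated MAPQs to all members of each partition.

    The best partition's representative score and the runner-up partition's
    representative score feed the model; every member of the best partition
    receives the resulting MAPQ (the representative is primary, duplicates
    are marked secondary). Members of non-best partitions get MAPQ 0 and
    the secondary flag.
    """
    if not partitions:
        return []
    if read_length is None:
        read_length = len(partitions[0].representative.seq)
    best = partitions[0].representative_score
    second = partitions[1].representative_score if len(partitions) > 1 else None
    value = model.mapq(best, second, scheme.min_score(read_length),
                       scheme.perfect_score(read_length))
    out = []
    for rank, part in enumerate(partitions):
        for member in part.members:
            rec = member.copy()
            if rank == 0:
                rec.mapq = value
                rec.set_flag(FLAG_SECONDARY, member is not part.representative)
            else:
                rec.mapq = 0
                rec.set_flag(FLAG_SECONDARY, True)
            out.append(rec)
    return out


def filter_max_mapq(records: Sequence) -> AlignmentRecord:
    """Keep one read's maximum-MAPQ alignment (MM mode).

    Ties break by maximum alignment score (AS tag, when present), then by
    lowest (target, position). The kept record loses its secondary flag.
    """
    if not records:
        raise ValueError("no records to filter")

    def sort_key(rec):
        score = int(rec.tags.get("AS", 0))
        return (-rec.mapq, -score, rec.target_name or "", rec.leftmost)

    best = min(records, key=sort_key)
    kept = best.copy()
    kept.set_flag(FLAG_SECONDARY, False)
    return kept
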