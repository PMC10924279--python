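"""Reference-bias and alignment-accuracy evaluation.

Reference bias shows up as an excess of reference-allele-supporting reads
at heterozygous sites. For each het site this module counts the reads
supporting the reference allele (R) and the correct alternative allele (A)
among alignments that fully enclose the site, computes the balance
x_i = R / (R + A), and summarises the deviation from the ideal 0.5 as the
mean absolute error (1/n) * sum |x_i - 0.5|, overall and grouped by the
alt-minus-ref allele length difference.

Alignment accuracy compares each read's single reported placement against
its simulated truth position with a small tolerance (default 5 bases);
wrong placements count as both FP and FN so that TP + FN always equals the
number of reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import ALIGN_OPS, AlignmentRecord

DEFAULT_MIN_COVERAGE = 20
DEFAULT_TOLERANCE = 5


@dataclass(frozen=True)
class VariantSite:
    """A heterozygous site to evaluate; positions are 0-based."""

    contig: str
    ref_position: int
    ref_allele: str
    alt_allele: str
    heterozygous: bool = True

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")

    @property
    def ref_end(self) -> int:
        return self.ref_position + len(self.ref_allele)

    @property
    def length_diff(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


def _site_observation(rec: AlignmentRecord, start: int, end: int):
    """Classify one alignment against one site's reference span.

    Returns ``None`` unless the alignment fully encloses the site (>= 1
    aligned base strictly before ``start`` and >= 1 match/mismatch
    operation consuming reference at or after ``end``); otherwise returns
    the read bases covering the span: bases aligned to reference positions
    in [start, end) plus insertions anchored strictly inside (start, end].
    """
    seg = []
    aligned_before = False
    aligned_after = False
    q = 0
    r = rec.leftmost
    for op, ln in rec.cigar:
        if op in ALIGN_OPS:
            if r < start:
                aligned_before = True
            if r + ln > end:
                aligned_after = True
            first = max(r, start)
            last = min(r + ln, end)
            if first < last:
                seg.append(rec.seq[q + (first - r):q + (last - r)])
            q += ln
            r += ln
        elif op == "I":
            if start < r <= end:
                seg.append(rec.seq[q:q + ln])
            q += ln
        elif op in ("D", "N"):
            r += ln
        elif op == "S":
            q += ln
    if not (aligned_before and aligned_after):
        return None
    return "".join(seg).upper()


def pileup_balance(
    alignments: Sequence,
    sites: Sequence,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    count_neither_in_coverage: bool = True,
) -> pd.DataFrame:
    """Per-site R/A counts and balances from projected alignments.

    Only alignments that fully enclose a site (with an aligned base on each
    side, see :func:`_site_observation`) count toward its coverage. A read
    supports REF/ALT when its bases over the site's reference span
    reproduce the respective allele string exactly; reads matching neither
    enter coverage (configurable) but neither count. Sites with coverage
    below *min_coverage* or with R + A = 0 are dropped.

    Returns a DataFrame with columns contig, position, ref, alt,
    length_diff, R, A, coverage, balance.
    """
    positions = [s.ref_position for s in sites]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("sites must be sorted by position")
    mapped = [rec for rec in alignments if not rec.is_unmapped]
    starts = np.array([rec.leftmost for rec in mapped], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    mapped = [mapped[i] for i in order]
    starts = starts[order]
    max_span = max((rec.reference_end - rec.leftmost for rec in mapped), default=0)

    rows = []
    for site in sites:
        start, end = site.ref_position, site.ref_end
        lo = int(np.searchsorted(starts, start - max_span, side="left"))
        hi = int(np.searchsorted(starts, start, side="right"))
        R = A = neither = 0
        for rec in mapped[lo:hi]:
            if rec.target_name != site.contig:
                continue
            if rec.reference_end <= end:
                continue
            seg = _site_observation(rec, start, end)
            if seg is None:
                continue
            if seg == site.ref_allele.upper():
                R += 1
            elif seg == site.alt_allele.upper():
                A += 1
            else:
                neither += 1
        coverage = R + A + (neither if count_neither_in_coverage else 0)
        if coverage < min_coverage or R + A == 0:
            continue
        rows.append(
            {
                "contig": site.contig,
                "position": site.ref_position,
                "ref": site.ref_allele,
                "alt": site.alt_allele,
                "length_diff": site.length_diff,
                "R": R,
                "A": A,
                "coverage": coverage,
                "balance": R / (R + A),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "position", "ref", "alt", "length_diff",
                 "R", "A", "coverage", "balance"],
    )


def mean_absolute_error(balances: Iterable) -> float:
    """MAE of balances with respect to 0.5: (1/n) * sum |x_i - 0.5|."""
    values = np.asarray(list(balances), dtype=float)
    if values.size == 0:
        raise ValueError("mean_absolute_error requires at least one balance")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("balances must lie in [0, 1]")
    return float(np.mean(np.abs(values - 0.5)))


def group_by_length_diff(table: pd.DataFrame) -> pd.DataFrame:
    """Per-length-difference balance summaries (n, quartiles, MAE).

    The overall MAE is appended as a row with length_diff = 'overall'.
    """
    if table.empty:
        raise ValueError("balance table is empty")
    rows = []
    for diff, group in table.groupby("length_diff"):
        x = group["balance"].to_numpy()
        rows.append(
            {
                "length_diff": diff,
                "n": len(x),
                "q1": float(np.quantile(x, 0.25)),
                "median": float(np.median(x)),
                "q3": float(np.quantile(x, 0.75)),
                "mae": mean_absolute_error(x),
            }
        )
    overall = table["balance"].to_numpy()
    rows.append(
        {
            "length_diff": "overall",
            "n": len(overall),
            "q1": float(np.quantile(overall, 0.25)),
            "median": float(np.median(overall)),
            "q3": float(np.quantile(overall, 0.75)),
            "mae": mean_absolute_error(overall),
        }
    )
    return pd.DataFrame(rows, columns=["length_diff", "n", "q1", "median", "q3", "mae"])


def alignment_precision_recall(
    alignments: Sequence,
    truth: pd.DataFrame,
    tolerance: int = DEFAULT_TOLERANCE,
) -> dict:
    """Precision/recall of read placements against simulated truth.

    *alignments* holds at most one evaluated placement per read (pre-filter
    with MM or primary selection); *truth* is a DataFrame with columns
    read_id, contig, pos0 (0-based true leftmost), strand. A placement
    within *tolerance* bases of truth on the right contig is a TP; placed
    elsewhere counts as FP and FN; unaligned or missing reads are FN only,
    so TP + FN equals the number of reads.
    """
    if truth["read_id"].duplicated().any():
        raise ValueError("truth table contains duplicate read_ids")
    placements = {}
    for rec in alignments:
        if rec.read_id in placements:
            raise ValueError(
                f"duplicate placement for read {rec.read_id}; pre-filter to one per read"
            )
        placements[rec.read_id] = rec
    tp = fp = fn = 0
    for row in truth.itertuples(index=False):
        rec = placements.get(row.read_id)
        if rec is None or rec.is_unmapped:
            fn += 1
            continue
        if rec.target_name == row.contig and abs(rec.leftmost - row.pos0) <= tolerance:
            tp += 1
        else:
            fp += 1
            fn += 1
    n_reads = len(truth)
    assert tp + fn == n_reads, "accounting identity TP + FN == reads violated"
    aligned = tp + fp
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "precision": tp / aligned if aligned else float("nan"),
        "recall": tp / n_reads if n_reads else float("nan"),
    }
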