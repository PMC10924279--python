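"""Independent brute-force oracles used by the test suite.

Everything here recomputes results by explicit per-column / per-base
expansion or exhaustive enumeration, independently of the linear-time
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

GAP = "-"


# ---------------------------------------------------------------------------
# projection: per-column composition oracle


def expand_read_vs_founder(cigar, founder_leftmost):
    """Expand a read-vs-founder script into ordered (q_idx, f_pos) pairs.

    Either element may be None (insertion / deletion). Soft and hard clips
    are returned separately as (leading, trailing) op lists.
    """
    pairs = []
    lead, tail = [], []
    q = 0
    f = founder_leftmost
    seen_core = False
    for op, ln in cigar:
        if op in ("S", "H"):
            target = tail if seen_core else lead
            target.append((op, ln))
            if op == "S":
                q += ln
            continue
        seen_core = True
        if op in ("M", "=", "X"):
            for _ in range(ln):
                pairs.append((q, f))
                q += 1
                f += 1
        elif op == "I":
            for _ in range(ln):
                pairs.append((q, None))
                q += 1
        elif op in ("D", "N"):
            for _ in range(ln):
                pairs.append((None, f))
                f += 1
        else:
            raise ValueError(op)
    return lead, pairs, tail


def project_by_columns(ref_row, founder_row, cigar, founder_leftmost):
    """Brute-force projection via explicit MSA column walk.

    Returns ``(ref_leftmost or None, raw_ops)`` where raw_ops is the
    un-normalized projected script (leading/trailing deletions stripped,
    run-length merged).
    """
    col_of_f = []  # founder position -> column
    ref_at_col = []  # column -> ref position or None
    r = 0
    for c, (rc, fc) in enumerate(zip(ref_row, founder_row)):
        if fc != GAP:
            col_of_f.append(c)
        if rc != GAP:
            ref_at_col.append(r)
            r += 1
        else:
            ref_at_col.append(None)

    lead, pairs, tail = expand_read_vs_founder(cigar, founder_leftmost)

    events = []  # (op, ref_pos or None), one per base
    prev_col = None
    for q_idx, f_pos in pairs:
        if f_pos is None:
            events.append(("I", None))
            continue
        col = col_of_f[f_pos]
        # reference bases in founder-gap columns between consecutive pairs
        if prev_col is not None:
            for c in range(prev_col + 1, col):
                if ref_at_col[c] is not None and founder_row[c] == GAP:
                    events.append(("D", ref_at_col[c]))
        rp = ref_at_col[col]
        if q_idx is None:  # read deletion over this founder base
            if rp is not None:
                events.append(("D", rp))
        else:
            events.append(("M" if rp is not None else "I", rp))
        prev_col = col

    # drop deletions outside the outermost aligned bases (no anchor in SAM)
    m_indices = [i for i, (op, _) in enumerate(events) if op == "M"]
    if m_indices:
        first_m, last_m = m_indices[0], m_indices[-1]
        events = [
            e for i, e in enumerate(events)
            if e[0] != "D" or first_m < i < last_m
        ]
    else:
        events = [e for e in events if e[0] != "D"]

    ref_positions = [rp for op, rp in events if op == "M"]
    ref_leftmost = min(ref_positions) if ref_positions else None

    ops = []
    for op, _ in events:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ref_leftmost, lead + ops + tail


def random_msa_pair(rng, max_columns=60):
    """Random (ref_row, founder_row) with at least one base in each."""
    n = int(rng.integers(2, max_columns + 1))
    kinds = rng.choice(["both", "ref_only", "founder_only"], size=n,
                       p=[0.6, 0.2, 0.2])
    bases = "ACGT"
    ref, fnd = [], []
    for kind in kinds:
        rb = bases[rng.integers(0, 4)]
        fb = bases[rng.integers(0, 4)]
        if kind == "both":
            ref.append(rb)
            fnd.append(fb)
        elif kind == "ref_only":
            ref.append(rb)
            fnd.append(GAP)
        else:
            ref.append(GAP)
            fnd.append(fb)
    if all(c == GAP for c in ref):
        ref[int(rng.integers(0, n))] = "A"
    if all(c == GAP for c in fnd):
        fnd[int(rng.integers(0, n))] = "A"
    return "".join(ref), "".join(fnd)


def random_alignment(rng, founder_length, max_read=30):
    """Random read-vs-founder script fitting inside the founder."""
    while True:
        leftmost = int(rng.integers(0, founder_length))
        ops = []
        f_span = 0
        q_len = 0
        n_ops = int(rng.integers(1, 7))
        for _ in range(n_ops):
            op = str(rng.choice(["M", "M", "M", "I", "D"]))
            ln = int(rng.integers(1, 5))
            if op in ("M", "D") and leftmost + f_span + ln > founder_length:
                break
            if op in ("M", "I") and q_len + ln > max_read:
                break
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + ln)
            else:
                ops.append((op, ln))
            if op in ("M", "D"):
                f_span += ln
            if op in ("M", "I"):
                q_len += ln
        # need at least one founder-consuming aligned op
        if any(op == "M" for op, _ in ops):
            # strip boundary deletions (aligners never emit them)
            while ops and ops[0][0] == "D":
                leftmost += ops[0][1]
                ops.pop(0)
            while ops and ops[-1][0] == "D":
                ops.pop()
            if rng.random() < 0.3:
                ops.insert(0, ("S", int(rng.integers(1, 4))))
            if rng.random() < 0.3:
                ops.append(("S", int(rng.integers(1, 4))))
            return leftmost, ops


# ---------------------------------------------------------------------------
# scoring oracle: expand the alignment and re-score base by base


def score_by_expansion(cigar, seq, quals, reference, leftmost, scheme):
    """Re-score an alignment from its fully expanded base pairs."""
    total = 0
    q = 0
    r = leftmost
    for op, ln in cigar:
        if op in ("M", "=", "X"):
            for _ in range(ln):
                read_base = seq[q].upper()
                ref_base = reference[r].upper()
                if "N" in (read_base, ref_base):
                    total -= scheme.n_penalty
                elif read_base == ref_base:
                    total += scheme.match_bonus
                else:
                    quality = quals[q] if quals is not None else scheme.quality_cap
                    qq = min(quality, scheme.quality_cap)
                    spread = scheme.mismatch_penalty_max - scheme.mismatch_penalty_min
                    total -= scheme.mismatch_penalty_min + (
                        spread * qq
                    ) // scheme.quality_cap
                q += 1
                r += 1
        elif op == "I":
            total -= scheme.gap_open + ln * scheme.gap_extend
            q += ln
        elif op == "D":
            total -= scheme.gap_open + ln * scheme.gap_extend
            r += ln
        elif op == "S":
            q += ln
        elif op == "N":
            r += ln
    return total


# ---------------------------------------------------------------------------
# segmentation: exhaustive search over all valid segmentations


def valid_segmentations(n_sites, L):
    """All boundary lists [0, ..., n_sites] with every block >= L sites
    (the last block may be shorter only when n_sites < L)."""
    if n_sites < L:
        yield [0, n_sites]
        return

    def rec(start):
        if start == n_sites:
            yield []
            return
        for end in range(start + L, n_sites + 1):
            if n_sites - end != 0 and n_sites - end < L:
                continue
            for rest in rec(end):
                yield [end] + rest

    for tail in rec(0):
        yield [0] + tail


def min_segment_count(matrix, F, L):
    """Minimum number of segments over all valid segmentations where every
    segment has <= F-1 distinct haplotype strings; None if none exists."""
    n_sites = matrix.shape[1]
    best = None
    for boundaries in valid_segmentations(n_sites, L):
        ok = True
        for lo, hi in zip(boundaries, boundaries[1:]):
            distinct = {tuple(row[lo:hi]) for row in matrix}
            if len(distinct) > F - 1:
                ok = False
                break
        if ok:
            count = len(boundaries) - 1
            if best is None or count < best:
                best = count
    return best


def haplotype_is_recombination(hap_alleles, founder_set):
    """Check by DP over segments that a haplotype equals a founder mosaic
    switching only at segment boundaries."""
    seg = founder_set.segmentation
    matrix = founder_set.allele_matrix
    reachable = set(range(matrix.shape[0]))
    for segment in seg.segments:
        target = tuple(int(a) for a in hap_alleles[segment.start:segment.end])
        matching = {
            k
            for k in range(matrix.shape[0])
            if tuple(int(a) for a in matrix[k, segment.start:segment.end]) == target
        }
        if not matching:
            return False
        reachable = matching  # switching allowed at every boundary
    return True
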