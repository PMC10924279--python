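"""Alignment scoring, partitioning and mapping-quality recalculation."""

import numpy as np
import pytest

from _oracles import score_by_expansion
from panproject.mapq import (
    MapqModel,
    ScoringScheme,
    alignment_score,
    filter_max_mapq,
    partition_alignments,
    recalculate_mapq,
)
from panproject.records import AlignmentRecord, FLAG_REVERSE, FLAG_SECONDARY

SCHEME = ScoringScheme()
MODEL = MapqModel()


def record(cigar, seq, pos=0, quals=None, target="ref", read_id="r", **kw):
    return AlignmentRecord(read_id=read_id, target_name=target, leftmost=pos,
                           cigar=cigar, seq=seq, quals=quals, **kw)


class TestAlignmentScore:
    def test_perfect_end_to_end_scores_zero(self):
        rec = record([("M", 10)], "ACGTACGTAC")
        assert alignment_score(rec, SCHEME, reference="ACGTACGTACGT") == 0

    def test_one_mismatch_at_q40_costs_six(self):
        rec = record([("M", 10)], "ACGTACGTAC", quals=(40,) * 10)
        assert alignment_score(rec, SCHEME, reference="ACGAACGTACGT") == -6

    def test_low_quality_mismatch_costs_less(self):
        quals = (40,) * 3 + (10,) + (40,) * 6
        rec = record([("M", 10)], "ACGTACGTAC", quals=quals)
        # MN + floor((MX-MN)*10/40) = 2 + 1 = 3
        assert alignment_score(rec, SCHEME, reference="ACGAACGTACGT") == -3

    def test_one_base_insertion_costs_eight(self):
        rec = record([("M", 4), ("I", 1), ("M", 5)], "ACGTTACGTA")
        assert alignment_score(rec, SCHEME, reference="ACGTACGTACGT") == -8

    def test_soft_clips_and_n_bases(self):
        rec = record([("S", 2), ("M", 4)], "GGACNT")
        # clipped GG contributes nothing; the single N column costs n_penalty
        assert alignment_score(rec, SCHEME, reference="ACNTGG") == -SCHEME.n_penalty

    def test_md_tag_substitutes_for_reference(self):
        rec = record([("M", 10)], "ACGTACGTAC", quals=(40,) * 10)
        rec.tags["MD"] = "3A6"
        assert alignment_score(rec, SCHEME) == -6

    def test_no_reference_no_md_is_error(self):
        rec = record([("M", 10)], "ACGTACGTAC")
        with pytest.raises(ValueError, match="reference"):
            alignment_score(rec, SCHEME)

    def test_matches_expansion_oracle_on_random_records(self):
        rng = np.random.default_rng(11)
        bases = "ACGTN"
        for _ in range(2000)        :
            ref = "".join(bases[rng.integers(0, 5)] for _ in range(60))
            pos = int(rng.integers(0, 20))
            ops = []
            q_len = 0
            r_len = 0
            for _ in range(int(rng.integers(1, 6))):
                op = str(rng.choice(["M", "M", "M", "I", "D", "S"]))
                ln = int(rng.integers(1, 6))
                if ops and ops[-1][0] == op:
                    continue
                if op == "S" and ops and ops[0][0] == "S":
                    continue
                ops.append((op, ln))
                if op in "MIS":
                    q_len += ln
                if op in "MD":
                    r_len += ln
            if not any(op == "M" for op, _ in ops):
                continue
            # keep S at ends only
            core = [x for x in ops if x[0] != "S"]
            while core and core[0][0] == "D":
                core.pop(0)
            while core and core[-1][0] == "D":
                core.pop()
            if not core:
                continue
            ops = ([("S", 2)] if rng.random() < 0.3 else []) + core
            q_len = sum(ln for op, ln in ops if op in "MIS")
            r_len = sum(ln for op, ln in ops if op in "MD")
            if pos + r_len > len(ref):
                continue
            seq = "".join(bases[rng.integers(0, 5)] for _ in range(q_len))
            quals = tuple(int(q) for q in rng.integers(0, 41, size=q_len))
            rec = record(ops, seq, pos=pos, quals=quals)
            assert alignment_score(rec, SCHEME, reference=ref) == \
                score_by_expansion(ops, seq, quals, ref, pos, SCHEME)


class TestPartitionAlignments:
    def test_same_projected_coordinate_collapses(self):
        a = record([("M", 10)], "A" * 10, pos=100, target="ref", tags={"AS": 0})
        b = record([("M", 10)], "A" * 10, pos=100, target="ref", tags={"AS": 0})
        parts = partition_alignments([a, b])
        assert len(parts) == 1
        assert len(parts[0].members) == 2

    def test_distinct_coordinates_stay_separate(self):
        a = record([("M", 10)], "A" * 10, pos=100, tags={"AS": 0})
        b = record([("M", 10)], "A" * 10, pos=250, tags={"AS": 0})
        assert len(partition_alignments([a, b])) == 2

    def test_representative_is_max_score(self):
        a = record([("M", 10)], "A" * 10, pos=100, tags={"AS": -14})
        b = record([("M", 10)], "A" * 10, pos=100, tags={"AS": -6})
        parts = partition_alignments([a, b])
        assert parts[0].representative_score == -6
        assert parts[0].representative is b

    def test_strand_separates_partitions(self):
        a = record([("M", 10)], "A" * 10, pos=100, tags={"AS": 0})
        b = record([("M", 10)], "A" * 10, pos=100, tags={"AS": 0},
                   flag=FLAG_REVERSE)
        assert len(partition_alignments([a, b])) == 2
        assert len(partition_alignments([a, b], strand_in_key=False)) == 1

    def test_mixed_read_ids_rejected(self):
        a = record([("M", 10)], "A" * 10, tags={"AS": 0}, read_id="r1")
        b = record([("M", 10)], "A" * 10, tags={"AS": 0}, read_id="r2")
        with pytest.raises(ValueError, match="multiple reads"):
            partition_alignments([a, b])


class TestRecalculateMapq:
    def test_unique_perfect_alignment_gets_42(self):
        rec = record([("M", 100)], "A" * 100, tags={"AS": 0})
        parts = partition_alignments([rec])
        out = recalculate_mapq(parts, SCHEME, MODEL)
        assert out[0].mapq == 42

    def test_equal_scores_in_two_partitions_cap_at_3(self):
        a = record([("M", 100)], "A" * 100, pos=100, tags={"AS": 0})
        b = record([("M", 100)], "A" * 100, pos=250, tags={"AS": 0})
        out = recalculate_mapq(partition_alignments([a, b]), SCHEME, MODEL)
        assert max(r.mapq for r in out) <= 3

    def test_duplicate_founder_regions_restore_uniqueness(self):
        # equal-scoring placements sharing one projected coordinate are one
        # partition: the recalculated MAPQ equals the unique-alignment value
        a = record([("M", 100)], "A" * 100, pos=100, tags={"AS": 0})
        b = record([("M", 100)], "A" * 100, pos=100, tags={"AS": 0})
        together = recalculate_mapq(partition_alignments([a, b]), SCHEME, MODEL)
        assert together[0].mapq == 42
        apart = recalculate_mapq(
            partition_alignments([a, b.copy(leftmost=300)]), SCHEME, MODEL
        )
        assert together[0].mapq >= apart[0].mapq
        assert apart[0].mapq <= 3

    def test_non_best_partitions_get_zero_and_secondary(self):
        a = record([("M", 100)], "A" * 100, pos=100, tags={"AS": 0})
        b = record([("M", 100)], "A" * 100, pos=250, tags={"AS": -30})
        out = recalculate_mapq(partition_alignments([a, b]), SCHEME, MODEL)
        loser = [r for r in out if r.leftmost == 250][0]
        assert loser.mapq == 0
        assert loser.is_secondary

    def test_mapq_monotone_in_score_gap_and_bounded(self):
        read_len = 100
        mn = SCHEME.min_score(read_len)
        perfect = SCHEME.perfect_score(read_len)
        rng = np.random.default_rng(3)
        for _ in range(3000):
            best = float(rng.uniform(mn, perfect))
            seconds = sorted(float(rng.uniform(mn, best)) for _ in range(2))
            q_far = MODEL.mapq(best, seconds[0], mn, perfect)
            q_near = MODEL.mapq(best, seconds[1], mn, perfect)
            assert 0 <= q_near <= 42 and 0 <= q_far <= 42
            assert q_far >= q_near  # larger gap, no lower confidence
            unique = MODEL.mapq(best, None, mn, perfect)
            tied = MODEL.mapq(best, best, mn, perfect)
            assert unique >= tied


class TestFilterMaxMapq:
    def test_keeps_max_mapq(self):
        a = record([("M", 10)], "A" * 10, pos=1, mapq=40)
        b = record([("M", 10)], "A" * 10, pos=2, mapq=10)
        assert filter_max_mapq([a, b]).leftmost == 1

    def test_mapq_tie_breaks_by_score(self):
        a = record([("M", 10)], "A" * 10, pos=1, mapq=30, tags={"AS": -8})
        b = record([("M", 10)], "A" * 10, pos=2, mapq=30, tags={"AS": -6})
        assert filter_max_mapq([a, b]).leftmost == 2

    def test_single_record_unchanged_and_primary(self):
        a = record([("M", 10)], "A" * 10, pos=5, mapq=7, flag=FLAG_SECONDARY)
        kept = filter_max_mapq([a])
        assert kept.leftmost == 5 and not kept.is_secondary

    def test_order_independent_up_to_tie_breaks(self):
        rng = np.random.default_rng(5)
        recs = [
            record([("M", 10)], "A" * 10, pos=int(p), mapq=int(m),
                   tags={"AS": int(s)})
            for p, m, s in zip(rng.integers(0, 50, 6),
                               rng.integers(0, 43, 6),
                               rng.integers(-20, 1, 6))
        ]
        baseline = filter_max_mapq(recs)
        for _ in range(10):
            perm = [recs[i] for i in rng.permutation(len(recs))]
            shuffled = filter_max_mapq(perm)
            assert (shuffled.leftmost, shuffled.mapq) == \
                (baseline.leftmost, baseline.mapq)
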