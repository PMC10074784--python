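"""Detection core: mate filtering, clip evidence, consensus, depth, verdict."""

import pysam
import pytest

from fusionclip.alignment import FusionRead
from fusionclip.detect import (
    breakpoint_depth,
    detect_fusion,
    five_prime_flank,
    identify_softclips,
    infer_breakpoint,
    select_mate_pairs,
    three_prime_flank,
    count_mate_pairs,
)
from fusionclip.errors import DataError
from fusionclip.simulate import SamRecord, write_bam

from conftest import WINDOW_3P, WINDOW_5P, make_target


def _read(qname="r1", pos=3000, cigar=((100, "M"),), seq=None,
          mate_chrom="chr2", mate_pos=11000):
    qlen = sum(l for l, op in cigar if op in "MIS=X")
    return FusionRead(
        qname=qname,
        chrom="chr2",
        pos=pos,
        cigar=tuple(cigar),
        seq=seq if seq is not None else "A" * qlen,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
    )


class TestSelectMatePairs:
    def test_mate_inside_window_kept(self):
        target = make_target()
        kept = select_mate_pairs([_read(mate_pos=WINDOW_3P.start + 500)], target)
        assert len(kept) == 1

    def test_mate_on_other_chromosome_dropped(self):
        target = make_target()
        assert select_mate_pairs([_read(mate_chrom="chr1")], target) == []

    @pytest.mark.parametrize(
        "mate_pos,kept",
        [
            (WINDOW_3P.start - 1, False),
            (WINDOW_3P.start, True),
            (WINDOW_3P.end, True),
            (WINDOW_3P.end + 1, False),
        ],
    )
    def test_window_boundaries_inclusive(self, mate_pos, kept):
        target = make_target()
        result = select_mate_pairs([_read(mate_pos=mate_pos)], target)
        assert bool(result) is kept

    def test_pair_count_is_distinct_read_names(self):
        reads = [_read(qname="a"), _read(qname="a", pos=3100), _read(qname="b")]
        assert count_mate_pairs(reads) == 2


class TestIdentifySoftclips:
    def test_right_clip_breakpoint_arithmetic(self):
        target = make_target()
        ev = identify_softclips([_read(pos=3000, cigar=((58, "M"), (42, "S")))], target)
        assert len(ev) == 1
        assert ev[0].clip_end == "right"
        assert ev[0].clip_len == 42
        assert ev[0].breakpoint_pos == 3000 + 58 - 1

    def test_left_clip_breakpoint_is_leftmost_aligned_base(self):
        target = make_target()
        ev = identify_softclips([_read(pos=3000, cigar=((42, "S"), (58, "M")))], target)
        assert ev[0].clip_end == "left"
        assert ev[0].breakpoint_pos == 3000

    def test_fully_aligned_read_contributes_no_evidence(self):
        target = make_target()
        assert identify_softclips([_read(cigar=((100, "M"),))], target) == []

    def test_longer_clip_wins_when_both_ends_clipped(self):
        target = make_target()
        ev = identify_softclips(
            [_read(pos=3000, cigar=((5, "S"), (60, "M"), (35, "S")))], target
        )
        assert ev[0].clip_end == "right"
        assert ev[0].clip_len == 35

    def test_equal_clips_use_right_end(self):
        target = make_target()
        ev = identify_softclips(
            [_read(pos=3000, cigar=((20, "S"), (60, "M"), (20, "S")))], target
        )
        assert ev[0].clip_end == "right"

    def test_clipped_seq_is_taken_from_the_clip(self):
        target = make_target()
        seq = "A" * 58 + "C" * 42
        ev = identify_softclips(
            [_read(pos=3000, cigar=((58, "M"), (42, "S")), seq=seq)], target
        )
        assert ev[0].clipped_seq == "C" * 42

    def test_breakpoint_outside_window_discarded(self):
        target = make_target()
        # aligned span ends beyond the window end
        ev = identify_softclips(
            [_read(pos=WINDOW_5P.end - 10, cigar=((58, "M"), (42, "S")))], target
        )
        assert ev == []

    def test_deletion_shifts_the_breakpoint(self):
        target = make_target()
        ev = identify_softclips(
            [_read(pos=3000, cigar=((50, "M"), (10, "D"), (8, "M"), (42, "S")))], target
        )
        assert ev[0].breakpoint_pos == 3000 + 50 + 10 + 8 - 1


class TestInferBreakpoint:
    def _ev(self, positions):
        target = make_target()
        reads = [
            _read(qname=f"r{i}", pos=p - 57, cigar=((58, "M"), (42, "S")))
            for i, p in enumerate(positions)
        ]
        return identify_softclips(reads, target)

    def test_modal_position_wins(self):
        table, consensus = infer_breakpoint(self._ev([4000, 4000, 4001]))
        assert table == {4000: 2, 4001: 1}
        assert consensus == 4000

    def test_single_evidence(self):
        _, consensus = infer_breakpoint(self._ev([4123]))
        assert consensus == 4123

    def test_tie_breaks_to_smallest_coordinate(self):
        _, consensus = infer_breakpoint(self._ev([4200, 4100, 4200, 4100]))
        assert consensus == 4100

    def test_empty_evidence_fails(self):
        with pytest.raises(DataError, match="junction"):
            infer_breakpoint([])


class TestFlanks:
    def _evidence(self, seqs, pos=3943, aligned=58, clip=42):
        target = make_target()
        reads = [
            _read(qname=f"r{i}", pos=pos, cigar=((aligned, "M"), (clip, "S")), seq=s)
            for i, s in enumerate(seqs)
        ]
        return identify_softclips(reads, target), pos + aligned - 1

    def test_five_prime_majority_and_tie_column(self):
        # two reads agreeing except at the final aligned base -> tie -> N
        s1 = "A" * 57 + "T" + "G" * 42
        s2 = "A" * 57 + "C" + "G" * 42
        ev, consensus = self._evidence([s1, s2])
        flank = five_prime_flank(ev, consensus, 4)
        assert flank == "AAAN"

    def test_five_prime_zero_flank_is_empty(self):
        ev, consensus = self._evidence(["A" * 100])
        assert five_prime_flank(ev, consensus, 0) == ""

    def test_five_prime_uncovered_columns_are_n(self):
        ev, consensus = self._evidence(["A" * 100], aligned=58)
        flank = five_prime_flank(ev, consensus, 60)  # longer than the aligned part
        assert flank[:2] == "NN"
        assert flank.endswith("A" * 58)

    def test_three_prime_single_evidence_verbatim(self):
        seq = "A" * 58 + "GATTACA" + "C" * 35
        ev, consensus = self._evidence([seq])
        assert three_prime_flank(ev, consensus, 7) == "GATTACA"

    def test_three_prime_truncated_to_longest_clip(self):
        target = make_target()
        reads = [
            _read(qname="a", pos=3943, cigar=((90, "M"), (10, "S")), seq="A" * 90 + "G" * 10),
            _read(qname="b", pos=3943 + 32, cigar=((58, "M"), (6, "S")), seq="A" * 58 + "G" * 6),
        ]
        ev = identify_softclips(reads, target)
        flank = three_prime_flank(ev, 3943 + 89, 20)
        assert len(flank) == 10  # longest clip, not flank_len

    def test_three_prime_tie_column_is_n(self):
        target = make_target()
        reads = [
            _read(qname="a", pos=3943, cigar=((58, "M"), (4, "S")), seq="A" * 58 + "GTTT"),
            _read(qname="b", pos=3943, cigar=((58, "M"), (4, "S")), seq="A" * 58 + "CTTT"),
        ]
        ev = identify_softclips(reads, target)
        assert three_prime_flank(ev, 3943 + 57, 4) == "NTTT"


class TestBreakpointDepth:
    def _bam(self, tmp_path, records):
        return write_bam(records, {"chr2": 20000}, tmp_path / "depth.bam")

    def _pair(self, qname, pos, cigar, seq_len=None, **kw):
        qlen = sum(l for l, op in cigar if op in "MIS=X")
        r1 = SamRecord(qname, "chr2", pos, list(cigar), "A" * qlen, False, True,
                       mate_chrom="chr2", mate_pos=pos, **kw)
        r2 = SamRecord(qname, "chr2", pos, list(cigar), "A" * qlen, True, False,
                       mate_chrom="chr2", mate_pos=pos, **kw)
        return [r1, r2]

    def test_deletion_spanning_position_counts(self, tmp_path):
        target = make_target()
        recs = self._pair("del", 3000, [(50, "M"), (10, "D"), (50, "M")])
        bam = self._bam(tmp_path, recs)
        assert breakpoint_depth(bam, target, 3055) == 2  # inside the D segment

    def test_refskip_spanning_position_not_counted(self, tmp_path):
        target = make_target()
        recs = self._pair("skip", 3000, [(50, "M"), (10, "N"), (50, "M")])
        bam = self._bam(tmp_path, recs)
        assert breakpoint_depth(bam, target, 3055) == 0

    def test_position_without_coverage_is_zero(self, tmp_path):
        target = make_target()
        bam = self._bam(tmp_path, self._pair("r", 3000, [(100, "M")]))
        assert breakpoint_depth(bam, target, 5000) == 0

    def test_matches_independent_pileup_oracle(self, positive_bundle, small_target):
        bundle, cfg = positive_bundle
        consensus = bundle.truth.breakpoint_5p
        depth = breakpoint_depth(bundle.bam, small_target, consensus)
        # oracle: samtools-style pileup column, counting deletion-spanning reads
        flag_mask = 0x4 | 0x100 | 0x200 | 0x400 | 0x800
        with pysam.AlignmentFile(str(bundle.bam), "rb") as bam:
            oracle = 0
            for col in bam.pileup(
                "chr2",
                consensus - 1,
                consensus,
                truncate=True,
                stepper="all",
                flag_filter=flag_mask,
                min_base_quality=0,
                max_depth=1_000_000,
            ):
                oracle = sum(1 for p in col.pileups if not p.is_refskip)
        assert depth == oracle
        assert depth > 0


class TestDetectFusion:
    def test_positive_sample_recovers_truth_breakpoint(self, positive_bundle, small_target):
        bundle, _ = positive_bundle
        call = detect_fusion(bundle.bam, small_target)
        assert call.status == "positive"
        assert call.consensus_breakpoint == bundle.truth.breakpoint_5p
        assert call.n_pairs >= 2 and call.n_clip_reads >= 2
        assert sum(call.breakpoint_table.values()) == call.n_clip_reads

    def test_fusion_free_sample_is_negative_with_empty_evidence(
        self, negative_bundle, small_target
    ):
        bundle, _ = negative_bundle
        call = detect_fusion(bundle.bam, small_target)
        assert call.status == "negative"
        assert call.evidence == []
        assert call.consensus_breakpoint is None
        assert call.eml4_flank is None and call.alk_flank is None

    def test_evidence_soundness(self, positive_bundle, small_target):
        bundle, _ = positive_bundle
        call = detect_fusion(bundle.bam, small_target)
        for ev in call.evidence:
            assert WINDOW_5P.contains(ev.breakpoint_pos)
            assert WINDOW_3P.start <= ev.read.mate_pos <= WINDOW_3P.end
            assert any(op == "S" for _, op in ev.read.cigar)

    def test_counts_match_naive_rescan(self, positive_bundle, small_target):
        bundle, _ = positive_bundle
        call = detect_fusion(bundle.bam, small_target)
        qnames = set()
        n_clip = 0
        with pysam.AlignmentFile(str(bundle.bam), "rb") as bam:
            for aln in bam.fetch(until_eof=True):
                if aln.flag & (0x4 | 0x8 | 0x100 | 0x200 | 0x400 | 0x800):
                    continue
                if not (
                    aln.reference_start + 1 <= WINDOW_5P.end
                    and aln.reference_end >= WINDOW_5P.start
                ):
                    continue
                if not (WINDOW_3P.start <= aln.next_reference_start + 1 <= WINDOW_3P.end):
                    continue
                qnames.add(aln.query_name)
                if "S" in aln.cigarstring:
                    n_clip += 1
        assert call.n_pairs == len(qnames)
        assert call.n_clip_reads == n_clip

    def test_determinism_identical_reports(self, positive_bundle, small_target):
        bundle, _ = positive_bundle
        first = detect_fusion(bundle.bam, small_target).to_dict()
        second = detect_fusion(bundle.bam, small_target).to_dict()
        assert first == second

    def test_raising_thresholds_never_creates_a_positive(
        self, negative_bundle, positive_bundle, small_target
    ):
        neg, _ = negative_bundle
        call = detect_fusion(neg.bam, small_target)
        assert call.status == "negative"
        stricter = make_target(min_pairs=5, min_clip_reads=5)
        assert detect_fusion(neg.bam, stricter).status == "negative"
        # and on a positive sample, stricter thresholds can only demote
        pos, _ = positive_bundle
        base = detect_fusion(pos.bam, small_target)
        huge = make_target(min_pairs=base.n_pairs + 1, min_clip_reads=base.n_clip_reads + 1)
        assert detect_fusion(pos.bam, huge).status == "negative"

    def test_lowering_thresholds_never_demotes(self, positive_bundle):
        pos, _ = positive_bundle
        lax = make_target(min_pairs=1, min_clip_reads=1)
        assert detect_fusion(pos.bam, lax).status == "positive"


def engineered_pairs_one_clip_bam(tmp_path):
    """Three discordant mate pairs, exactly one soft-clipped junction read."""
    records = []
    for i, (pos, cigar) in enumerate(
        [
            (3900, [(100, "M")]),
            (3920, [(100, "M")]),
            (3943, [(58, "M"), (42, "S")]),
        ]
    ):
        qlen = sum(l for l, op in cigar if op in "MIS=X")
        mate_pos = 11000 + 10 * i
        records.append(
            SamRecord(f"p{i}", "chr2", pos, cigar, "A" * qlen, False, True,
                      mate_chrom="chr2", mate_pos=mate_pos)
        )
        records.append(
            SamRecord(f"p{i}", "chr2", mate_pos, [(100, "M")], "A" * 100, True, False,
                      mate_chrom="chr2", mate_pos=pos)
        )
    return write_bam(records, {"chr2": 20000}, tmp_path / "engineered.bam")


class TestThresholdSemantics:
    def test_three_pairs_one_clip_negative_at_defaults(self, tmp_path):
        bam = engineered_pairs_one_clip_bam(tmp_path)
        call = detect_fusion(bam, make_target())
        assert call.status == "negative"
        assert call.n_pairs == 3
        assert call.n_clip_reads == 1
        assert call.evidence == []

    def test_same_sample_positive_when_min_clips_is_one(self, tmp_path):
        bam = engineered_pairs_one_clip_bam(tmp_path)
        call = detect_fusion(bam, make_target(min_clip_reads=1))
        assert call.status == "positive"
        assert call.consensus_breakpoint == 3943 + 58 - 1
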