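"""Fusion detection from soft-clipped reads with discordant mates.

The procedure for the built-in EML4-ALK target:

1. stream reads overlapping the EML4 window (flag-filtered);
2. keep reads whose mate maps inside the ALK window; the number of distinct
   read names among them is the mate-pair count;
3. among those candidates, reads with an "S" (soft clip) in the CIGAR span
   the genomic junction: the aligned part is EML4 sequence up to the
   breakpoint, the clipped part is ALK-derived sequence beyond it;
4. the sample is called positive when both the mate-pair count and the
   soft-clip count reach their thresholds (default 2 each);
5. for positive samples the breakpoint is the modal clip-adjacent position,
   consensus flanking sequences are reported for primer design, and the
   read depth at the breakpoint serves as a surrogate for ctDNA burden.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .alignment import (
    DEFAULT_POLICY,
    FlagPolicy,
    FusionRead,
    format_cigar,
    open_bam,
    resolve_chrom,
    stream_region_reads,
)
from .errors import DataError
from .targets import FusionTargetConfig, normalize_chrom

__all__ = [
    "ClipEvidence",
    "FusionCall",
    "select_mate_pairs",
    "count_mate_pairs",
    "identify_softclips",
    "infer_breakpoint",
    "five_prime_flank",
    "three_prime_flank",
    "breakpoint_depth",
    "detect_fusion",
    "write_report",
    "summary_row",
]


@dataclass(frozen=True)
class ClipEvidence:
    """One junction-spanning read: its used clip and inferred breakpoint.

    ``aligned_ref_bases`` maps each aligned reference position to the read
    base placed there (insertions skipped, deleted positions absent); it is
    what the flank consensus is built from.  ``clipped_seq`` holds the
    soft-clipped bases exactly as stored in the record.
    """

    read: FusionRead
    clip_end: str  # "left" | "right"
    clip_len: int
    breakpoint_pos: int
    aligned_tail: str
    clipped_seq: str
    aligned_ref_bases: dict[int, str] = field(repr=False, hash=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.clip_len < 1:
            raise ValueError("clip_len must be >= 1")
        if len(self.clipped_seq) != self.clip_len:
            raise ValueError("clipped_seq length must equal clip_len")

    @property
    def junction_adjacent_clip(self) -> str:
        """Clip bases ordered so index 0 is adjacent to the junction."""
        return self.clipped_seq if self.clip_end == "right" else self.clipped_seq[::-1]


@dataclass
class FusionCall:
    """The verdict for one sample."""

    status: str  # "positive" | "negative"
    n_pairs: int
    n_clip_reads: int
    breakpoint_table: dict[int, int] = field(default_factory=dict)
    consensus_breakpoint: int | None = None
    eml4_flank: str | None = None
    alk_flank: str | None = None
    breakpoint_depth: int | None = None
    evidence: list[ClipEvidence] = field(default_factory=list)

    @property
    def is_positive(self) -> bool:
        return self.status == "positive"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "n_pairs": self.n_pairs,
            "n_clip_reads": self.n_clip_reads,
            "breakpoint_table": {str(k): v for k, v in sorted(self.breakpoint_table.items())},
            "consensus_breakpoint": self.consensus_breakpoint,
            "five_prime_flank": self.eml4_flank,
            "three_prime_flank": self.alk_flank,
            "breakpoint_depth": self.breakpoint_depth,
            "evidence": [
                {
                    "qname": ev.read.qname,
                    "pos": ev.read.pos,
                    "cigar": format_cigar(list(ev.read.cigar)),
                    "clip_end": ev.clip_end,
                    "clip_len": ev.clip_len,
                    "breakpoint_pos": ev.breakpoint_pos,
                    "clipped_seq": ev.clipped_seq,
                }
                for ev in self.evidence
            ],
        }


def select_mate_pairs(
    reads: list[FusionRead] | "list", target: FusionTargetConfig
) -> list[FusionRead]:
    """Keep reads whose mate maps inside the 3' partner window.

    Input reads are assumed already restricted to the 5' partner window.
    Boundaries are inclusive on both sides.
    """
    three = target.three_prime
    want = normalize_chrom(three.chrom)
    return [
        r
        for r in reads
        if normalize_chrom(r.mate_chrom) == want and three.start <= r.mate_pos <= three.end
    ]


def count_mate_pairs(candidates: list[FusionRead]) -> int:
    """Distinct read names — a fragment is one pair however many records it has."""
    return len({r.qname for r in candidates})


def _aligned_ref_bases(read: FusionRead) -> dict[int, str]:
    """Reference position -> read base over the aligned part of the record."""
    out: dict[int, str] = {}
    ref = read.pos
    q = 0
    for length, op in read.cigar:
        if op in ("M", "=", "X"):
            for i in range(length):
                out[ref + i] = read.seq[q + i]
            ref += length
            q += length
        elif op == "I":
            q += length
        elif op == "S":
            q += length
        elif op in ("D", "N"):
            ref += length
        # H and P consume nothing
    return out


def _clip_slices(read: FusionRead) -> dict[str, tuple[int, int]]:
    """Query-coordinate slices of the leftmost and rightmost soft clips."""
    slices: dict[str, tuple[int, int]] = {}
    q = 0
    n_ops = len(read.cigar)
    for idx, (length, op) in enumerate(read.cigar):
        if op == "S":
            # a clip is terminal if only H ops separate it from the read end
            before = read.cigar[:idx]
            after = read.cigar[idx + 1 :]
            if all(o == "H" for _, o in before):
                slices["left"] = (q, q + length)
            elif all(o == "H" for _, o in after):
                slices["right"] = (q, q + length)
        if op in ("M", "I", "S", "=", "X"):
            q += length
    return slices


def identify_softclips(
    candidates: list[FusionRead], target: FusionTargetConfig
) -> list[ClipEvidence]:
    """One :class:`ClipEvidence` per candidate read carrying a soft clip.

    When both read ends are clipped the longer clip is used (junction clips
    dominate adapter/quality clips in length); equal lengths use the right
    end.  The breakpoint is the reference coordinate of the aligned base
    adjacent to the used clip.  Evidence whose breakpoint falls outside the
    5' window (edge-overlapping reads) is discarded so every reported
    breakpoint is a valid in-window coordinate.
    """
    evidence: list[ClipEvidence] = []
    for read in candidates:
        slices = _clip_slices(read)
        if not slices:
            continue
        if len(slices) == 2:
            left_len = slices["left"][1] - slices["left"][0]
            right_len = slices["right"][1] - slices["right"][0]
            end = "left" if left_len > right_len else "right"
        else:
            end = next(iter(slices))
        q0, q1 = slices[end]
        clip_len = q1 - q0
        if end == "right":
            breakpoint_pos = read.reference_end
        else:
            breakpoint_pos = read.pos
        if not target.five_prime.contains(breakpoint_pos):
            continue
        ref_bases = _aligned_ref_bases(read)
        aligned_tail = "".join(ref_bases[p] for p in sorted(ref_bases))
        evidence.append(
            ClipEvidence(
                read=read,
                clip_end=end,
                clip_len=clip_len,
                breakpoint_pos=breakpoint_pos,
                aligned_tail=aligned_tail,
                clipped_seq=read.seq[q0:q1],
                aligned_ref_bases=ref_bases,
            )
        )
    return evidence


def infer_breakpoint(evidence: list[ClipEvidence]) -> tuple[dict[int, int], int]:
    """Tally clip-adjacent positions; the consensus is the modal position.

    Ties break toward the smallest coordinate so the call is deterministic.
    """
    if not evidence:
        raise DataError("no junction-spanning reads: cannot infer a breakpoint")
    table = Counter(ev.breakpoint_pos for ev in evidence)
    consensus = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    return dict(table), consensus


def _column_consensus(bases: list[str]) -> str:
    """Majority base for one column; ties and empty columns give 'N'."""
    if not bases:
        return "N"
    counts = Counter(bases).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return "N"
    return counts[0][0]


def five_prime_flank(
    evidence: list[ClipEvidence], consensus: int, flank_len: int
) -> str:
    """Per-column majority consensus over aligned tails ending at the breakpoint.

    Covers reference positions ``[consensus - flank_len + 1, consensus]``,
    left to right; only evidence whose breakpoint equals the consensus
    contributes, and uncovered or tied columns emit 'N'.
    """
    used = [ev for ev in evidence if ev.breakpoint_pos == consensus]
    out = []
    for pos in range(consensus - flank_len + 1, consensus + 1):
        bases = [ev.aligned_ref_bases[pos] for ev in used if pos in ev.aligned_ref_bases]
        out.append(_column_consensus(bases))
    return "".join(out)


def three_prime_flank(
    evidence: list[ClipEvidence], consensus: int, flank_len: int
) -> str:
    """Per-column majority consensus over the clipped (partner-gene) bases.

    Column 0 is the clipped base adjacent to the junction.  The output is
    ``min(flank_len, longest clip)`` long; columns some clips do not reach
    use only the clips that do.
    """
    used = [ev for ev in evidence if ev.breakpoint_pos == consensus]
    if not used or flank_len == 0:
        return ""
    length = min(flank_len, max(ev.clip_len for ev in used))
    out = []
    for col in range(length):
        bases = [
            ev.junction_adjacent_clip[col] for ev in used if col < ev.clip_len
        ]
        out.append(_column_consensus(bases))
    return "".join(out)


def breakpoint_depth(
    bam: pysam.AlignmentFile | str | Path,
    target: FusionTargetConfig,
    consensus: int,
    policy: FlagPolicy = DEFAULT_POLICY,
) -> int:
    """Read depth at the 5'-gene breakpoint — the ctDNA-burden surrogate.

    Counts filter-passing records whose aligned span covers the consensus
    position through an M, D, = or X op; N (skipped region) does not count
    as coverage.
    """
    if consensus is None:
        raise DataError("breakpoint depth requires a consensus breakpoint")
    own = not isinstance(bam, pysam.AlignmentFile)
    handle = open_bam(bam) if own else bam
    try:
        contig = resolve_chrom(handle, target.five_prime.chrom)
        depth = 0
        for aln in handle.fetch(contig, consensus - 1, consensus):
            if not policy.passes(aln):
                continue
            ref = aln.reference_start + 1
            covered = False
            for code, length in aln.cigartuples:
                op = "MIDNSHP=X"[code]
                if op in ("M", "D", "=", "X"):
                    if ref <= consensus <= ref + length - 1:
                        covered = True
                        break
                    ref += length
                elif op == "N":
                    ref += length
            if covered:
                depth += 1
        return depth
    finally:
        if own:
            handle.close()


def detect_fusion(
    bam: str | Path | pysam.AlignmentFile,
    target: FusionTargetConfig,
    policy: FlagPolicy = DEFAULT_POLICY,
) -> FusionCall:
    """Run the full detection procedure on one sample.

    Positive iff the distinct mate-pair count reaches ``min_pairs`` and the
    soft-clip count reaches ``min_clip_reads``.  Negative calls carry the
    counts but no evidence or characterization; fusion-free input is never
    an error.
    """
    own = not isinstance(bam, pysam.AlignmentFile)
    handle = open_bam(bam) if own else bam
    try:
        reads = list(stream_region_reads(handle, target.five_prime, policy))
        candidates = select_mate_pairs(reads, target)
        n_pairs = count_mate_pairs(candidates)
        evidence = identify_softclips(candidates, target)
        n_clip = len(evidence)
        if n_pairs >= target.min_pairs and n_clip >= target.min_clip_reads:
            table, consensus = infer_breakpoint(evidence)
            call = FusionCall(
                status="positive",
                n_pairs=n_pairs,
                n_clip_reads=n_clip,
                breakpoint_table=table,
                consensus_breakpoint=consensus,
                eml4_flank=five_prime_flank(evidence, consensus, target.flank_len),
                alk_flank=three_prime_flank(evidence, consensus, target.flank_len),
                breakpoint_depth=breakpoint_depth(handle, target, consensus, policy),
                evidence=evidence,
            )
        else:
            # mirrors the empty-result contract: a negative sample reports
            # counts only, with an empty evidence set
            call = FusionCall(status="negative", n_pairs=n_pairs, n_clip_reads=n_clip)
        return call
    finally:
        if own:
            handle.close()


def write_report(call: FusionCall, path: str | Path) -> None:
    """Write the machine-readable JSON report for one sample."""
    Path(path).write_text(json.dumps(call.to_dict(), indent=2, sort_keys=False) + "\n")


SUMMARY_COLUMNS = [
    "sample_id",
    "status",
    "n_pairs",
    "n_clip_reads",
    "consensus_breakpoint",
    "breakpoint_depth",
]


def summary_row(sample_id: str, call: FusionCall) -> dict:
    """One-line summary suitable for cohort TSV concatenation."""
    return {
        "sample_id": sample_id,
        "status": call.status,
        "n_pairs": call.n_pairs,
        "n_clip_reads": call.n_clip_reads,
        "consensus_breakpoint": call.consensus_breakpoint if call.is_positive else "",
        "breakpoint_depth": call.breakpoint_depth if call.is_positive else "",
    }
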