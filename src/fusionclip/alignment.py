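"""BAM streaming, flag filtering, and CIGAR parsing.

Detection never touches pysam objects directly: records are reduced to
:class:`FusionRead`, which carries exactly the fields the algorithm needs.
The default flag policy drops unmapped, mate-unmapped, secondary,
supplementary, QC-fail and duplicate records — inputs are modeled as
position-deduplicated BAMs, and split-alignment artifacts must not inflate
evidence counts.  No mapping-quality cutoff is applied by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .errors import DataError, MissingIndexError
from .targets import GeneRegion, chrom_aliases

__all__ = [
    "CIGAR_OPS",
    "QUERY_OPS",
    "REF_OPS",
    "parse_cigar",
    "format_cigar",
    "cigar_has_softclip",
    "reference_length",
    "FusionRead",
    "FlagPolicy",
    "DEFAULT_POLICY",
    "open_bam",
    "stream_region_reads",
]

CIGAR_OPS = "MIDNSHP=X"
#: ops that consume the query sequence
QUERY_OPS = frozenset("MIS=X")
#: ops that consume the reference (the aligned span used for overlap)
REF_OPS = frozenset("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar_text: str) -> list[tuple[int, str]]:
    """Parse a SAM CIGAR string into an ordered ``(length, op)`` list."""
    if not cigar_text or cigar_text == "*":
        raise ValueError(f"cannot parse CIGAR {cigar_text!r}")
    pos = 0
    out: list[tuple[int, str]] = []
    for match in _CIGAR_RE.finditer(cigar_text):
        if match.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
        length = int(match.group(1))
        if length < 1:
            raise ValueError(f"zero-length op in CIGAR {cigar_text!r}")
        out.append((length, match.group(2)))
        pos = match.end()
    if pos != len(cigar_text):
        raise ValueError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
    return out


def format_cigar(ops: list[tuple[int, str]]) -> str:
    return "".join(f"{length}{op}" for length, op in ops)


def cigar_has_softclip(ops: list[tuple[int, str]]) -> bool:
    return any(op == "S" for _, op in ops)


def reference_length(ops: list[tuple[int, str]]) -> int:
    """Number of reference bases consumed by the alignment (M, D, N, =, X)."""
    return sum(length for length, op in ops if op in REF_OPS)


@dataclass(frozen=True)
class FusionRead:
    """One alignment record reduced to the fields detection needs.

    ``pos`` and ``mate_pos`` are 1-based leftmost coordinates.
    """

    qname: str
    chrom: str
    pos: int
    cigar: tuple[tuple[int, str], ...]
    seq: str
    mate_chrom: str
    mate_pos: int
    is_reverse: bool = False
    mate_is_reverse: bool = False
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"read {self.qname}: pos must be >= 1")
        qlen = sum(length for length, op in self.cigar if op in QUERY_OPS)
        if qlen != len(self.seq):
            raise ValueError(
                f"read {self.qname}: CIGAR query length {qlen} != SEQ length {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + reference_length(list(self.cigar)) - 1

    @property
    def has_softclip(self) -> bool:
        return cigar_has_softclip(list(self.cigar))

    def overlaps(self, region: GeneRegion) -> bool:
        from .targets import normalize_chrom

        return (
            normalize_chrom(self.chrom) == normalize_chrom(region.chrom)
            and self.pos <= region.end
            and self.reference_end >= region.start
        )


@dataclass(frozen=True)
class FlagPolicy:
    """Which records are admitted into the evidence stream."""

    exclude_unmapped: bool = True
    exclude_mate_unmapped: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True
    exclude_duplicate: bool = True
    min_mapq: int = 0

    def passes(self, aln: pysam.AlignedSegment) -> bool:
        if self.exclude_unmapped and aln.is_unmapped:
            return False
        if self.exclude_mate_unmapped and (not aln.is_paired or aln.mate_is_unmapped):
            return False
        if self.exclude_secondary and aln.is_secondary:
            return False
        if self.exclude_supplementary and aln.is_supplementary:
            return False
        if self.exclude_qcfail and aln.is_qcfail:
            return False
        if self.exclude_duplicate and aln.is_duplicate:
            return False
        if aln.mapping_quality < self.min_mapq:
            return False
        return True


DEFAULT_POLICY = FlagPolicy()


def _to_fusion_read(aln: pysam.AlignedSegment) -> FusionRead:
    return FusionRead(
        qname=aln.query_name,
        chrom=aln.reference_name,
        pos=aln.reference_start + 1,
        cigar=tuple((length, CIGAR_OPS[code]) for code, length in aln.cigartuples),
        seq=aln.query_sequence or "",
        mate_chrom=aln.next_reference_name or "",
        mate_pos=aln.next_reference_start + 1,
        is_reverse=aln.is_reverse,
        mate_is_reverse=aln.mate_is_reverse,
        mapq=aln.mapping_quality,
    )


def open_bam(path: str | Path, require_index: bool = True) -> pysam.AlignmentFile:
    """Open a coordinate-sorted BAM, insisting on a BAI index by default."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"BAM file not found: {path}")
    bam = pysam.AlignmentFile(str(path), "rb")
    if require_index and not bam.has_index():
        bam.close()
        raise MissingIndexError(
            f"{path} has no index; create one with `samtools index {path}` "
            "(or pysam.index) before running detection"
        )
    return bam


def resolve_chrom(bam: pysam.AlignmentFile, chrom: str) -> str:
    """Reconcile the "chr2" / "2" naming dialects against the BAM header."""
    for candidate in chrom_aliases(chrom):
        if candidate in bam.references:
            return candidate
    raise DataError(
        f"chromosome {chrom!r} absent from BAM header under either naming "
        f"dialect (tried {', '.join(chrom_aliases(chrom))})"
    )


def stream_region_reads(
    bam: pysam.AlignmentFile | str | Path,
    region: GeneRegion,
    policy: FlagPolicy = DEFAULT_POLICY,
) -> Iterator[FusionRead]:
    """Yield filter-passing reads whose aligned span overlaps ``region``.

    Overlap is on the reference-consuming span (M, D, N, =, X).  The BAM
    must be coordinate-sorted and indexed.
    """
    own = not isinstance(bam, pysam.AlignmentFile)
    handle = open_bam(bam) if own else bam
    try:
        contig = resolve_chrom(handle, region.chrom)
        for aln in handle.fetch(contig, region.start - 1, region.end):
            if not policy.passes(aln):
                continue
            yield _to_fusion_read(aln)
    finally:
        if own:
            handle.close()
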