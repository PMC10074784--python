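"""Ground-truthed synthetic capture-NGS BAMs emulating cfDNA plasma samples.

The generator emulates the sequencing geometry the detector is built for:
cfDNA fragments of ~165 bp (sd 10) sequenced as 100 bp paired-end reads.
A fusion-positive sample carries fragments drawn from a junction template
that joins the 5' gene's sequence up to its breakpoint to the reverse
complement of the 3' gene's sequence at its breakpoint (the EML4/ALK
opposite-strand inversion), on top of wild-type background fragments over
both gene windows.

The simulator is its own aligner: reads falling entirely within one gene
segment are emitted fully aligned; reads spanning the junction are emitted
with the anchored side as M ops and the partner side as a terminal soft
clip adjacent to the junction, mirroring how a local aligner treats
fusion-spanning reads.  ``min_anchor`` (default 20 bp) approximates the
minimum aligned length a real aligner needs to place a read.  Every sample
comes with a machine-readable truth record naming the junction-carrying
reads, so each detection stage can be verified against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigError, DataError
from .targets import GeneRegion, builtin_target

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimBundle",
    "SamRecord",
    "FusionTemplate",
    "revcomp",
    "synth_references",
    "make_fusion_template",
    "sample_fragments",
    "oracle_align",
    "simulate_sample",
    "write_bam",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_five() -> GeneRegion:
    return builtin_target("EML4-ALK", "hg38").five_prime


def _default_three() -> GeneRegion:
    return builtin_target("EML4-ALK", "hg38").three_prime


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic plasma sample."""

    seed: int = 0
    five_prime_window: GeneRegion = field(default_factory=_default_five)
    three_prime_window: GeneRegion = field(default_factory=_default_three)
    breakpoint_5p: int | None = None  # default: window midpoint
    breakpoint_3p: int | None = None
    fusion_fragments: int = 0
    wildtype_depth: float = 30.0
    frag_len_mean: float = 165.0
    frag_len_sd: float = 10.0
    read_len: int = 100
    error_rate: float = 0.0
    min_anchor: int = 20

    def __post_init__(self) -> None:
        if self.fusion_fragments < 0:
            raise ConfigError("fusion_fragments must be >= 0")
        if self.wildtype_depth < 0:
            raise ConfigError("wildtype_depth must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.min_anchor < 1:
            raise ConfigError("min_anchor must be >= 1")
        if self.read_len < 1:
            raise ConfigError("read_len must be >= 1")
        if self.frag_len_mean <= 0 or self.frag_len_sd < 0:
            raise ConfigError("fragment length parameters must be positive")

    @property
    def resolved_breakpoint_5p(self) -> int:
        w = self.five_prime_window
        return self.breakpoint_5p if self.breakpoint_5p is not None else (w.start + w.end) // 2

    @property
    def resolved_breakpoint_3p(self) -> int:
        w = self.three_prime_window
        return self.breakpoint_3p if self.breakpoint_3p is not None else (w.start + w.end) // 2

    @property
    def min_window_len(self) -> int:
        return int(math.ceil(2 * (self.frag_len_mean + self.read_len)))


@dataclass
class TruthRecord:
    """Ground truth for one synthetic sample."""

    fusion_present: bool
    breakpoint_5p: int | None
    breakpoint_3p: int | None
    junction_read_ids: list[str]
    eml4_junction_qnames: list[str]
    pair_ids: list[str]
    five_prime_seq: str
    three_prime_seq: str
    windows: dict

    def to_dict(self) -> dict:
        return {
            "fusion_present": self.fusion_present,
            "breakpoint_5p": self.breakpoint_5p,
            "breakpoint_3p": self.breakpoint_3p,
            "junction_read_ids": sorted(self.junction_read_ids),
            "eml4_junction_qnames": sorted(self.eml4_junction_qnames),
            "pair_ids": sorted(self.pair_ids),
            "five_prime_seq": self.five_prime_seq,
            "three_prime_seq": self.three_prime_seq,
            "windows": self.windows,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        doc = json.loads(Path(path).read_text())
        return cls(
            fusion_present=doc["fusion_present"],
            breakpoint_5p=doc["breakpoint_5p"],
            breakpoint_3p=doc["breakpoint_3p"],
            junction_read_ids=doc["junction_read_ids"],
            eml4_junction_qnames=doc["eml4_junction_qnames"],
            pair_ids=doc["pair_ids"],
            five_prime_seq=doc["five_prime_seq"],
            three_prime_seq=doc["three_prime_seq"],
            windows=doc["windows"],
        )


@dataclass(frozen=True)
class SimBundle:
    bam: Path
    bai: Path
    fasta: Path
    truth_json: Path
    truth: TruthRecord


def synth_references(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, str]:
    """Uniform-random reference sequences for the two configured windows.

    Windows must be at least ``2 * (frag_len_mean + read_len)`` long so
    fragments fit with room on both sides of a central breakpoint.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    min_len = config.min_window_len
    for name, window in (
        ("five_prime_window", config.five_prime_window),
        ("three_prime_window", config.three_prime_window),
    ):
        if len(window) < min_len:
            raise ConfigError(
                f"{name} is {len(window)} bp; the simulator needs at least "
                f"{min_len} bp (2 x (frag_len_mean + read_len))"
            )
    bases = np.array(list("ACGT"))
    seq5 = "".join(rng.choice(bases, size=len(config.five_prime_window)))
    seq3 = "".join(rng.choice(bases, size=len(config.three_prime_window)))
    return seq5, seq3


@dataclass(frozen=True)
class FusionTemplate:
    """The fused contig: 5' gene up to its breakpoint, then the reverse
    complement of the 3' gene down from its breakpoint."""

    seq: str
    junction_index: int  # template offset of the last 5'-gene base
    five_window: GeneRegion
    three_window: GeneRegion
    breakpoint_5p: int
    breakpoint_3p: int

    def offset_to_locus(self, offset: int) -> tuple[str, int]:
        if not (0 <= offset < len(self.seq)):
            raise ValueError(f"template offset {offset} out of range")
        if offset <= self.junction_index:
            return ("five", self.five_window.start + offset)
        return ("three", self.breakpoint_3p - (offset - self.junction_index - 1))

    def locus_to_offset(self, gene: str, pos: int) -> int:
        if gene == "five":
            offset = pos - self.five_window.start
            if not (0 <= offset <= self.junction_index):
                raise ValueError(f"position {pos} not on the template's 5' segment")
            return offset
        if gene == "three":
            offset = self.junction_index + 1 + (self.breakpoint_3p - pos)
            if not (self.junction_index < offset < len(self.seq)):
                raise ValueError(f"position {pos} not on the template's 3' segment")
            return offset
        raise ValueError(f"unknown gene tag {gene!r}")


def make_fusion_template(config: SimConfig, seq5: str, seq3: str) -> FusionTemplate:
    bp5, bp3 = config.resolved_breakpoint_5p, config.resolved_breakpoint_3p
    w5, w3 = config.five_prime_window, config.three_prime_window
    if not w5.contains(bp5):
        raise ConfigError(f"breakpoint_5p {bp5} outside window {w5.start}-{w5.end}")
    if not w3.contains(bp3):
        raise ConfigError(f"breakpoint_3p {bp3} outside window {w3.start}-{w3.end}")
    a_part = seq5[: bp5 - w5.start + 1]
    b_part = revcomp(seq3[: bp3 - w3.start + 1])
    return FusionTemplate(
        seq=a_part + b_part,
        junction_index=len(a_part) - 1,
        five_window=w5,
        three_window=w3,
        breakpoint_5p=bp5,
        breakpoint_3p=bp3,
    )


def _draw_lengths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fragment lengths: normal(mean, sd) truncated to [read_len/2, 2*mean]."""
    if n == 0:
        return np.zeros(0, dtype=int)
    lo = config.read_len / 2
    hi = 2 * config.frag_len_mean
    if config.frag_len_sd == 0:
        return np.full(n, int(round(config.frag_len_mean)), dtype=int)
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.normal(config.frag_len_mean, config.frag_len_sd, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return np.maximum(np.rint(out).astype(int), 1)


@dataclass(frozen=True)
class FragmentSet:
    """Fragment intervals: template coordinates for fusion fragments,
    0-based window offsets for wild-type fragments."""

    fusion: list[tuple[int, int]]  # (start offset, length) on the template
    wildtype_five: list[tuple[int, int]]
    wildtype_three: list[tuple[int, int]]


def sample_fragments(
    config: SimConfig,
    template: FusionTemplate | None,
    rng: np.random.Generator,
) -> FragmentSet:
    """Draw fragment placements.

    Fusion fragment midpoints are uniform over a span of one mean fragment
    length on either side of the junction, so a calculable fraction of them
    covers the junction.  Wild-type fragments are placed uniformly over each
    window at a count chosen to hit ``wildtype_depth`` in expectation.
    """
    fusion: list[tuple[int, int]] = []
    if config.fusion_fragments > 0:
        if template is None:
            raise DataError("fusion fragments requested but no template given")
        lengths = _draw_lengths(config.fusion_fragments, config, rng)
        span = int(round(config.frag_len_mean))
        mids = rng.integers(
            template.junction_index - span,
            template.junction_index + span + 1,
            size=config.fusion_fragments,
        )
        for mid, length in zip(mids, lengths):
            start = int(mid) - int(length) // 2
            start = max(0, min(start, len(template.seq) - int(length)))
            fusion.append((start, int(length)))

    def _wildtype(window: GeneRegion) -> list[tuple[int, int]]:
        wlen = len(window)
        n = int(round(config.wildtype_depth * wlen / (2 * config.read_len)))
        lengths = _draw_lengths(n, config, rng)
        out = []
        for length in lengths:
            length = int(min(length, wlen))
            start = int(rng.integers(0, wlen - length + 1))
            out.append((start, length))
        return out

    return FragmentSet(
        fusion=fusion,
        wildtype_five=_wildtype(config.five_prime_window),
        wildtype_three=_wildtype(config.three_prime_window),
    )


@dataclass
class SamRecord:
    """A fully specified alignment record ready to be written to BAM."""

    qname: str
    chrom: str
    pos: int  # 1-based leftmost
    cigar: list[tuple[int, str]]
    seq: str
    is_reverse: bool
    is_read1: bool
    mate_chrom: str = ""
    mate_pos: int = 0
    mate_is_reverse: bool = False
    mapq: int = 60
    is_proper_pair: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_qcfail: bool = False
    tlen: int = 0
    # simulator bookkeeping, not written to the file
    gene: str = ""
    is_junction: bool = False

    @property
    def reference_end(self) -> int:
        return self.pos + sum(l for l, op in self.cigar if op in "MDN=X") - 1

    @property
    def read_id(self) -> str:
        return f"{self.qname}/{1 if self.is_read1 else 2}"


def _reads_of_fragment(start: int, length: int, read_len: int) -> list[tuple[int, int, bool]]:
    """(interval start, interval end, is_read1) for the two reads of a fragment.

    Read 1 is sequenced template-forward from the fragment start, read 2
    template-reverse from the fragment end; short fragments give
    overlapping (or identical) mate intervals.
    """
    end = start + length - 1
    r1 = (start, min(end, start + read_len - 1), True)
    r2 = (max(start, end - read_len + 1), end, False)
    return [r1, r2]


def oracle_align(
    fragment: tuple[int, int],
    template: FusionTemplate,
    config: SimConfig,
    qname: str,
) -> list[SamRecord]:
    """Emit the aligner's-eye view of one fusion-template fragment.

    A read wholly inside one gene segment aligns fully to that gene.  A
    junction-spanning read anchors on the side with >= ``min_anchor``
    template bases (the longer side when both or neither qualify, ties to
    the 5' gene) and carries the other side as a terminal soft clip placed
    adjacent to the junction.
    """
    start, length = fragment
    jidx = template.junction_index
    records = []
    for t0, t1, is_read1 in _reads_of_fragment(start, length, config.read_len):
        n_five = max(0, min(t1, jidx) - t0 + 1)
        n_three = max(0, t1 - max(t0, jidx + 1) + 1)
        sub = template.seq[t0 : t1 + 1]
        if n_three == 0:  # wholly in the 5' gene: forward-strand segment
            rec = SamRecord(
                qname=qname,
                chrom=template.five_window.chrom,
                pos=template.five_window.start + t0,
                cigar=[(len(sub), "M")],
                seq=sub,
                is_reverse=not is_read1,
                is_read1=is_read1,
                gene="five",
            )
        elif n_five == 0:  # wholly in the 3' gene: minus-strand segment
            rec = SamRecord(
                qname=qname,
                chrom=template.three_window.chrom,
                pos=template.breakpoint_3p - (t1 - jidx - 1),
                cigar=[(len(sub), "M")],
                seq=revcomp(sub),
                is_reverse=is_read1,
                is_read1=is_read1,
                gene="three",
            )
        else:  # junction-spanning
            five_ok = n_five >= config.min_anchor
            three_ok = n_three >= config.min_anchor
            if five_ok != three_ok:
                anchor_five = five_ok
            else:
                anchor_five = n_five >= n_three
            if anchor_five:
                rec = SamRecord(
                    qname=qname,
                    chrom=template.five_window.chrom,
                    pos=template.five_window.start + t0,
                    cigar=[(n_five, "M"), (n_three, "S")],
                    seq=sub,
                    is_reverse=not is_read1,
                    is_read1=is_read1,
                    gene="five",
                    is_junction=True,
                )
            else:
                rec = SamRecord(
                    qname=qname,
                    chrom=template.three_window.chrom,
                    pos=template.breakpoint_3p - n_three + 1,
                    cigar=[(n_three, "M"), (n_five, "S")],
                    seq=revcomp(sub),
                    is_reverse=is_read1,
                    is_read1=is_read1,
                    gene="three",
                    is_junction=True,
                )
        records.append(rec)
    return records


def _wildtype_records(
    fragment: tuple[int, int],
    window: GeneRegion,
    seq: str,
    gene: str,
    config: SimConfig,
    qname: str,
) -> list[SamRecord]:
    start, length = fragment
    records = []
    for t0, t1, is_read1 in _reads_of_fragment(start, length, config.read_len):
        records.append(
            SamRecord(
                qname=qname,
                chrom=window.chrom,
                pos=window.start + t0,
                cigar=[(t1 - t0 + 1, "M")],
                seq=seq[t0 : t1 + 1],
                is_reverse=not is_read1,
                is_read1=is_read1,
                gene=gene,
            )
        )
    return records


def _inject_errors(records: list[SamRecord], config: SimConfig, rng: np.random.Generator) -> None:
    if config.error_rate == 0:
        return
    bases = "ACGT"
    for rec in records:
        hits = np.flatnonzero(rng.random(len(rec.seq)) < config.error_rate)
        if hits.size == 0:
            continue
        seq = list(rec.seq)
        for i in hits:
            alternatives = bases.replace(seq[i], "")
            seq[i] = alternatives[int(rng.integers(len(alternatives)))]
        rec.seq = "".join(seq)


def _set_mate_fields(pair: list[SamRecord]) -> None:
    for rec, mate in ((pair[0], pair[1]), (pair[1], pair[0])):
        rec.mate_chrom = mate.chrom
        rec.mate_pos = mate.pos
        rec.mate_is_reverse = mate.is_reverse
    a, b = pair
    if a.chrom == b.chrom:
        left = min(a.pos, b.pos)
        right = max(a.reference_end, b.reference_end)
        span = right - left + 1
        a.tlen = span if a.pos <= b.pos else -span
        b.tlen = -a.tlen
    else:
        a.tlen = b.tlen = 0
    # an aligner marks concordant same-gene pairs proper; discordant
    # cross-gene pairs (the fusion evidence) are left anomalous
    proper = a.gene == b.gene and a.gene != ""
    a.is_proper_pair = b.is_proper_pair = proper


_FLAG_PAIRED = 0x1
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def write_bam(records: list[SamRecord], chrom_lengths: dict[str, int], path: str | Path) -> Path:
    """Write records as a coordinate-sorted, indexed BAM; returns the path."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    tid = {name: i for i, name in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in sorted(records, key=lambda r: (tid[r.chrom], r.pos, r.qname, not r.is_read1)):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = rec.qname
            flag = _FLAG_PAIRED
            if rec.is_proper_pair:
                flag |= 0x2
            if rec.is_reverse:
                flag |= _FLAG_REVERSE
            if rec.mate_is_reverse:
                flag |= _FLAG_MATE_REVERSE
            flag |= _FLAG_READ1 if rec.is_read1 else _FLAG_READ2
            if rec.is_duplicate:
                flag |= 0x400
            if rec.is_secondary:
                flag |= 0x100
            if rec.is_supplementary:
                flag |= 0x800
            if rec.is_qcfail:
                flag |= 0x200
            aln.flag = flag
            aln.reference_id = tid[rec.chrom]
            aln.reference_start = rec.pos - 1
            aln.mapping_quality = rec.mapq
            aln.cigarstring = "".join(f"{l}{op}" for l, op in rec.cigar)
            aln.query_sequence = rec.seq
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            aln.next_reference_id = tid.get(rec.mate_chrom, -1)
            aln.next_reference_start = rec.mate_pos - 1 if rec.mate_pos else -1
            aln.template_length = rec.tlen
            out.write(aln)
    pysam.index(str(path))
    return path


def write_fasta(entries: list[tuple[str, str, str]], path: str | Path) -> Path:
    """Write (id, description, sequence) triples as wrapped FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, desc, seq in entries:
            fh.write(f">{name} {desc}\n" if desc else f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def simulate_sample(config: SimConfig, out_prefix: str | Path) -> SimBundle:
    """Generate one synthetic sample: BAM + BAI, reference FASTA, truth JSON.

    All randomness flows from a single generator seeded with
    ``config.seed``, so a given configuration reproduces byte-identical
    truth output.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seq5, seq3 = synth_references(config, rng)
    w5, w3 = config.five_prime_window, config.three_prime_window

    template = None
    if config.fusion_fragments > 0:
        template = make_fusion_template(config, seq5, seq3)
    frags = sample_fragments(config, template, rng)

    records: list[SamRecord] = []
    pairs: list[list[SamRecord]] = []
    for i, frag in enumerate(frags.fusion):
        pair = oracle_align(frag, template, config, qname=f"fus{i:06d}")
        pairs.append(pair)
    for i, frag in enumerate(frags.wildtype_five):
        pairs.append(_wildtype_records(frag, w5, seq5, "five", config, qname=f"wt5_{i:06d}"))
    for i, frag in enumerate(frags.wildtype_three):
        pairs.append(_wildtype_records(frag, w3, seq3, "three", config, qname=f"wt3_{i:06d}"))
    for pair in pairs:
        _set_mate_fields(pair)
        records.extend(pair)
    _inject_errors(records, config, rng)

    junction_ids = [r.read_id for r in records if r.is_junction]
    eml4_junction = sorted(
        {
            rec.qname
            for pair in pairs
            for rec, mate in ((pair[0], pair[1]), (pair[1], pair[0]))
            if rec.is_junction and rec.gene == "five" and mate.gene == "three"
        }
    )
    pair_ids = sorted({p[0].qname for p in pairs if p[0].gene != p[1].gene})
    truth = TruthRecord(
        fusion_present=config.fusion_fragments > 0,
        breakpoint_5p=config.resolved_breakpoint_5p if template else None,
        breakpoint_3p=config.resolved_breakpoint_3p if template else None,
        junction_read_ids=junction_ids,
        eml4_junction_qnames=eml4_junction,
        pair_ids=pair_ids,
        five_prime_seq=seq5,
        three_prime_seq=seq3,
        windows={
            "five_prime": {"chrom": w5.chrom, "start": w5.start, "end": w5.end},
            "three_prime": {"chrom": w3.chrom, "start": w3.start, "end": w3.end},
        },
    )

    chrom_lengths: dict[str, int] = {}
    for w in (w5, w3):
        chrom_lengths[w.chrom] = max(chrom_lengths.get(w.chrom, 0), w.end + 1000)
    bam_path = write_bam(records, chrom_lengths, out_prefix.with_suffix(".bam"))
    fasta_path = write_fasta(
        [
            ("five_prime", f"{w5.chrom}:{w5.start}-{w5.end}", seq5),
            ("three_prime", f"{w3.chrom}:{w3.start}-{w3.end}", seq3),
        ],
        out_prefix.with_suffix(".fasta"),
    )
    truth_path = out_prefix.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return SimBundle(
        bam=bam_path,
        bai=Path(str(bam_path) + ".bai"),
        fasta=fasta_path,
        truth_json=truth_path,
        truth=truth,
    )
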