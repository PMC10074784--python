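"""Genomic target windows and detection thresholds.

A fusion target is a pair of gene windows on the reference genome: reads
aligned inside the 5' partner window (EML4 for the built-in target) are
scanned, and a read is fusion evidence when its mate maps inside the 3'
partner window (ALK).  Thresholds on mate-pair and soft-clip counts decide
the final call.  All coordinates at this interface are 1-based inclusive,
matching the SAM text convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

from .errors import ConfigError

__all__ = [
    "GeneRegion",
    "FusionTargetConfig",
    "builtin_target",
    "load_target_config",
    "normalize_chrom",
    "chrom_aliases",
]


def normalize_chrom(name: str) -> str:
    """Canonical chromosome name for comparisons ("chr2" and "2" are equal)."""
    return name[3:] if name.lower().startswith("chr") else name


def chrom_aliases(name: str) -> tuple[str, ...]:
    """The configured name first, then its alternate dialect form."""
    if name.lower().startswith("chr"):
        return (name, name[3:])
    return (name, "chr" + name)


@dataclass(frozen=True)
class GeneRegion:
    """A 1-based inclusive genomic window; strand is annotation only."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ConfigError(f"region {self.label or '?'}: chrom must be non-empty")
        if self.start < 1:
            raise ConfigError(f"region {self.label or self.chrom}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ConfigError(
                f"region {self.label or self.chrom}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ConfigError(f"region {self.label or self.chrom}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GeneRegion") -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(other.chrom)
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class FusionTargetConfig:
    """Windows plus thresholds that parameterize fusion detection.

    min_pairs / min_clip_reads are the published defaults (2 each);
    flank_len is how many bases are reported on each side of the called
    breakpoint for primer design.
    """

    name: str
    build: str
    five_prime: GeneRegion
    three_prime: GeneRegion
    min_pairs: int = 2
    min_clip_reads: int = 2
    flank_len: int = 20

    def __post_init__(self) -> None:
        if self.min_pairs < 1:
            raise ConfigError(f"min_pairs must be >= 1, got {self.min_pairs}")
        if self.min_clip_reads < 1:
            raise ConfigError(f"min_clip_reads must be >= 1, got {self.min_clip_reads}")
        if self.flank_len < 0:
            raise ConfigError(f"flank_len must be >= 0, got {self.flank_len}")
        if self.five_prime.overlaps(self.three_prime):
            raise ConfigError("five_prime and three_prime windows overlap")

    def with_thresholds(
        self,
        min_pairs: int | None = None,
        min_clip_reads: int | None = None,
        flank_len: int | None = None,
    ) -> "FusionTargetConfig":
        """Copy with some thresholds replaced (used by the CLI flags)."""
        kwargs = {}
        if min_pairs is not None:
            kwargs["min_pairs"] = min_pairs
        if min_clip_reads is not None:
            kwargs["min_clip_reads"] = min_clip_reads
        if flank_len is not None:
            kwargs["flank_len"] = flank_len
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "FusionTargetConfig":
        required = ("name", "build", "five_prime", "three_prime")
        for key in required:
            if key not in doc:
                raise ConfigError(f"target config: missing field '{key}'")
        regions = {}
        for key in ("five_prime", "three_prime"):
            sub = doc[key]
            if not isinstance(sub, dict):
                raise ConfigError(f"target config: field '{key}' must be an object")
            for rkey in ("chrom", "start", "end"):
                if rkey not in sub:
                    raise ConfigError(f"target config: {key} is missing field '{rkey}'")
            try:
                regions[key] = GeneRegion(
                    chrom=sub["chrom"],
                    start=int(sub["start"]),
                    end=int(sub["end"]),
                    strand=sub.get("strand", "+"),
                    label=sub.get("label", ""),
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"target config: {key}: {exc}") from exc
        try:
            return cls(
                name=doc["name"],
                build=doc["build"],
                five_prime=regions["five_prime"],
                three_prime=regions["three_prime"],
                min_pairs=int(doc.get("min_pairs", 2)),
                min_clip_reads=int(doc.get("min_clip_reads", 2)),
                flank_len=int(doc.get("flank_len", 20)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"target config: {exc}") from exc


def _builtin_table() -> dict:
    with resources.files("fusionclip.data").joinpath("targets.json").open() as fh:
        return json.load(fh)


def builtin_target(name: str = "EML4-ALK", build: str = "hg38") -> FusionTargetConfig:
    """A validated built-in target configuration.

    ``builtin_target("EML4-ALK", "hg38")`` returns the published windows
    (EML4 chr2:42,169,353-42,332,548 scanned; mates required in ALK
    chr2:29,192,774-29,921,586) with the default thresholds of 2 mate pairs
    and 2 soft-clipped reads.  hg19 windows are liftover-derived and shipped
    as package data.
    """
    table = _builtin_table()
    if name not in table:
        raise ConfigError(
            f"unknown target '{name}'; supported targets: {', '.join(sorted(table))}"
        )
    builds = table[name]
    if build not in builds:
        raise ConfigError(
            f"unknown build '{build}' for target '{name}'; "
            f"supported builds: {', '.join(sorted(builds))}"
        )
    doc = dict(builds[build])
    doc.update(name=name, build=build)
    doc.pop("comment", None)
    return FusionTargetConfig.from_dict(doc)


def load_target_config(path: str | Path) -> FusionTargetConfig:
    """Load and validate a user-supplied JSON target configuration."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read target config {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON in target config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"target config {path}: top level must be an object")
    return FusionTargetConfig.from_dict(doc)
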