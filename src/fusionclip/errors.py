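"""Exception hierarchy shared across the package."""


class FusionClipError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(FusionClipError):
    """Invalid target configuration (bad window, threshold, or schema)."""


class DataError(FusionClipError):
    """Problem with an input file (BAM, index, manifest, reference)."""


class MissingIndexError(DataError):
    """A coordinate-sorted BAM is present but its index is not."""
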