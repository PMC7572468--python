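"""Exception hierarchy shared across the pipeline."""


class GlycoQuantError(Exception):
    """Base class for all package errors."""


class ParseError(GlycoQuantError):
    """A spectrum file could not be parsed; names the offending scan when known."""


class LinkageError(GlycoQuantError):
    """MS3 scans reference parent MS2 scans that do not exist or mismatch."""

    def __init__(self, message: str, offending_scans: list[int] | None = None):
        super().__init__(message)
        self.offending_scans = offending_scans or []


class DegenerateInputError(GlycoQuantError):
    """Input is structurally valid but numerically degenerate (e.g. all-zero spectrum)."""


class AlphabetError(GlycoQuantError):
    """A sequence contains residues outside the supported amino-acid alphabet."""


class LocationError(GlycoQuantError):
    """A peptide could not be located within its claimed parent protein."""


class ConfigurationError(GlycoQuantError):
    """Invalid or inconsistent configuration (empty pools, overlapping windows, ...)."""
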