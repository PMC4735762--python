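"""Exception hierarchy shared across the package."""


class CassexError(Exception):
    """Base class for all package errors."""


class ParseError(CassexError):
    """A record could not be parsed into a valid gene model."""


class UnsupportedFormatError(CassexError):
    """Requested an input format the reader does not understand."""


class ValidationError(CassexError):
    """A domain invariant was violated (overlapping exons, zero-length intron, ...)."""


class TruncatedSiteError(CassexError):
    """Requested junction flanks exceed the available exon/intron sequence.

    Carries ``available``, the number of nucleotides actually present.
    """

    def __init__(self, message: str, available: int):
        super().__init__(message)
        self.available = available


class ShapeError(CassexError):
    """Sequence length does not match the matrix / label geometry."""


class InvalidBackgroundError(CassexError):
    """Background distribution contains a zero or does not normalise."""


class InvalidBaseError(CassexError):
    """A nucleotide outside {A, C, G, T} where a concrete base is required."""


class InsufficientEvidenceError(CassexError):
    """A rule was asked to fire without the inputs it needs (e.g. missing PWMS)."""


class EstimationError(CassexError):
    """An estimator received too little data."""


class ConfigError(CassexError):
    """A generator or pipeline configuration is infeasible or invalid."""
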