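"""Exception types shared across the package."""


class MacrodomainsError(Exception):
    """Base class for package errors."""


class InvalidParameterError(MacrodomainsError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidRecordError(MacrodomainsError, ValueError):
    """A malformed interval or table record (e.g. start >= end)."""


class LayoutMismatchError(MacrodomainsError, ValueError):
    """Two binned tracks or interval sets refer to different genome layouts."""


class UndefinedCorrelationError(MacrodomainsError, ValueError):
    """Correlation requested for a track with zero variance."""


class FormatError(MacrodomainsError, ValueError):
    """An input file does not conform to the expected format."""


class InfeasibleLayoutError(MacrodomainsError, RuntimeError):
    """Simulation could not place the requested features."""
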