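"""Exception hierarchy shared across the package."""


class OxivalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OxivalError):
    """A file could not be parsed; the message names file and line."""


class ValidationError(OxivalError):
    """Parsed data violates a domain invariant."""


class ConfigError(OxivalError):
    """A simulation or run configuration is inconsistent."""


class AlignmentError(OxivalError):
    """A reference sample cannot be aligned to a stream/annotation."""


class DegenerateDataError(OxivalError):
    """Input is degenerate for the requested statistic (zero variance, empty, ...)."""
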