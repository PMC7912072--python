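"""Exception hierarchy shared across the package."""


class PlasmaPatternError(Exception):
    """Base class for all package-specific errors."""


class DataError(PlasmaPatternError, ValueError):
    """Invalid data content (values violating a domain invariant)."""


class ParseError(DataError):
    """Malformed input file; the message names the offending row/column."""


class DomainError(DataError):
    """A numeric value outside its physical/clinical domain."""


class CalibrationError(PlasmaPatternError, RuntimeError):
    """Simulator moment-matching targets cannot be met by the chosen family."""
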