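"""Exception hierarchy shared across the package."""


class RegpatternError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RegpatternError, ValueError):
    """An object violates one of its declared invariants."""


class FormatError(RegpatternError, ValueError):
    """An on-disk input does not match the expected file format."""


class EmptyResultError(RegpatternError, ValueError):
    """An operation produced an empty result where that is not meaningful."""


class ConvergenceError(RegpatternError, RuntimeError):
    """An iterative solver exceeded its iteration budget."""
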