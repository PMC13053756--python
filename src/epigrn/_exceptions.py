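"""Exception types shared across the package."""


class EpigrnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EpigrnError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(EpigrnError):
    """An in-memory object or parsed table violates a type invariant."""


class UndefinedStatisticError(EpigrnError):
    """A statistic is undefined for the given input (e.g. a single-class
    label vector for a concordance statistic, or a constant vector for a
    rank correlation).  Raised instead of silently returning 0."""
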