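"""Exception hierarchy shared across the package."""


class RepmethError(Exception):
    """Base class for all package errors."""


class ParseError(RepmethError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(RepmethError):
    """Input data violated a structural invariant (duplicates, bad intervals, ...)."""


class UndefinedScoreError(RepmethError):
    """A score or rate was requested for a region/matrix with no usable observations."""
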