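"""Exception hierarchy for swimquant.

All package errors derive from :class:`SwimquantError` so callers can catch
one base class; subclasses distinguish dialect problems, validation failures,
unrecoverable tracks and statistical design errors.
"""


class SwimquantError(Exception):
    """Base class for all swimquant errors."""


class PoseDialectError(SwimquantError):
    """The file does not follow the three-header-row pose CSV dialect."""


class EmptyInputError(SwimquantError):
    """A file or table contained no data rows."""


class ValidationError(SwimquantError):
    """A value violates a domain invariant (bounds, signs, shapes)."""


class UnrecoverableTrackError(SwimquantError):
    """A body part cannot be imputed (no retained frames, or gap over cap)."""


class DesignError(SwimquantError):
    """A statistical design precondition is violated (group sizes, balance)."""


class PairingError(SwimquantError):
    """A record has no time-matched control to normalize against."""
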