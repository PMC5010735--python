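"""Exception hierarchy for runtumble.

All errors raised on bad user input derive from :class:`RunTumbleError`
so callers can catch one base class; ``FormatError`` and
``ValidationError`` separate file-shape problems from value problems.
"""


class RunTumbleError(Exception):
    """Base class for all runtumble errors."""


class FormatError(RunTumbleError, ValueError):
    """A table is missing mandatory columns or is otherwise malformed."""


class ValidationError(RunTumbleError, ValueError):
    """Values violate an invariant (negative weight, duplicate times, ...)."""


class FitError(RunTumbleError, RuntimeError):
    """A density/line/threshold fit cannot be performed on the input."""
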