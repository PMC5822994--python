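"""Exception hierarchy.

Every error raised while reading a file carries a tag name or a line number
so the offending record can be located; validation errors list the offending
reflections where that is meaningful.
"""


class RefweightError(Exception):
    """Base class for all package errors."""


class FormatError(RefweightError):
    """A file is structurally not what the reader expects (missing block,
    missing required tag or record)."""


class ParseError(RefweightError):
    """A field inside an otherwise well-formed file could not be parsed."""


class ValidationError(RefweightError):
    """Parsed or computed values violate a domain invariant."""


class ConfigurationError(RefweightError):
    """An option combination that cannot run (e.g. a grid step smaller than
    its stopping step)."""
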