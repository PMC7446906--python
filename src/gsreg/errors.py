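"""Exception hierarchy shared across the package."""


class GsrError(Exception):
    """Base class for all gsreg errors."""


class FormatError(GsrError):
    """A file could not be parsed in the declared format."""


class ValidationError(GsrError):
    """Parsed data violates an invariant of its domain type."""


class UsageError(GsrError):
    """The caller combined inputs or options incorrectly."""
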