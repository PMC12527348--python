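"""Exception hierarchy.

Every user-facing failure derives from :class:`PolytailError` so the CLI can
map library errors to exit status 1 with a clean message.
"""


class PolytailError(Exception):
    """Base class for all polytail errors."""


class SchemaError(PolytailError):
    """A required column or attribute is missing from an input table/file."""


class ValidationError(PolytailError):
    """Input values violate a documented precondition."""


class ConflictError(ValidationError):
    """Contradictory annotation (e.g. one transcript mapped to two genes)."""


class FormatError(PolytailError):
    """A file is syntactically readable but semantically malformed."""


class UndefinedStatisticError(PolytailError):
    """A test statistic is undefined for the given data (e.g. zero variance)."""
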