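"""Exception hierarchy.

All package errors derive from :class:`BCSubtypeError` so callers (and the
CLI) can distinguish handled domain errors from genuine bugs.
"""


class BCSubtypeError(Exception):
    """Base class for all bcsubtype errors."""


class FormatError(BCSubtypeError):
    """A file on disk does not conform to the expected dialect or schema."""


class ValidationError(BCSubtypeError):
    """In-memory data violates a documented invariant or precondition."""


class UndefinedCorrelationError(BCSubtypeError):
    """A correlation is undefined (e.g. a constant vector under Spearman)."""


class SchemaVersionError(FormatError):
    """A serialized model declares an unsupported schema version."""
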