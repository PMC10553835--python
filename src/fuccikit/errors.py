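"""Exception hierarchy.

All errors raised by fuccikit derive from :class:`FuccikitError` so callers
can catch the package's failures with a single except clause. Validation
failures additionally derive from ``ValueError``.
"""


class FuccikitError(Exception):
    """Base class for all fuccikit errors."""


class InvalidParameterError(FuccikitError, ValueError):
    """A numeric parameter is outside its valid domain."""


class SchemaError(FuccikitError, ValueError):
    """An input table does not match the expected column schema."""


class TrackValidationError(FuccikitError, ValueError):
    """A cell track violates a structural invariant (e.g. non-monotone times)."""


class EmptyInputError(FuccikitError, ValueError):
    """An operation received an empty collection where data is required."""


class NoTransitionsError(FuccikitError, ValueError):
    """No exits from a phase were observed, so its duration is not estimable."""
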