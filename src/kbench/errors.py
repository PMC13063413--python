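"""Exception hierarchy for kbench.

All package errors derive from :class:`KbenchError` so callers can catch the
whole family; the leaves distinguish file-format problems, invariant
violations, numeric domain errors and insufficient-data conditions.
"""


class KbenchError(Exception):
    """Base class for all kbench errors."""


class FormatError(KbenchError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(KbenchError):
    """Data violate a declared invariant (e.g. non-positive k on a valid row)."""


class AmbiguityError(ValidationError):
    """Duplicate records where at most one was allowed."""


class DomainError(KbenchError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class InsufficientDataError(KbenchError):
    """Too few valid values to compute the requested statistic."""


class InsufficientOverlapError(InsufficientDataError):
    """Chemical and benchmark share no valid sites."""


class ConfigurationError(KbenchError):
    """A configuration value or grouping is unusable (e.g. singleton group)."""


class UsageError(KbenchError, ValueError):
    """The operation was called with arguments that can never be valid."""
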