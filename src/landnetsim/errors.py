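"""Exception hierarchy for landscape-network analyses.

All package errors derive from :class:`LandnetError` so callers can catch one
base class; the subclasses distinguish malformed files, invariant violations,
cross-file inconsistencies and metrics that are mathematically undefined for
the given input (which is different from a metric that is legitimately zero).
"""


class LandnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LandnetError):
    """A file does not have the expected tabular/tree format."""


class ValidationError(LandnetError):
    """An input value violates a domain invariant (e.g. count < 1)."""


class ConsistencyError(LandnetError):
    """Two inputs that must agree do not (e.g. habitat absent from site metadata)."""


class ConfigurationError(LandnetError):
    """A run configuration references something that does not exist."""


class CoverageError(LandnetError):
    """A community contains species that the phylogeny cannot place."""


class UndefinedMetricError(LandnetError):
    """The requested metric is undefined for this input (not zero)."""
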