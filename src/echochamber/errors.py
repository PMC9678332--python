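"""Exception hierarchy shared across the package."""


class EchoChamberError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EchoChamberError):
    """Invalid generator or pipeline configuration (bad probability vector, negative rate, ...)."""


class SchemaError(EchoChamberError):
    """A corpus table is missing a column or uses an out-of-vocabulary value."""


class ReferentialIntegrityError(EchoChamberError):
    """A tweet references a parent that does not exist in the corpus."""

    def __init__(self, message: str, offending_ids: list | None = None):
        super().__init__(message)
        self.offending_ids = list(offending_ids or [])


class EmptyCorpusError(EchoChamberError):
    """An operation that needs at least one record received an empty corpus."""


class UndefinedMetricsError(EchoChamberError):
    """Ego-network metrics requested for an isolated node (no contacts)."""


class UndefinedRoleError(EchoChamberError):
    """Echo role or attitude requested for a user with no labeled activity."""


class DegenerateTableError(EchoChamberError):
    """Contingency table has a zero row or column marginal."""
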