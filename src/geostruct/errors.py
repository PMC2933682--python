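"""Exception hierarchy for the geostruct pipeline."""


class GeostructError(Exception):
    """Base class for all geostruct errors."""


class DomainError(GeostructError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class StandardizationError(GeostructError):
    """The count table cannot be indirectly standardised (e.g. an empty band)."""


class SimulationError(GeostructError):
    """The synthetic-cohort generator could not satisfy its constraints."""


class UndefinedCorrelationError(DomainError):
    """Weighted correlation undefined because a weighted variance is zero."""
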