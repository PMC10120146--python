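"""Exception hierarchy for scenario validation and solver domains."""


class VilipowerError(ValueError):
    """Base class for all domain errors raised by this package."""


class DomainError(VilipowerError):
    """An input lies outside the physical or mathematical domain of an operation."""


class ConsistencyError(VilipowerError):
    """Mutually redundant inputs (e.g. Ps vs V_T/C + PEEP) disagree."""


class DegenerateCycleError(DomainError):
    """The cycle has no tidal excursion (driving pressure is zero)."""


class UnboundedTargetError(DomainError):
    """The requested ratio admits no finite target (e.g. HR_Elastic = 1)."""
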