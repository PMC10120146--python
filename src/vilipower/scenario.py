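"""Ventilation scenario container and basic respiratory-mechanics closure.

A scenario describes one passive tidal inflation by its static circuit
pressures (plateau pressure ``ps`` and ``peep``, both in cmH2O referenced to
atmosphere), tidal volume ``vt`` (L), ventilating frequency ``f``
(breaths/min) and the threshold elastic pressure ``pt`` (cmH2O) that
partitions per-cycle energy into safe and hazardous fractions.

Respiratory-system compliance ``c`` (L/cmH2O) is redundant with the
pressures under the linear single-compartment model, Ps = V_T/C + PEEP.
Exactly one of {``c``, ``ps``} may be omitted and is derived from the other;
when both are supplied they must agree to 1e-9 relative tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConsistencyError, DomainError

#: Conversion factor from the clinical energy unit cmH2O·L to joules.
CMH2O_L_TO_J = 0.0980665

#: Relative tolerance for the Ps = V_T/C + PEEP closure check.
CLOSURE_RTOL = 1e-9


def plateau_from_mechanics(vt: float, c: float, peep: float) -> float:
    """Plateau pressure implied by tidal volume, compliance and PEEP.

    Under linear single-compartment mechanics the end-inspiratory static
    (elastic) pressure is ``Ps = V_T/C + PEEP``.

    Parameters
    ----------
    vt : tidal volume, L (must be > 0)
    c : respiratory-system compliance, L/cmH2O (must be > 0)
    peep : positive end-expiratory pressure, cmH2O (must be >= 0)
    """
    if vt <= 0:
        raise DomainError(f"tidal volume must be positive, got {vt!r}")
    if c <= 0:
        raise DomainError(f"compliance must be positive, got {c!r}")
    if peep < 0:
        raise DomainError(f"PEEP must be non-negative, got {peep!r}")
    return vt / c + peep


@dataclass(frozen=True)
class VentilationScenario:
    """One passive ventilation pattern.

    Attributes
    ----------
    ps : plateau pressure, cmH2O (derived from ``vt``/``c``/``peep`` if omitted)
    peep : positive end-expiratory pressure, cmH2O
    vt : tidal volume, L
    f : ventilating frequency, breaths/min
    pt : threshold elastic pressure partitioning safe from hazardous energy, cmH2O
    c : respiratory-system compliance, L/cmH2O (derived from pressures if omitted)
    """

    peep: float
    vt: float
    f: float
    pt: float
    ps: float | None = None
    c: float | None = None
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise DomainError(f"PEEP must be non-negative, got {self.peep!r}")
        if self.vt <= 0:
            raise DomainError(f"tidal volume must be positive, got {self.vt!r}")
        if self.f <= 0:
            raise DomainError(f"frequency must be positive, got {self.f!r}")
        if self.ps is None and self.c is None:
            raise DomainError("at least one of plateau pressure or compliance is required")
        if self.ps is None:
            object.__setattr__(self, "ps", plateau_from_mechanics(self.vt, self.c, self.peep))
        elif self.c is None:
            if self.ps <= self.peep:
                raise DomainError(
                    f"plateau pressure ({self.ps}) must exceed PEEP ({self.peep})"
                )
            object.__setattr__(self, "c", self.vt / (self.ps - self.peep))
        else:
            if self.c <= 0:
                raise DomainError(f"compliance must be positive, got {self.c!r}")
            implied = plateau_from_mechanics(self.vt, self.c, self.peep)
            if not math.isclose(self.ps, implied, rel_tol=CLOSURE_RTOL, abs_tol=0.0):
                raise ConsistencyError(
                    f"plateau pressure {self.ps} inconsistent with V_T/C + PEEP = {implied}"
                )
        if self.ps <= self.peep:
            raise DomainError(
                f"plateau pressure ({self.ps}) must exceed PEEP ({self.peep})"
            )
        if not math.isfinite(self.pt):
            raise DomainError(f"threshold pressure must be finite, got {self.pt!r}")

    @property
    def dp(self) -> float:
        """Driving pressure DP = Ps − PEEP, cmH2O."""
        return self.ps - self.peep

    def with_threshold(self, pt: float) -> "VentilationScenario":
        """Copy of this scenario with a different threshold pressure."""
        return replace(self, pt=pt)

    def as_dict(self) -> dict[str, float | str | None]:
        return {
            "name": self.name,
            "ps": self.ps,
            "peep": self.peep,
            "vt": self.vt,
            "c": self.c,
            "f": self.f,
            "pt": self.pt,
        }
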