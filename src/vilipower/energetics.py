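"""Per-cycle elastic energy accounting and hazard/safety partitioning.

Under linear single-compartment mechanics, one passive inflation traces a
straight line on the pressure–volume plane from (PEEP, 0) to (Ps, V_T).
The conserved (elastic) energy of the breath is the area under that line:

    W_Elastic = ½ (Ps + PEEP) V_T  =  V_T²/(2C) + V_T·PEEP

Its purely tidal component, excluding the rectangular PEEP block, is the
*drive energy*:

    W_Drive = ½ DP · V_T  =  V_T²/(2C),       DP = Ps − PEEP

A threshold elastic pressure Pt (PEEP ≤ Pt ≤ Ps) splits each energy into an
infra-threshold "safe" part and a supra-threshold "hazardous" part.  The
hazard ratio HR is the supra-threshold fraction; geometrically:

    HR_Drive   = (2DP + Pt − Ps)(Ps − Pt) / DP²  =  1 − ((Pt − PEEP)/DP)²
    HR_Elastic = (Ps² − Pt²) / (Ps² − PEEP²)

and the safety ratio is the complement, SR = 1 − HR.  Damaging power is
frequency × supra-threshold energy per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DegenerateCycleError, DomainError
from .scenario import CMH2O_L_TO_J, VentilationScenario

ThresholdPolicy = Literal["clamp", "strict"]


def _resolve_pt(ps: float, peep: float, pt: float, policy: ThresholdPolicy) -> float:
    """Clamp Pt into [PEEP, Ps] or raise, per the out-of-range policy.

    Clamping preserves the geometric meaning: a threshold at or above the
    plateau marks no energy hazardous (HR = 0); a threshold at or below
    PEEP marks all tidal energy hazardous (HR = 1).
    """
    if policy == "strict":
        if not (peep <= pt <= ps):
            raise DomainError(
                f"threshold pressure {pt} outside [PEEP={peep}, Ps={ps}] in strict mode"
            )
        return pt
    if policy == "clamp":
        return min(max(pt, peep), ps)
    raise ValueError(f"unknown threshold policy {policy!r}")


def _check_cycle(ps: float, peep: float) -> None:
    if peep < 0:
        raise DomainError(f"PEEP must be non-negative, got {peep!r}")
    if ps == peep:
        raise DegenerateCycleError("driving pressure is zero (Ps == PEEP)")
    if ps < peep:
        raise DomainError(f"plateau pressure ({ps}) must exceed PEEP ({peep})")


def w_elastic(scenario: VentilationScenario) -> float:
    """Total conserved elastic energy per inflation, cmH2O·L.

    Trapezoidal P–V area ½(Ps + PEEP)·V_T, including the PEEP block.
    """
    return 0.5 * (scenario.ps + scenario.peep) * scenario.vt


def w_drive(scenario: VentilationScenario) -> float:
    """Tidal (drive) elastic energy per inflation, cmH2O·L.

    Triangular P–V area ½·DP·V_T = V_T²/(2C), excluding the PEEP block.
    """
    return 0.5 * scenario.dp * scenario.vt


def hr_drive(
    ps: float, peep: float, pt: float, policy: ThresholdPolicy = "clamp"
) -> float:
    """Hazardous fraction of drive energy: supra-threshold share of W_Drive.

    HR_Drive = (2DP + Pt − Ps)(Ps − Pt)/DP², equivalently 1 − ((Pt−PEEP)/DP)².
    """
    _check_cycle(ps, peep)
    pt = _resolve_pt(ps, peep, pt, policy)
    dp = ps - peep
    # factored form of (2DP + Pt − Ps)(Ps − Pt)/DP²: 2DP + Pt − Ps = DP + (Pt − PEEP)
    return (dp + (pt - peep)) * (ps - pt) / (dp * dp)


def hr_elastic(
    ps: float, peep: float, pt: float, policy: ThresholdPolicy = "clamp"
) -> float:
    """Hazardous fraction of total elastic energy: supra-threshold share of W_Elastic.

    HR_Elastic = (Ps² − Pt²)/(Ps² − PEEP²).
    """
    _check_cycle(ps, peep)
    pt = _resolve_pt(ps, peep, pt, policy)
    # difference-of-squares factored for accuracy; coincides bit-for-bit with
    # the drive variant at PEEP = 0
    return ((ps - pt) * (ps + pt)) / ((ps - peep) * (ps + peep))


def safety_ratios(
    ps: float, peep: float, pt: float, policy: ThresholdPolicy = "clamp"
) -> tuple[float, float]:
    """Safe (infra-threshold) fractions (SR_Drive, SR_Elastic); SR = 1 − HR."""
    return (
        1.0 - hr_drive(ps, peep, pt, policy),
        1.0 - hr_elastic(ps, peep, pt, policy),
    )


@dataclass(frozen=True)
class EnergyPartition:
    """Per-cycle energies, their safe/hazardous split, and per-minute powers.

    Energies are in cmH2O·L and powers in cmH2O·L/min; ``*_j`` properties
    convert with 1 cmH2O·L = 0.0980665 J.
    """

    w_elastic: float
    w_drive: float
    hr_drive: float
    hr_elastic: float
    sr_drive: float
    sr_elastic: float
    hazardous_energy_drive: float
    hazardous_energy_elastic: float
    driving_power: float
    elastic_power: float
    damaging_power_drive: float
    damaging_power_elastic: float

    @property
    def driving_power_j(self) -> float:
        return self.driving_power * CMH2O_L_TO_J

    @property
    def elastic_power_j(self) -> float:
        return self.elastic_power * CMH2O_L_TO_J

    @property
    def damaging_power_drive_j(self) -> float:
        return self.damaging_power_drive * CMH2O_L_TO_J

    @property
    def damaging_power_elastic_j(self) -> float:
        return self.damaging_power_elastic * CMH2O_L_TO_J

    def as_dict(self) -> dict[str, float]:
        """Flat mapping of all fields plus the joule-converted powers."""
        out = {
            "w_elastic": self.w_elastic,
            "w_drive": self.w_drive,
            "hr_drive": self.hr_drive,
            "hr_elastic": self.hr_elastic,
            "sr_drive": self.sr_drive,
            "sr_elastic": self.sr_elastic,
            "hazardous_energy_drive": self.hazardous_energy_drive,
            "hazardous_energy_elastic": self.hazardous_energy_elastic,
            "driving_power": self.driving_power,
            "elastic_power": self.elastic_power,
            "damaging_power_drive": self.damaging_power_drive,
            "damaging_power_elastic": self.damaging_power_elastic,
            "driving_power_j": self.driving_power_j,
            "elastic_power_j": self.elastic_power_j,
            "damaging_power_drive_j": self.damaging_power_drive_j,
            "damaging_power_elastic_j": self.damaging_power_elastic_j,
        }
        return out


def partition(
    scenario: VentilationScenario, policy: ThresholdPolicy = "clamp"
) -> EnergyPartition:
    """Full safe/hazardous energy and power accounting for one scenario.

    Damaging power is frequency × hazardous energy per cycle,
    f × HR_X × W_X, for both the drive and the all-inclusive elastic variant.
    """
    we = w_elastic(scenario)
    wd = w_drive(scenario)
    hd = hr_drive(scenario.ps, scenario.peep, scenario.pt, policy)
    he = hr_elastic(scenario.ps, scenario.peep, scenario.pt, policy)
    f = scenario.f
    return EnergyPartition(
        w_elastic=we,
        w_drive=wd,
        hr_drive=hd,
        hr_elastic=he,
        sr_drive=1.0 - hd,
        sr_elastic=1.0 - he,
        hazardous_energy_drive=hd * wd,
        hazardous_energy_elastic=he * we,
        driving_power=f * wd,
        elastic_power=f * we,
        damaging_power_drive=f * hd * wd,
        damaging_power_elastic=f * he * we,
    )
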