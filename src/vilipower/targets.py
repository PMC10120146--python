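"""Inverse solvers: ventilator-setting targets for a requested hazard ratio.

Given a tolerated hazard ratio h, the closed forms invert the partition:

    Target DP = (1 − √(1 − h)) / h · (Ps − Pt)     (drive variant;
                Ps and Pt held fixed, so PEEP moves with DP)
    Target Ps = √((Pt² − h·PEEP²) / (1 − h))       (elastic variant;
                PEEP and Pt held fixed)

and the tidal volume rescales linearly at fixed compliance:

    Target V_T = (Target DP / DP) · V_T  =  ((Target Ps − PEEP) / DP) · V_T

Target DP is evaluated through the equivalent form (Ps − Pt)/(1 + √(1 − h)),
which is exact at the limits h → 0 (giving (Ps − Pt)/2) and h = 1 (giving
Ps − Pt) without the indeterminate 0/0 of the raw quotient.

Requests may be phrased as a hazard ratio or as a safety ratio; the two are
complements (HR = 1 − SR), so safe mode converts and applies the same solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from . import energetics
from .errors import DomainError, UnboundedTargetError
from .scenario import VentilationScenario

Variant = Literal["drive", "elastic"]
RatioKind = Literal["hazard", "safe"]


def target_dp(hr_drive_desired: float, ps: float, pt: float) -> float:
    """Driving pressure achieving the requested drive hazard ratio, cmH2O.

    Ps and Pt are held fixed; the round trip hr_drive at the returned DP
    (with Ps − Pt unchanged) recovers the request exactly.
    """
    h = hr_drive_desired
    if not 0.0 <= h <= 1.0:
        raise DomainError(f"hazard ratio must lie in [0, 1], got {h!r}")
    if pt > ps:
        raise DomainError(f"threshold pressure ({pt}) must not exceed plateau ({ps})")
    return (ps - pt) / (1.0 + math.sqrt(1.0 - h))


def target_ps(hr_elastic_desired: float, pt: float, peep: float) -> float:
    """Plateau pressure achieving the requested elastic hazard ratio, cmH2O.

    PEEP and Pt are held fixed.  h = 1 has no finite plateau (all energy
    supra-threshold requires Ps → ∞) and raises UnboundedTargetError.
    """
    h = hr_elastic_desired
    if not 0.0 <= h <= 1.0:
        raise DomainError(f"hazard ratio must lie in [0, 1], got {h!r}")
    if h == 1.0:
        raise UnboundedTargetError("elastic hazard ratio of 1 admits no finite plateau")
    if peep < 0:
        raise DomainError(f"PEEP must be non-negative, got {peep!r}")
    if pt < peep:
        raise DomainError(f"threshold pressure ({pt}) must be at least PEEP ({peep})")
    return math.sqrt((pt**2 - h * peep**2) / (1.0 - h))


def target_vt(
    scenario: VentilationScenario,
    *,
    target_dp: float | None = None,
    target_ps: float | None = None,
) -> float:
    """Tidal volume matching a target pressure at the scenario's compliance, L.

    Exactly one of ``target_dp``/``target_ps`` must be supplied.  The two
    printed scalings agree whenever target_ps − PEEP = target_dp.
    """
    if (target_dp is None) == (target_ps is None):
        raise DomainError("supply exactly one of target_dp or target_ps")
    if target_dp is None:
        if target_ps <= scenario.peep:
            raise DomainError(
                f"target plateau ({target_ps}) must exceed PEEP ({scenario.peep})"
            )
        target_dp = target_ps - scenario.peep
    elif target_dp <= 0:
        raise DomainError(f"target driving pressure must be positive, got {target_dp!r}")
    return (target_dp / scenario.dp) * scenario.vt


@dataclass(frozen=True)
class TargetPrescription:
    """Inverse-solved ventilator targets for a requested hazard/safety ratio.

    ``held_fixed`` records which scenario inputs the solver treats as
    constant, i.e. which knob the model assumes the clinician leaves alone.
    """

    requested_ratio: float
    variant: Variant
    kind: RatioKind
    hazard_ratio: float
    target_dp: float
    target_ps: float | None
    target_vt: float
    held_fixed: tuple[str, ...]

    def as_dict(self) -> dict[str, object]:
        return {
            "requested_ratio": self.requested_ratio,
            "variant": self.variant,
            "kind": self.kind,
            "hazard_ratio": self.hazard_ratio,
            "target_dp": self.target_dp,
            "target_ps": self.target_ps,
            "target_vt": self.target_vt,
            "held_fixed": list(self.held_fixed),
        }


def prescribe(
    scenario: VentilationScenario,
    desired_ratio: float,
    variant: Variant = "drive",
    kind: RatioKind = "hazard",
) -> TargetPrescription:
    """Solve the scenario's settings for a requested hazard or safety ratio.

    Safe mode converts via HR = 1 − SR and applies the hazard solvers.  In
    the drive variant Ps and Pt are held fixed and DP (hence PEEP and V_T)
    moves; in the elastic variant PEEP and Pt are held fixed and Ps (hence
    DP and V_T) moves.
    """
    if not 0.0 <= desired_ratio <= 1.0:
        raise DomainError(f"requested ratio must lie in [0, 1], got {desired_ratio!r}")
    h = desired_ratio if kind == "hazard" else 1.0 - desired_ratio
    if variant == "drive":
        dp = target_dp(h, scenario.ps, scenario.pt)
        return TargetPrescription(
            requested_ratio=desired_ratio,
            variant=variant,
            kind=kind,
            hazard_ratio=h,
            target_dp=dp,
            target_ps=scenario.ps,
            target_vt=target_vt(scenario, target_dp=dp),
            held_fixed=("ps", "pt", "c"),
        )
    if variant == "elastic":
        ps = target_ps(h, scenario.pt, scenario.peep)
        return TargetPrescription(
            requested_ratio=desired_ratio,
            variant=variant,
            kind=kind,
            hazard_ratio=h,
            target_dp=ps - scenario.peep,
            target_ps=ps,
            target_vt=target_vt(scenario, target_ps=ps),
            held_fixed=("peep", "pt", "c"),
        )
    raise ValueError(f"unknown variant {variant!r}")


def verify_round_trip(prescription: TargetPrescription, scenario: VentilationScenario) -> float:
    """Re-evaluate the relevant HR at the prescribed target; returns the HR.

    For the drive variant the HR_Drive expression is evaluated with DP
    replaced by the target and Ps − Pt held fixed — the reading under which
    the closed-form inversion is exact (the implied PEEP = Ps − target_dp
    may exceed Pt, where the clamped geometric HR would saturate at 1).
    For the elastic variant PEEP and Pt are unchanged and the plateau is
    the target, so the ordinary geometric HR applies.
    """
    if prescription.variant == "drive":
        dp = prescription.target_dp
        gap = scenario.ps - scenario.pt  # Ps − Pt, held fixed by the solver
        return (2.0 * dp - gap) * gap / dp**2
    return energetics.hr_elastic(prescription.target_ps, scenario.peep, scenario.pt)
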