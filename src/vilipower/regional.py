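"""Position-dependent damage thresholds along the gravitational axis.

Transpulmonary pressure — the true distending stress of lung tissue — varies
with height in the lung because pleural pressure follows a gravitational
gradient.  At equal airway pressure the non-dependent (gravitationally
upper) regions carry higher transpulmonary pressure and are therefore more
vulnerable: their local airway-pressure threshold for damage is *lower*
than the lung-average value, while dependent regions tolerate more.

This module models the local threshold as a linear function of normalized
height, centered on the lung-average threshold:

    Pt_local(x) = Pt_avg + span · (½ − x)

with x = 0 the most dependent and x = 1 the most non-dependent position,
and ``span`` the total pleural-pressure difference across the lung (cmH2O).
The prone position flattens the pleural gradient, so its default span is
smaller than supine.  Regional vulnerability enters the energy model only
through this substituted local threshold: the ordinary airway-pressure
hazard ratios are evaluated per position with Pt_local in place of Pt.

The linear profile and the default spans (supine 7.5, prone 3.0 cmH2O) are
modeling choices of this package — illustrative magnitudes, not measured
constants; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .energetics import hr_drive, hr_elastic
from .errors import DomainError
from .scenario import VentilationScenario

Posture = Literal["supine", "prone"]

#: Default total pleural-pressure span across the lung by posture, cmH2O.
#: Illustrative values; the prone gradient is flatter than supine.
DEFAULT_SPANS: dict[str, float] = {"supine": 7.5, "prone": 3.0}

DEFAULT_N_POSITIONS = 11


def local_pt(pt_average: float, pleural_gradient_span: float, position: float) -> float:
    """Local threshold pressure at a normalized gravitational position, cmH2O.

    ``position`` runs from 0 (most dependent, highest local Pt) to 1 (most
    non-dependent, lowest local Pt); position ½ returns the average.
    """
    if pleural_gradient_span < 0:
        raise DomainError(
            f"pleural gradient span must be non-negative, got {pleural_gradient_span!r}"
        )
    if not 0.0 <= position <= 1.0:
        raise DomainError(f"position must lie in [0, 1], got {position!r}")
    return pt_average + pleural_gradient_span * (0.5 - position)


@dataclass(frozen=True)
class RegionalProfile:
    """Local thresholds and hazard ratios along the gravitational axis.

    Arrays are indexed by ``positions`` (0 = most dependent, 1 = most
    non-dependent).  Local HRs use the clamped threshold policy, so a local
    Pt below PEEP saturates at HR = 1 and one above Ps at HR = 0.
    """

    positions: np.ndarray
    pleural_gradient_span: float
    posture: Posture
    pt_average: float
    pt_local: np.ndarray
    hr_drive_local: np.ndarray
    hr_elastic_local: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Per-position table (one row per gravitational position)."""
        return pd.DataFrame(
            {
                "position": self.positions,
                "pt_local": self.pt_local,
                "hr_drive_local": self.hr_drive_local,
                "hr_elastic_local": self.hr_elastic_local,
            }
        )


def regional_hazard(
    scenario: VentilationScenario,
    *,
    posture: Posture = "supine",
    pleural_gradient_span: float | None = None,
    pt_average: float | None = None,
    n_positions: int = DEFAULT_N_POSITIONS,
) -> RegionalProfile:
    """Evaluate local thresholds and hazard ratios over a position grid.

    The scenario's threshold (or ``pt_average`` if given) is taken as the
    lung-average Pt; each position substitutes its local Pt into the global
    hazard-ratio formulas.  Non-dependent positions are at least as
    hazardous as the average, dependent ones at most.
    """
    if n_positions < 2:
        raise DomainError(f"need at least 2 positions, got {n_positions!r}")
    if posture not in DEFAULT_SPANS:
        raise DomainError(f"posture must be 'supine' or 'prone', got {posture!r}")
    span = DEFAULT_SPANS[posture] if pleural_gradient_span is None else pleural_gradient_span
    pt_avg = scenario.pt if pt_average is None else pt_average

    positions = np.linspace(0.0, 1.0, n_positions)
    pts = pt_avg + span * (0.5 - positions)
    hrd = np.array([hr_drive(scenario.ps, scenario.peep, p, "clamp") for p in pts])
    hre = np.array([hr_elastic(scenario.ps, scenario.peep, p, "clamp") for p in pts])
    return RegionalProfile(
        positions=positions,
        pleural_gradient_span=span,
        posture=posture,
        pt_average=pt_avg,
        pt_local=pts,
        hr_drive_local=hrd,
        hr_elastic_local=hre,
    )
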