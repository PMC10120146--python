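"""Independent numeric verification of the closed-form hazard ratios.

The hazard ratio is, by construction, a quotient of pressure–volume areas:
along the linear elastic inflation line V = C(P − PEEP), the drive variant
compares the supra-threshold part of the area between the P–V line and the
PEEP ordinate to the whole of it, and the elastic variant does the same
for the full area under the line down to zero pressure.  Compliance scales
both numerator and denominator and cancels.

``oracle_hr`` computes those areas by composite trapezoid quadrature on a
fine pressure grid, with no reference to the closed-form expressions, so
agreement between the two routes is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

from .energetics import _check_cycle, _resolve_pt

DEFAULT_N_PANELS = 100_000


def oracle_hr(
    ps: float,
    peep: float,
    pt: float,
    variant: str = "drive",
    n_panels: int = DEFAULT_N_PANELS,
) -> float:
    """Supra-threshold energy fraction by numeric P–V area integration.

    Integrates along the elastic inflation line with unit compliance
    (compliance cancels in the ratio).  ``variant`` selects the drive
    (PEEP-excluding) or elastic (all-inclusive) energy denominator.
    """
    if n_panels < 1000:
        raise ValueError(f"n_panels must be at least 1000, got {n_panels!r}")
    if variant not in ("drive", "elastic"):
        raise ValueError(f"variant must be 'drive' or 'elastic', got {variant!r}")
    _check_cycle(ps, peep)
    pt = _resolve_pt(ps, peep, pt, "clamp")

    # With C = 1, dV = dP along the inflation line from PEEP to Ps.
    def area(p_lo: float, p_hi: float) -> float:
        if p_hi <= p_lo:
            return 0.0
        p = np.linspace(p_lo, p_hi, n_panels + 1)
        integrand = (p - peep) if variant == "drive" else p
        return float(np.trapezoid(integrand, p))

    total = area(peep, ps)
    hazardous = area(pt, ps)
    return hazardous / total
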