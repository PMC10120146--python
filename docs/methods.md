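# Methods

## Model

`vilipower` implements an energy-based view of ventilator-induced lung
injury (VILI) risk for **passive** mechanical ventilation under linear
single-compartment respiratory mechanics. One inflation moves the lung
along a straight line in the pressure–volume plane from (PEEP, 0) to
(Ps, V_T), where Ps is the static end-inspiratory plateau pressure,
DP = Ps − PEEP the driving pressure and C = V_T/DP the compliance. The
conserved ("elastic") energy of the breath is the area under that line:

    W_Elastic = ½ (Ps + PEEP) V_T = V_T²/(2C) + V_T·PEEP        [cmH2O·L]

and its purely tidal component, excluding the rectangular PEEP block, is
the drive energy:

    W_Drive = ½ DP · V_T = V_T²/(2C)

A hypothetical threshold elastic pressure Pt (referenced to atmosphere,
PEEP ≤ Pt ≤ Ps) splits each energy into an infra-threshold "safe" part and
a supra-threshold "hazardous" part. The hazard ratio HR is the
supra-threshold fraction; geometry of the P–V areas gives the closed forms

    HR_Drive   = (2DP + Pt − Ps)(Ps − Pt) / DP² = 1 − ((Pt − PEEP)/DP)²
    HR_Elastic = (Ps² − Pt²) / (Ps² − PEEP²)

with safety ratio SR = 1 − HR in either variant. Per-minute powers are
frequency products: elastic power f·W_Elastic, driving power f·W_Drive,
and *damaging* power f·HR·W — the same total power can be entirely
innocuous (Pt ≥ Ps) or largely damaging depending on where the threshold
sits and how often the cycle repeats. The model deliberately ignores chest
wall elastance (airway pressure stands in for transpulmonary pressure),
resistive/dissipated energy, spontaneous effort, viscoelastic losses and
alveolar micro-mechanics.

The literature prints the drive energy both as ½·Ps·V_T and as V_T²/(2C);
these disagree whenever PEEP > 0. This package uses W_Drive = ½·DP·V_T =
V_T²/(2C), the only reading consistent with the P–V geometry of the
drive area and with the HR_Drive expression above.

## Inverse targets

Given a tolerated hazard ratio h, the partition inverts in closed form:

    Target DP = (1 − √(1 − h))/h · (Ps − Pt)        (Ps, Pt held fixed)
    Target Ps = √((Pt² − h·PEEP²)/(1 − h))           (PEEP, Pt held fixed)
    Target V_T = (Target DP / DP)·V_T = ((Target Ps − PEEP)/DP)·V_T

Numerically, Target DP is evaluated as (Ps − Pt)/(1 + √(1 − h)), which is
algebraically identical but finite at h = 0 (yielding the analytic limit
(Ps − Pt)/2) and exact at h = 1 (yielding Ps − Pt). Each solver records
which inputs it holds fixed (`held_fixed`): the drive solver assumes the
plateau and threshold stay put, so PEEP implicitly moves with DP; the
elastic solver holds PEEP and Pt. The drive round trip closes at the
formula level (DP replaced by the target with Ps − Pt fixed) — for small h
the implied PEEP rises above Pt, where the clamped geometric hazard would
saturate at 1; users asking for very low drive hazards should read the
prescription as "reduce DP and V_T this far", not as a complete new
scenario. Safety-ratio requests are served by the complement h = 1 − SR
and the same solvers.

## Regional thresholds

Pleural pressure falls along the gravitational axis, so at equal airway
pressure the non-dependent lung carries higher transpulmonary stress and
is more vulnerable: its local damage threshold is lower than the
lung-average Pt. We model the local threshold linearly in normalized
height x (0 = most dependent, 1 = most non-dependent):

    Pt_local(x) = Pt_avg + span·(½ − x)

where `span` is the total pleural-pressure difference across the lung
(cmH2O). Regional vulnerability enters **only** through this substituted
threshold; the global HR formulas are then evaluated per position with the
clamped out-of-range policy (local Pt above Ps saturates at HR = 0, below
PEEP at HR = 1). Defaults: 11 evenly spaced positions; span 7.5 cmH2O
supine and 3.0 cmH2O prone. The linear profile and these spans are
modeling choices of this package — illustrative magnitudes chosen so that
the prone gradient is distinctly flatter than supine, not measured
constants — and both are user-configurable.

## Waveform simulation

`simulate_cycle` integrates one inflation on a uniform time grid
(default n_steps = 2000 intervals): volume by trapezoid accumulation of
the chosen flow profile, elastic pressure P_el = V/C + PEEP, airway
pressure P_aw = R·Q + P_el, and cumulative elastic energy by trapezoid
integration of the intracycle power P_el·Q in time. Supported profiles:
constant flow Q = V_T/Ti; decelerating-linear ramp from peak 2·V_T/Ti to
zero; and arbitrary non-negative sampled profiles, linearly interpolated.
Every profile is rescaled on the simulation grid so the delivered volume
is exactly V_T, which pins the final elastic pressure at Ps and makes the
waveform-invariance property (identical total elastic energy for all
profiles) a genuine numerical check rather than an imposed identity.
Time above threshold is the measure of {t : P_el(t) > Pt} with grid
crossings refined by linear interpolation. Energy error converges ~O(n⁻²)
in the step count; at the default grid the invariance holds to ~1e-7
relative. Expiration is not modeled — the energy accounting is
inflation-only — and resistance affects only P_aw, never the conserved
energy.

## Numeric oracle

The closed-form hazard ratios are cross-checked against an independent
route: composite trapezoid quadrature of the P–V areas along the inflation
line with unit compliance (compliance cancels in the ratio), default 1e5
panels. Because the integrands are linear in pressure the quadrature is
exact up to roundoff, so oracle agreement at 1e-9 absolute is a test of
the algebra, not of grid resolution.

## Degenerate inputs and policies

- Ps = PEEP (zero driving pressure) raises `DegenerateCycleError`.
- Pt outside [PEEP, Ps]: default `clamp` policy saturates (HR = 0 above
  Ps, HR = 1 below PEEP), preserving the geometric meaning and keeping
  batch runs alive; `strict` raises `DomainError`.
- Scenario closure: exactly one of {C, Ps} may be omitted and is derived
  from the other; if both are given they must satisfy Ps = V_T/C + PEEP to
  1e-9 relative.
- HR_Elastic = 1 admits no finite plateau target (`UnboundedTargetError`).
- Energies are kept in cmH2O·L internally; reports also emit joules via
  1 cmH2O·L = 0.0980665 J.

## Scenario batches and fixtures

Batch inputs are flat JSON objects or CSV rows with keys
`name, ps, peep, vt, c, f, pt` (pressures cmH2O, volumes L, frequency
breaths/min). Row-level validation failures become error rows and never
abort a batch. The seeded fixture generator draws PEEP ~ U[0, 15], DP ~
U[5, 25] (Ps = PEEP + DP), Pt ~ U[PEEP, Ps], V_T ~ U[0.2, 0.8] L and f ~
U[10, 35] min⁻¹ — a grid spanning the clinically plausible passive-ARDS
range — and is byte-reproducible for a given seed. These synthetic grids
exercise the algebraic and geometric properties of the model; they do not
emulate measurement noise, breath-to-breath variability, nonlinear
compliance or active effort, so passing tests validate the calculator, not
the model's fidelity to any patient.

## Problem sizes used in checks

The property suites run the oracle comparison on 10,000 randomized
triples, round trips on a 100-scenario × ~50-ratio grid, waveform
invariance on 22 profiles at 2000 steps, and regional structure on
50 scenarios; `scripts/acceptance.py` re-derives its reported quantities
from scratch at comparable sizes. All sizes are configurable through the
public interfaces.

## Known limitations

Everything the threshold model abstracts away: no chest-wall/esophageal
partitioning, no resistive or expiratory energy, no stress amplification
from tissue heterogeneity, no vascular cofactors, no frequency re-tuning
rule for constant minute ventilation. The regional module is a
parameterized stand-in for a full regional mechanics treatment: it moves
only the threshold, not the local compliance or volume distribution.
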