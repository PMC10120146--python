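# vilipower

Energy-based bedside assessment of ventilator-induced lung injury (VILI)
risk for passive mechanical ventilation.

Clinicians steer lung-protective ventilation with static airway pressures —
plateau pressure Ps, PEEP, driving pressure DP = Ps − PEEP — yet tissue is
injured by *energy*, not pressure alone. `vilipower` turns those bedside
numbers into an explicit per-breath energy budget: it partitions the
conserved (elastic) energy of each inflation at a threshold elastic
pressure Pt into "safe" and "hazardous" fractions, inversely solves
ventilator-setting targets that achieve a tolerated hazard, extends the
threshold regionally along the gravitational pleural-pressure gradient,
and expresses damaging power as frequency × supra-threshold energy.

The core quantities, for a passive breath with tidal volume V_T and linear
compliance C = V_T/DP:

    W_Elastic = ½ (Ps + PEEP) V_T            total elastic energy per cycle
    W_Drive   = ½ DP · V_T                   tidal (PEEP-excluding) component

    HR_Drive   = (2DP + Pt − Ps)(Ps − Pt)/DP²     hazardous fraction of W_Drive
    HR_Elastic = (Ps² − Pt²)/(Ps² − PEEP²)        hazardous fraction of W_Elastic
    SR = 1 − HR                                    safety ratio

    damaging power = f · HR · W              [cmH2O·L/min; ×0.0980665 → J/min]

and the closed-form inverse targets

    Target DP  = (1 − √(1 − HR_Drive))/HR_Drive · (Ps − Pt)
    Target Ps  = √((Pt² − HR_Elastic·PEEP²)/(1 − HR_Elastic))
    Target V_T = (Target DP/DP)·V_T = ((Target Ps − PEEP)/DP)·V_T

Intended users: respiratory physiologists and critical-care researchers
exploring threshold-based energy partitioning, and anyone who wants the
algebra above as tested, scriptable code. It is a conceptual calculator,
not a clinical device.

## Worked example

A common ARDS-range pattern: Ps = 25 cmH2O, PEEP = 5 cmH2O, V_T = 0.5 L,
f = 20 breaths/min, with the damage threshold at Pt = 20 cmH2O.

```python
from vilipower import VentilationScenario, partition, prescribe

s = VentilationScenario(ps=25, peep=5, vt=0.5, f=20, pt=20)
p = partition(s)
print(p.w_elastic, p.w_drive)            # 7.5 5.0        cmH2O·L per breath
print(p.hr_drive, p.hr_elastic)          # 0.4375 0.375
print(p.hazardous_energy_drive)          # 2.1875         cmH2O·L per breath
print(p.damaging_power_drive)            # 43.75          cmH2O·L/min
print(round(p.damaging_power_drive_j, 3))  # 4.29         J/min

rx = prescribe(s, 0.1, variant="elastic", kind="hazard")
print(round(rx.target_ps, 3), round(rx.target_vt, 4))   # 21.016 0.4004
```

Reading: each breath stores 7.5 cmH2O·L of elastic energy, 5.0 of it
tidal. With the threshold at 20 cmH2O, 43.75 % of the tidal energy
(2.1875 cmH2O·L) is delivered above threshold; at 20 breaths/min that is a
damaging power of 43.75 cmH2O·L/min (≈ 4.29 J/min). To cap the
all-inclusive elastic hazard at 10 % while keeping PEEP and Pt fixed, the
plateau would have to come down to ≈ 21.0 cmH2O, i.e. tidal volume down to
≈ 0.40 L.

The same is available from a shell:

```
vilipower compute --ps 25 --peep 5 --vt 0.5 --f 20 --pt 20
vilipower target 0.1 --ps 25 --peep 5 --vt 0.5 --pt 20 --variant elastic
vilipower regional --ps 25 --peep 5 --vt 0.5 --pt 20 --gradient-span 6
vilipower simulate trace.csv --ps 25 --peep 5 --vt 0.5 --pt 20 --waveform decelerating
vilipower fixtures batch.json --seed 1 --n 25 && vilipower batch batch.json report.tsv
```

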