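# alveotension

Translate bedside ventilator measurements into the stresses that actually
act at the alveolar boundary.

Ventilator-induced lung injury (VILI) is monitored at the bedside through
pressures and volumes — plateau pressure *P*<sub>plat</sub>, PEEP, driving
pressure DP and tidal volume *V*<sub>T</sub> — but the tissue-rending force
develops in the shell-like cellular membrane (SLM) that encloses the
alveolar space, where the relevant variables are wall **tension** (force
per unit length) and **surface area**, not pressure and volume.
`alveotension` implements the spherical model that connects the two
descriptions, for clinicians and physiologists reasoning about mechanical
power and damaging energy in ARDS.

## The model

The aerated lung (or any subunit of it) is a thin-walled sphere with
constant compliance *C*:

- **Geometry.** R = (3V/4π)<sup>1/3</sup>, A<sub>s</sub> = 4πR², and the
  finite-increment strain ratio ΔA/ΔV = 3(R₂² − R₁²)/(R₂³ − R₁³) → 2/R.
- **LaPlace tension.** T = PR/2 (thin wall); with wall thickness *z*,
  T = PR/2z (a wall stress), where a fixed quantity of wall tissue thins
  on expansion: z = z₀(R₀/R)².
- **Absolute volume.** V = FRC + PEEP·C + V<sub>T</sub>, with the
  unmeasured resting volume of the ARDS "baby lung" estimated as
  V<sub>rest</sub> = (C<sub>obs</sub>/C<sub>norm</sub>) · FRC<sub>pred</sub>.
- **Subunit scaling.** Splitting the same volume at the same pressure into
  *n* subunits scales each wall tension by n<sup>−1/3</sup>
  (T<sub>B</sub> = T<sub>A</sub>/(n<sub>B</sub>/n<sub>A</sub>)<sup>1/3</sup>):
  more aerated units means less tension per unit.
- **Energy.** Elastic energy per breath is the area under the P–V curve,
  C(P₂² − P₁²)/2, identically equal to the accumulated T·ΔA<sub>s</sub> at
  the membrane. The **damaging energy** DE is the part delivered above a
  pressure threshold Pt, and the **damaging power** is f × DE for
  frequency f. Pressure thresholds map to tension thresholds and back.

Units are fixed: cm, mL, cmH₂O; tension in cmH₂O·cm; energy in mL·cmH₂O
(1 mL·cmH₂O = 9.80665×10⁻⁵ J, displayed where useful).

## Worked example

A moderate-ARDS patient with observed compliance 40 mL/cmH₂O (normal
reference 80, predicted FRC 2400 mL, so an estimated resting baby-lung
volume of 1200 mL), ventilated with V_T = 400 mL at PEEP 10 cmH₂O and
20 breaths/min, damage threshold 15 cmH₂O:

```yaml
# scenario.yaml
patient:
  C_obs_ml_cmH2O: 40.0
  C_norm_ml_cmH2O: 80.0
  FRC_pred_ml: 2400.0
vent:
  V_T_ml: 400.0
  PEEP_cmH2O: 10.0
  f_per_min: 20.0
Pt_cmH2O: 15.0
```

```sh
$ alveotension compute scenario.yaml --out out
P_plat=20.000 cmH2O  E_total=6000.00 mL*cmH2O  DE=3500.00 mL*cmH2O (delivered)  power=70000.00 mL*cmH2O/min (6.8647 J/min)
```

Plateau pressure is PEEP + V_T/C = 20 cmH₂O; the tidal elastic energy is
C(20² − 10²)/2 = 6000 mL·cmH₂O, of which 40·(20² − 15²)/2 = 3500 mL·cmH₂O
is delivered above the 15 cmH₂O threshold — about 6.86 J/min of damaging
power at this rate. `out/states.csv` holds the sphere states:

```
phase,scale,P_cmH2O,R_cm,V_ml,A_s_cm2,T_cmH2Ocm,z_cm
end_exp,whole,10.0,7.25566335719562,1600.0,661.5521922250875,36.2783167859781,
end_insp,whole,20.0,7.815926417967721,2000.0,767.6633170710054,78.15926417967721,
...
```

At end-inspiration the 2000 mL sphere (1200 resting + 400 PEEP volume +
400 tidal) has radius 7.82 cm and wall tension PR/2 ≈ 78.2 cmH₂O·cm.
Over this breath volume rises 25 %, membrane area 16 %, but tension
115 % — tension outpaces the strain the membrane experiences, which is the
model's central clinical point.

The same library is importable directly (`alveotension.run_scenario`,
`whole_lung_state`, `subunit_state`, `prediction_sweep`, ...), and
`alveotension sweep` / `alveotension fixtures` run parameter grids and
generate seeded synthetic scenario sets.

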