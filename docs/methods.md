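# Methods

## Model

The package treats the aerated lung compartment — at whole-lung or
subunit scale — as a single thin-walled, balloon-like sphere with uniform
inflation properties and a constant respiratory-system compliance *C*
over the tidal range. Every inflation state is then a point
(P, R, V, A_s, T): pressure, radius, volume, membrane surface area and
wall tension, linked by V = 4πR³/3, A_s = 4πR² and the LaPlace relation
T = PR/2. The `SphereState` container enforces these identities at
construction (relative tolerance 1e-12), so no downstream computation can
operate on an inconsistent state. Pressures are the monitored elastic
(static) respiratory-system pressures; flow-resistive pressure is
dissipated, not stored, and is excluded throughout. Negative pressures
are rejected rather than interpreted: this is an inflation model.

Two descriptions of the conserved elastic energy coexist: the radial
∫P dV and the surface ∫T dA_s. For a sphere they are identical
(T dA = (PR/2)(8πR dR) = P·4πR² dR = P dV), and the package keeps both —
closed forms on the P–V side as the primary computation, trapezoidal
accumulation of T ΔA_s along an `InflationPath` as the independent check
and as the route for user-supplied nonlinear paths. The energy identity
is what licenses translating bedside P–V quantities into
membrane-boundary tension and area, where stretch injury actually occurs.

## Clinical layer

Absolute volume at end-expiration is V_rest + C·PEEP and at
end-inspiration additionally + V_T. The unmeasured resting volume of the
ARDS baby lung is estimated as V_rest = (C_obs/C_norm)·FRC_pred, on the
assumption that observed compliance counts open, quasi-normally
compliant units rather than measuring unit stiffness. C_norm outside
80–100 mL/cmH2O triggers a warning, not an error — the estimate degrades
rather than breaks. FRC_pred depends on age, sex and body size through
published reference equations that are not reproduced here; it is a
required input.

The lung resolves into n identical spherical subunits sharing one
pressure. Each has volume V/n, radius R/n^(1/3) and hence tension
T/n^(1/3); two lungs of equal cumulative volume and pressure compare as
T_B/T_A = (n_B/n_A)^(−1/3). The absolute value of n is not identifiable
from bedside data, so n is user-supplied or derived as round(V_rest/v0)
from a per-subunit resting volume v0; all cross-lung statements the
package makes are ratio-based and independent of the absolute scale, and
absolute subunit tensions should be read as scale-dependent.

In FRC sweeps, compliance is re-coupled to the swept FRC through constant
specific compliance, C_obs = C_norm·FRC/FRC_pred, with the subunit count
scaling alongside (fixed v0). Without this coupling the inverse
tension–FRC relation would not follow; with it, end-inspiratory subunit
tension is strictly decreasing in FRC at zero PEEP and fixed V_T. The
constant-specific-compliance assumption is known to weaken in late,
fibrotic ARDS; no alternative is modelled.

## Damaging energy and thresholds

Damaging energy is the per-breath elastic energy associated with
pressures above a threshold Pt. Two conventions are implemented because
the notion is genuinely ambiguous: `delivered` (default) counts all
energy delivered while P > Pt, C(P_plat² − P_lo²)/2 with
P_lo = max(Pt, PEEP); `excess` subtracts the part a breath would store at
P = Pt, i.e. minus C·Pt·(P_plat − P_lo). The lower bound is never below
PEEP: the PEEP-stored volume's energy is held between breaths, and only
the tidal cycle's delivery is counted each cycle. Damaging power is
exactly f × DE. A pressure threshold maps to the wall tension at the
crossing moment, Tt = Pt·R(V_rest + C·Pt)/2; the inverse map (expressing
a tension-defined safety limit as a monitorable pressure) is strictly
monotone and solved by bracketed Brent iteration to 1e-8 cmH2O, with a
default 500 cmH2O bracket cap beyond which a convergence error is raised.

## Wall thickness

Alveolar walls are not negligibly thin. In thick mode the quantity
PR/2z is computed; it has pressure units and is named wall *stress*,
with the identity stress × z = thin-wall tension documented and tested,
so the thin and thick formulas never get unit-confused. The wall is a
fixed quantity of tissue: the default thinning law conserves thin-shell
tissue volume, 4πR²z constant, so z = z0(R0/R)² — thicker on contraction,
thinner on expansion. The reference state (R0, z0) is explicit; whether
z0 is measured at FRC or another inflation is the caller's choice. The
law is a strategy hook (`WallModel.thinning_law`) so a mid-surface or
incompressible thick-shell law can be substituted without touching the
rest of the model.

## Numerical choices

- Units: cm / mL / cmH2O throughout; 1 mL·cmH2O = 9.80665e-5 J and
  1 cmH2O·cm = 0.980665 N/m exist only as display conversions.
- The finite-increment ratio ΔA/ΔV switches to its analytic limit 2/R1
  when |R2 − R1| < 1e-9·max(R1, R2), preserving continuity instead of
  evaluating 0/0.
- The force-balance residual is evaluated in the factored form
  πR(PR − 2T), algebraically identical to πR²P − 2πRT, so equilibrium
  states cancel exactly in floating point.
- The finite tension increment (P2R2 − P1R1)/2 is primary; the
  differential form (R ΔP + P ΔR)/2 is exposed alongside it. Their gap is
  exactly ΔP·ΔR/2, second order in the increments.
- `InflationPath` requires at least two states and strictly increasing
  volumes; degenerate (zero-volume-change) paths are rejected rather than
  silently integrating to zero.
- Identity tests use relative 1e-12 where the algebra is exact, matching
  the state-consistency tolerance; "exact zero" is asserted only where
  the factored evaluation guarantees it.

## Synthetic scenarios

`generate_fixtures` draws seeded, clinically plausible scenario sets:
severity strata fix C_obs/C_norm on {0.2, 0.4, 0.6, 0.8, 1.0} (the
baby-lung fraction of units still aerated), C_norm uniform on 80–100
mL/cmH2O, FRC_pred on 1800–3000 mL, PEEP on 0–20 cmH2O, V_T on
200–600 mL, f on 10–35 /min and Pt on 15–25 cmH2O. These emulate the
*ranges* of adult ICU ventilation, not their joint clinical distribution:
parameters are drawn independently, so combinations a clinician would
avoid (high V_T on a stiff lung) occur by design, which is useful for
stress-testing invariants. Passing tests on these fixtures demonstrates
the model's internal consistency over the clinical envelope, not
agreement with any patient data.

Desk-scale problem sizes are used throughout the suite and the
acceptance script — 10⁴ path states and 100 random inflations for the
energy identity, 10⁶ random states for the force balance, 10⁴ scenarios
for the strain ordering — enough to expose any discretisation or
algebra error while keeping the whole suite under a minute.

## Limitations

Real alveoli are irregular, interdependent, and unfold before they
stretch at low volume; no shape-correction factor exists in the model.
Stress focusing at interfaces between open and collapsed tissue — a major
amplifier of local tension in ARDS — is out of scope, as are
recruitment/derecruitment dynamics, surfactant film dynamics,
viscoelastic dissipation, expiratory energetics, heterogeneous subunit
populations and chest-wall/transpulmonary pressure partitioning: the
model takes whatever elastic pressure it is given. Constant compliance
is assumed over the tidal range and is unrealistic at the extremes of
inflation. The model is a conceptual translation device, not a
quantitative predictor for individual patients.
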