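# Methods

## Physical model

`skinburn` models a flat patch of skin as a one-dimensional layered slab
(epidermis, dermis, subcutaneous fat) and solves transient heat
conduction

    rho C dT/dt = d/dx ( k dT/dx ),      0 <= x <= Delta,

with constant per-layer properties.  Blood perfusion and metabolic heat
are neglected: the exposures of interest last a fraction of a second to
a few tens of seconds, during which external surface fluxes (tens of
kW/m^2) dwarf perfusion, and vasodilation needs tens of seconds to
respond.  Properties are temperature-independent.  The inner boundary at
x = Delta is adiabatic; the slab is deep enough (11.343 mm with the
default stack) that the surface history never reaches it during a run —
the bottom node first moves at the fifth decimal after ~32 s in the
reference scenario, so the adiabatic wall has no influence on the
damage-relevant depths.

The skin surface follows a piecewise schedule of three boundary-condition
kinds:

* **convective** — spray or pool cooling, flux out of the skin
  `h (T_s - T_water)`;
* **fixed flux** — flame exposure, a prescribed net flux into the skin
  (the flux absorbed after any water-film losses);
* **adiabatic** — transport through air, where free convection is
  negligible next to the other two mechanisms.

The reference scenario is 30 s of 5 degC spray cooling (h = 300
W/m^2 K), 1 s relaxation, 0.74 s of flame at 62 kW/m^2, 1.26 s
relaxation, then pool cooling at the spray temperature; the case catalog
permutes water temperature, pre-wetting time, exposure length and the
62/86 kW/m^2 wet/dry flux split.  Shortening the spray phase shifts all
later breakpoints so that the relaxation and flame durations are
preserved and the pool phase always lasts 7 s.

## Thermal injury

Injury is quantified by the Henriques damage index
`Omega = ln(C0/C_tau)`, accumulated at the basal layer with first-order
Arrhenius kinetics gated at 44 degC:

    dOmega/dt = P exp(-dE / (R T)),   T >= 44 degC; 0 otherwise,

with `P = 2.185e124 1/s, dE = 7.78e5 J/mol` for 44-50 degC and
`P = 1.823e51 1/s, dE = 3.27e5 J/mol` above 50 degC.  The two parameter
sets do not meet continuously: the rate jumps at the band switch, and
the inclusive low band owns exactly 50 degC.  This discontinuity is a
property of the published parameter pairs and is deliberately not
smoothed.  `Omega` thresholds 0.53 / 1.0 / 1e4 separate no burn and
first-, second- and third-degree burns; the pain threshold is 44.8 degC
at the 0.1 mm receptor depth.

The damage-evaluation depth defaults to 0.1 mm even though the default
epidermis is only 43 um thick — the convention places the "basal layer"
at the pain-receptor depth rather than at the anatomical
epidermis-dermis junction — and is configurable.

Two numerical points matter here.  First, `P exp(-dE/RT)` pairs a
~1e124 prefactor with a ~1e-126 exponential, so the rate is evaluated in
log space (`exp(ln P - dE/RT)`); the unit tests check it against a
50-digit mpmath evaluation.  Second, the integral is a trapezoidal
quadrature of the gated rate over the recorded series (1 ms default
sampling); halving the sampling interval moves the reference-case
`Omega` by far less than 0.5%, and a constant supra-threshold hold
reproduces `duration x rate` exactly.

## Discretization

Space: a uniform vertex-centred finite-volume grid.  Interior nodes own
a cell of width dx, the two boundary nodes own half cells, and the
conductivity at each cell face is the harmonic mean of the adjacent node
conductivities, which keeps the interface flux continuous across layer
boundaries.  A node lying exactly on a layer interface takes the deeper
layer's properties; interfaces that do not fall on a node are snapped to
the nearest node and the snapped geometry is recorded.  With both
boundaries adiabatic the scheme conserves discrete enthalpy to rounding
error, which the test suite verifies to 1e-6 relative.

Time: two schemes.

* **explicit** (default) — forward Euler, subject to the Fourier limit
  `Fo = a_max dt / dx^2 < 1/2`; the solver refuses an unstable
  configuration and names the offending Fourier number.  At dx = 1 um
  the dermis (a = 1.14e-7 m^2/s) limits dt to just over 4 us.
* **implicit** — a theta scheme (Crank-Nicolson, theta = 0.5, by
  default; backward Euler at theta = 1) with one Thomas tridiagonal
  solve per step, unconditionally stable.  Crank-Nicolson at dt = 1 ms
  reproduces the explicit basal-layer series of the reference case
  within 1e-3 degC at roughly a fifth of the cost; the acceptance suite
  gates the two schemes against each other at 0.1 degC.

Phase boundaries are rounded to the nearest time step (worst-case timing
error dt/2, i.e. ~8 us of a 0.74 s exposure at the resolutions used).
Probe depths that fall between nodes are linearly interpolated from the
two bracketing nodes at recording time.

Resolution defaults: dx = 1 um, dt = 4 us reproduce the historically
used settings; all damage results in the tests and the acceptance
script are computed at dx = 2 um (explicit, Fo ~ 0.45), where the grid
convergence gate shows `Omega` moves by far less than 0.01 relative to
dx = 1 um on representative cases.  The full 13-case table takes about
2.5 minutes explicit at dx = 2 um on one core, and about 30 s with the
implicit scheme at 1 ms.

## Validation oracles

The solver is checked against independent references that share none of
its code:

* the exact semi-infinite constant-flux solution
  `T = T0 + (q/k)[2 sqrt(at/pi) e^{-x^2/4at} - x erfc(x/2 sqrt(at))]`
  and the convective erfc solution, within 1% before back-wall
  influence (agreement is in practice ~1e-4 relative);
* an independently assembled method-of-lines system integrated with
  scipy's BDF solver on a scaled-down layered five-phase scenario
  (agreement < 0.02 degC);
* discrete enthalpy bookkeeping under flux and adiabatic phases;
* a maximum principle under purely convective/adiabatic schedules.

## What the case catalog does and does not emulate

The catalog encodes idealized exposure scenarios: piecewise-constant
net fluxes, instantaneous phase switches, uniform 33 degC initial
temperature, one spatial dimension.  Real exposures differ: the net
flame flux rises as the protecting water film thins and evaporates,
there is radiant pre- and post-exposure outside the flame zone, skin
curvature and site-to-site thickness variation matter, and perfusion
responds over longer times.  Passing the property gates therefore
demonstrates correct conduction physics and damage bookkeeping for the
stated scenarios, not a validated prediction of a specific real burn.

## Reference-value comparison

Each catalogued case carries the damage integral reported for that
scenario in the original case study of this exposure (`expected_omega`),
and `reproduce_table` reports deviations against a configurable
tolerance (default +-0.03 absolute or +-10% relative).  With the
catalogued inputs exactly as stated, the computed integrals come out
systematically far below those reference values (factors ~10-70; e.g.
reference scenario 0.0013 vs 0.13, warmest-water case 0.23 vs 2.38),
while reproducing their qualitative structure: late high flux harms more
than early, and damage grows with warmer spray water, shorter
pre-wetting and longer exposure.  The closed-form and
independent-integrator checks above, plus grid and scheme refinement,
rule out discretization as the cause: the stated spray cooling
(h = 300 W/m^2 K, 5 degC, 30 s) cools the 0.1 mm depth to ~14.8 degC
(reported: 18.6), and no material in the stack can raise 0.1 mm by the
reported +39.5 K under 62 kW/m^2 for 0.74 s.  The reference values
appear to derive from an effectively weaker spray exchange and a lower
near-surface conductivity than the stated inputs.  The package keeps the
stated inputs and surfaces the deviations in the comparison report
rather than adjusting any parameter to match.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| layer stack | 43 um / 1.3 mm / 10 mm | epidermis, dermis, subcutaneous (back) |
| initial temperature | 33 degC | uniform skin temperature |
| h (spray and pool) | 300 W/m^2 K | water-skin exchange |
| wet / dry flame flux | 62 / 86 kW/m^2 | with and without water film |
| injury / pain threshold | 44.0 / 44.8 degC | rate gate; pain onset |
| evaluation depth | 0.1 mm | basal layer |
| dx, dt | 1 um, 4 us | explicit-scheme resolution |
| record interval | 1 ms | probe sampling for damage quadrature |

## Known limitations

* One-dimensional, constant-property, perfusion-free conduction only;
  no evaporation-front or boiling model at the surface.
* Piecewise-constant fluxes only; no ramps.
* Damage is evaluated at stated probe depths, not as a depth-resolved
  map.
* The bundled reference damage integrals are not reproduced
  quantitatively from the stated inputs (see above); comparisons against
  them should be read with that deviation in mind.
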