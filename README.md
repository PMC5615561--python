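# skinburn

Transient heat conduction through layered skin with Arrhenius
burn-damage integration, built around a documented flame-stunt case
study: a water-sprayed person passing through engulfing kerosene flames,
with spray pre-cooling, flame exposure and pool cooling in one
continuous simulation.

The package is aimed at fire-safety and thermal-injury modellers who
want a small, verifiable 1D bioheat tool: it solves

    rho C \partial T/\partial t = \partial/\partial x (k \partial T/\partial x)

on an epidermis/dermis/subcutaneous stack under a five-phase surface
boundary schedule — convective water-spray cooling, adiabatic
relaxation, prescribed flame heat flux, a second relaxation, convective
pool cooling — and accumulates the Henriques damage integral at the
basal layer (0.1 mm):

    \Omega = \int P exp(-\Delta E / (R T)) dt   for T >= 44 degC,

with the two-band parameter set (P = 2.185e124 1/s, dE = 7.78e5 J/mol up
to 50 degC; P = 1.823e51 1/s, dE = 3.27e5 J/mol above) and burn-degree
thresholds Omega = 0.53 / 1.0 / 1e4.  See `docs/methods.md` for the
discretization, validation oracles and limitations.

## Worked example

Run the reference scenario (case A: 30 s of 5 degC spray, 0.74 s of
62 kW/m^2 flame) at 2 um resolution:

```sh
$ skinburn run --case A --dx 2e-6 --dt 1.6e-5 --out out/
phase convective: 0 -> 30 s
phase adiabatic: 30 -> 31 s
phase fixed_flux: 31 -> 31.74 s
phase adiabatic: 31.74 -> 33 s
phase convective: 33 -> 40 s
omega = 0.00133121 (none)
wrote out/history_a.csv and out/report_a.csv
```

The log echoes the five schedule phases, then the damage integral at
0.1 mm depth with its classification: the spray pre-cooling keeps the
basal layer cold enough (peak 49.1 degC in this computation) that the
accumulated damage 0.0013 stays far below the 0.53 first-degree
threshold.  `history_a.csv` holds the probe temperature series (time_s
plus one column per depth), `report_a.csv` the damage summary including
pain onset and duration.

The full scenario matrix (flux splits, warmer water, shorter
pre-wetting, longer exposure) with its comparison against the damage
integrals reported in the original study of this stunt:

```sh
$ skinburn table --out case_table.csv
case  computed_omega  expected_omega  ...  basal_peak_C  pain_duration_s
   A        0.001331            0.13  ...     49.146369         0.265588
   B        0.003554            0.25  ...     51.021657         0.314967
   ...
   K        0.226148            2.38  ...     60.697116         1.470830
   M        0.077068            1.51  ...     58.413807         0.952605
```

The computed integrals reproduce the study's qualitative findings —
high flux late in the exposure harms more than the same energy early
(B > C, E > F), and damage rises steeply with warmer spray water
(A < J < K), shorter pre-wetting (A < H < I) and longer exposure
(B < L) — but sit well below the reported magnitudes; the
`within_tolerance` column flags this, and `docs/methods.md` documents
why the deviation is attributed to the study's stated inputs rather
than to discretization.

Custom scenarios go in a YAML file (any omitted field keeps the
reference value):

```yaml
schedule:
  water_temp: 25        # degC, spray and pool
solver:
  dx: 2.0e-6            # m
  scheme: implicit
  dt: 1.0e-3            # s
```

```sh
skinburn validate --config warm.yaml && skinburn run --config warm.yaml
```

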