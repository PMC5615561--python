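"""Conduction solver checks against independent oracles.

The closed-form oracles (semi-infinite constant-flux and convective erfc
solutions) are evaluated with scipy.special directly from the analytic
expressions; the layered oracle integrates an independently assembled
method-of-lines system with scipy's BDF solver.  Neither shares any code
with the package kernels.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

from skinburn import (
    BoundaryPhase,
    ExposureSchedule,
    LayerStack,
    SkinLayer,
    SolverConfig,
    TemperatureHistory,
    build_base_schedule,
    build_grid,
    convective_flux,
    probe_series,
    solve,
)
from skinburn.tissue import back_skin_stack

DERMIS = SkinLayer("dermis", 0.45, 1200.0, 3300.0, 5e-3)


def homogeneous_grid(dx=2e-6, layer=DERMIS):
    return build_grid(LayerStack((layer,)), dx)


def enthalpy(grid, field):
    w = np.ones(grid.n_nodes)
    w[0] = w[-1] = 0.5
    return float(np.sum(grid.node_volumetric_heat_capacity * field * w) * grid.spacing)


# ---------------------------------------------------------------- oracles


def surface_flux_closed_form(q, k, rho, cp, t, T0, x=0.0):
    """Semi-infinite solid, constant surface flux q from t=0 (exact)."""
    a = k / (rho * cp)
    s = np.sqrt(a * t)
    return T0 + (q / k) * (
        2.0 * np.sqrt(a * t / np.pi) * np.exp(-(x**2) / (4 * a * t)) - x * erfc(x / (2 * s))
    )


def convective_closed_form(h, Tf, k, rho, cp, t, T0, x=0.0):
    """Semi-infinite solid, convective exchange with fluid Tf from t=0 (exact)."""
    a = k / (rho * cp)
    s = np.sqrt(a * t)
    theta = erfc(x / (2 * s)) - np.exp(h * x / k + h * h * a * t / (k * k)) * erfc(
        x / (2 * s) + h * s / k
    )
    return T0 + (Tf - T0) * theta


def reference_mol_solution(stack, schedule, T0, dx, t_eval, probe_depth):
    """Independent layered reference: separately assembled control-volume
    operator integrated with scipy BDF."""
    from scipy import sparse

    iface = np.cumsum([l.thickness for l in stack.layers])
    n = int(round(iface[-1] / dx)) + 1
    depth = np.arange(n) * dx
    idx = np.minimum(np.searchsorted(iface, depth, side="right"), len(stack.layers) - 1)
    k = np.array([l.conductivity for l in stack.layers])[idx]
    rc = np.array([l.density * l.specific_heat for l in stack.layers])[idx]
    kh = 2 * k[:-1] * k[1:] / (k[:-1] + k[1:])
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    cap = rc * w * dx

    def surface_power(t, Ts):
        for p in schedule.phases:
            if p.start <= t <= p.end:
                if p.kind == "convective":
                    return p.heat_transfer_coefficient * (p.fluid_temperature - Ts)
                if p.kind == "fixed_flux":
                    return p.net_flux
                return 0.0
        return 0.0

    def rhs(t, T):
        q = kh * (T[1:] - T[:-1]) / dx
        dT = np.zeros(n)
        dT[:-1] += q
        dT[1:] -= q
        dT[0] += surface_power(t, T[0])
        return dT / cap

    jac = sparse.diags([np.ones(n - 1), -2 * np.ones(n), np.ones(n - 1)], [-1, 0, 1], format="csc")
    sol = solve_ivp(
        rhs, (0.0, schedule.t_end), np.full(n, T0), method="BDF", t_eval=t_eval,
        jac_sparsity=jac, rtol=1e-9, atol=1e-9, max_step=0.05,
    )
    node = int(round(probe_depth / dx))
    return sol.y[node]


# ----------------------------------------------------------------- tests


def test_adiabatic_equilibrium_is_exact():
    grid = homogeneous_grid(dx=10e-6, layer=SkinLayer("slab", 0.45, 1200, 3300, 1e-3))
    sched = ExposureSchedule((BoundaryPhase("adiabatic", 0.0, 1.0),), 1.0)
    cfg = SolverConfig(dx=10e-6, dt=1e-4, probe_depths=(0.0, 5e-4))
    hist = solve(grid, sched, 33.0, cfg)
    assert np.all(hist.probe_temperatures == 33.0)
    assert np.all(hist.final_field == 33.0)


@pytest.mark.parametrize("scheme,dt", [("explicit", 1.6e-5), ("implicit", 5e-4)])
def test_constant_flux_matches_semi_infinite_closed_form(scheme, dt):
    """Surface and 0.1 mm temperatures under constant flux stay within 1%
    of the exact semi-infinite solution before the back wall is felt."""
    grid = homogeneous_grid()
    sched = ExposureSchedule((BoundaryPhase("fixed_flux", 0.0, 0.5, net_flux=62e3),), 0.5)
    cfg = SolverConfig(dx=2e-6, dt=dt, scheme=scheme, probe_depths=(0.0, 1e-4), record_interval=1e-3)
    hist = solve(grid, sched, 33.0, cfg)
    for x in (0.0, 1e-4):
        times, temps = probe_series(hist, x)
        for t_check in (0.05, 0.2, 0.5):
            got = np.interp(t_check, times, temps)
            exact = surface_flux_closed_form(62e3, 0.45, 1200, 3300, t_check, 33.0, x)
            rise_exact = exact - 33.0
            if rise_exact > 0.5:
                assert abs(got - exact) / abs(rise_exact) < 0.01


def test_convective_cooling_matches_erfc_closed_form():
    grid = homogeneous_grid()
    sched = ExposureSchedule(
        (BoundaryPhase("convective", 0.0, 5.0, heat_transfer_coefficient=300.0,
                       fluid_temperature=5.0),), 5.0)
    cfg = SolverConfig(dx=2e-6, dt=1.6e-5, probe_depths=(0.0, 1e-4, 1e-3))
    hist = solve(grid, sched, 33.0, cfg)
    for x in (0.0, 1e-4, 1e-3):
        times, temps = probe_series(hist, x)
        for t_check in (0.5, 2.0, 5.0):
            got = np.interp(t_check, times, temps)
            exact = convective_closed_form(300.0, 5.0, 0.45, 1200, 3300, t_check, 33.0, x)
            drop = 33.0 - exact
            if drop > 0.5:
                assert abs(got - exact) / drop < 0.01


def test_layered_solution_matches_independent_bdf_reference():
    """Full five-phase scenario on a scaled-down layered slab agrees with a
    separately assembled BDF method-of-lines integration to 0.02 degC."""
    stack = back_skin_stack(subcutaneous_thickness=1.5e-3)
    sched = build_base_schedule(2.0, 300.0, 5.0, 0.3, [(0.3, 62e3)], 0.4, 300.0, 5.0, 4.0)
    grid = build_grid(stack, 2e-6)
    cfg = SolverConfig(dx=2e-6, dt=1.6e-5, probe_depths=(1e-4,), record_interval=1e-3)
    hist = solve(grid, sched, 33.0, cfg)
    times, temps = probe_series(hist, 1e-4)
    t_eval = np.linspace(0.05, 4.0, 80)
    ref = reference_mol_solution(stack, sched, 33.0, 2e-6, t_eval, 1e-4)
    got = np.interp(t_eval, times, temps)
    assert np.max(np.abs(got - ref)) < 0.02


def test_energy_conservation_with_flux_and_adiabatic_phases():
    """Injected surface energy is accounted for to 1e-6 relative, and the
    enthalpy stays put during the adiabatic relaxation that follows."""
    layer = SkinLayer("slab", 0.45, 1200.0, 3300.0, 1e-3)
    grid = build_grid(LayerStack((layer,)), 2e-6)
    q, t_flux = 62e3, 0.2
    cfg = SolverConfig(dx=2e-6, dt=1e-5, probe_depths=(0.0,))
    short = ExposureSchedule(
        (BoundaryPhase("fixed_flux", 0.0, t_flux, net_flux=q),
         BoundaryPhase("adiabatic", t_flux, t_flux + 0.01)), t_flux + 0.01)
    long = ExposureSchedule(
        (BoundaryPhase("fixed_flux", 0.0, t_flux, net_flux=q),
         BoundaryPhase("adiabatic", t_flux, t_flux + 2.0)), t_flux + 2.0)
    h0 = enthalpy(grid, np.full(grid.n_nodes, 33.0))
    h_short = enthalpy(grid, solve(grid, short, 33.0, cfg).final_field)
    h_long = enthalpy(grid, solve(grid, long, 33.0, cfg).final_field)
    injected = q * t_flux
    assert abs((h_short - h0) - injected) / injected < 1e-6
    assert abs(h_long - h_short) / abs(h_short) < 1e-6


def test_maximum_principle_under_convective_schedule():
    """Without any fixed-flux phase, temperatures stay between the initial
    value and the coldest/warmest fluid."""
    grid = build_grid(back_skin_stack(subcutaneous_thickness=1.5e-3), 2e-6)
    sched = ExposureSchedule(
        (BoundaryPhase("convective", 0.0, 1.0, heat_transfer_coefficient=300.0, fluid_temperature=5.0),
         BoundaryPhase("adiabatic", 1.0, 1.5),
         BoundaryPhase("convective", 1.5, 3.0, heat_transfer_coefficient=500.0, fluid_temperature=45.0)),
        3.0)
    cfg = SolverConfig(dx=2e-6, dt=1.6e-5, probe_depths=(0.0, 1e-4, 1e-3))
    hist = solve(grid, sched, 33.0, cfg)
    assert hist.probe_temperatures.min() >= 5.0 - 1e-9
    assert hist.probe_temperatures.max() <= 45.0 + 1e-9
    assert np.all(np.diff(hist.times) > 0)


def test_split_flux_phase_equivalent_to_unsplit():
    """Splitting the flame phase into two segments of the same flux leaves
    the solution unchanged to floating tolerance."""
    grid = build_grid(back_skin_stack(subcutaneous_thickness=1.5e-3), 2e-6)
    cfg = SolverConfig(dx=2e-6, dt=1.6e-5, probe_depths=(0.0, 1e-4))
    one = build_base_schedule(1.0, 300.0, 5.0, 0.2, [(0.4, 62e3)], 0.3, 300.0, 5.0, 3.0)
    two = build_base_schedule(1.0, 300.0, 5.0, 0.2, [(0.25, 62e3), (0.15, 62e3)], 0.3, 300.0, 5.0, 3.0)
    h1 = solve(grid, one, 33.0, cfg)
    h2 = solve(grid, two, 33.0, cfg)
    assert np.allclose(h1.probe_temperatures, h2.probe_temperatures, atol=1e-9)


def test_implicit_agrees_with_explicit_on_scaled_scenario():
    grid = build_grid(back_skin_stack(subcutaneous_thickness=1.5e-3), 2e-6)
    sched = build_base_schedule(2.0, 300.0, 5.0, 0.3, [(0.3, 62e3)], 0.4, 300.0, 5.0, 4.0)
    he = solve(grid, sched, 33.0, SolverConfig(dx=2e-6, dt=1.6e-5, probe_depths=(1e-4,)))
    hi = solve(grid, sched, 33.0,
               SolverConfig(dx=2e-6, dt=5e-4, scheme="implicit", probe_depths=(1e-4,)))
    tq = np.linspace(0.0, 4.0, 2001)
    te, Te = probe_series(he, 1e-4)
    ti, Ti = probe_series(hi, 1e-4)
    assert np.max(np.abs(np.interp(tq, te, Te) - np.interp(tq, ti, Ti))) < 0.1


def test_unstable_explicit_config_refused_with_fourier_number():
    grid = homogeneous_grid()
    sched = ExposureSchedule((BoundaryPhase("adiabatic", 0.0, 1.0),), 1.0)
    cfg = SolverConfig(dx=2e-6, dt=2e-5, probe_depths=(0.0,))  # Fo ~ 0.57
    with pytest.raises(ValueError, match="Fo"):
        solve(grid, sched, 33.0, cfg)


class TestConvectiveFlux:
    def test_reference_magnitude(self):
        assert convective_flux(300.0, 33.0, 5.0) == pytest.approx(8400.0)

    def test_zero_driving_force(self):
        assert convective_flux(300.0, 20.0, 20.0) == 0.0

    def test_sign_symmetry(self):
        assert convective_flux(300.0, 5.0, 33.0) == pytest.approx(-8400.0)

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            convective_flux(-1.0, 33.0, 5.0)


class TestProbeSeries:
    def _history(self):
        return TemperatureHistory(
            times=np.array([0.0, 1.0]),
            probe_depths=(0.0, 1e-4, 2e-4),
            probe_temperatures=np.array([[30.0, 10.0, 20.0], [31.0, 12.0, 22.0]]),
            final_field=np.zeros(3),
            node_depths=np.array([0.0, 1e-4, 2e-4]),
        )

    def test_exact_depth_returns_recorded_series(self):
        _, temps = probe_series(self._history(), 1e-4)
        assert temps == pytest.approx([10.0, 12.0])

    def test_midway_depth_interpolates(self):
        _, temps = probe_series(self._history(), 1.5e-4)
        assert temps == pytest.approx([15.0, 17.0])

    def test_surface_depth(self):
        _, temps = probe_series(self._history(), 0.0)
        assert temps == pytest.approx([30.0, 31.0])

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            probe_series(self._history(), 5e-4)
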