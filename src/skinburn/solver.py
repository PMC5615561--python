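"""Transient 1D conduction solver over the heterogeneous skin grid.

Space is discretized with vertex-centred finite volumes: interior nodes
own a cell of width dx, the surface and bottom nodes own half cells, and
the conductivity at each cell face is the harmonic mean of the two
adjacent node conductivities (the standard choice for layered media,
which keeps the interface heat flux continuous).  The surface boundary
condition of the active schedule phase enters through a half-cell energy
balance; the deepest node is adiabatic throughout.

Two time schemes are available: explicit forward Euler (subject to the
Fourier stability limit Fo < 1/2) and an implicit theta scheme
(Crank-Nicolson by default) that solves one tridiagonal system per step
and remains stable at much larger time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .schedule import ExposureSchedule
from .tissue import Grid1D, check_stability

__all__ = [
    "SolverConfig",
    "TemperatureHistory",
    "solve",
    "probe_series",
    "convective_flux",
    "NumericalFailure",
]

_BC_CODE = {"adiabatic": _kernels.BC_ADIABATIC, "convective": _kernels.BC_CONVECTIVE,
            "fixed_flux": _kernels.BC_FIXED_FLUX}

#: default probe depths, m: surface and the basal layer (pain-receptor depth)
DEFAULT_PROBES = (0.0, 0.1e-3)


class NumericalFailure(RuntimeError):
    """Raised when the temperature field becomes non-finite during stepping."""


def convective_flux(h: float, surface_temp: float, fluid_temp: float) -> float:
    """Convective heat flux out of the skin, W/m^2: h (T_s - T_fluid).

    Positive when the skin is warmer than the fluid (cooling).
    """
    if h < 0:
        raise ValueError("heat transfer coefficient must be >= 0")
    return h * (surface_temp - fluid_temp)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for one run.

    Parameters
    ----------
    dx
        Grid spacing, m.  1 um resolves the epidermis very finely; 2 um
        gives indistinguishable damage results at a quarter of the cost.
    dt
        Time step, s.  The explicit scheme requires Fo = a_max dt/dx^2
        < 1/2; the implicit scheme accepts any dt.
    scheme
        ``"explicit"`` (forward Euler) or ``"implicit"`` (theta scheme).
    theta
        Implicit weighting: 0.5 = Crank-Nicolson (default), 1.0 =
        backward Euler.  Ignored by the explicit scheme.
    probe_depths
        Depths, m, whose temperature series are recorded.
    record_interval
        Sampling period of the recorded series, s.
    """

    dx: float = 1e-6
    dt: float = 4e-6
    scheme: str = "explicit"
    theta: float = 0.5
    probe_depths: tuple[float, ...] = DEFAULT_PROBES
    record_interval: float = 1e-3

    def __post_init__(self) -> None:
        if self.scheme not in ("explicit", "implicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dx <= 0 or self.dt <= 0 or self.record_interval <= 0:
            raise ValueError("dx, dt and record_interval must be positive")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")


@dataclass(frozen=True)
class TemperatureHistory:
    """Recorded temperature series at the probe depths plus the final field."""

    times: np.ndarray = field(repr=False)
    probe_depths: tuple[float, ...]
    probe_temperatures: np.ndarray = field(repr=False)  # (n_times, n_probes)
    final_field: np.ndarray = field(repr=False)
    node_depths: np.ndarray = field(repr=False)

    def to_frame(self):
        """Probe series as a DataFrame: time_s plus one column per depth (mm)."""
        import pandas as pd

        data = {"time_s": self.times}
        for j, depth in enumerate(self.probe_depths):
            data[f"T_{depth * 1e3:g}mm_C"] = self.probe_temperatures[:, j]
        return pd.DataFrame(data)


def probe_series(history: TemperatureHistory, depth: float) -> tuple[np.ndarray, np.ndarray]:
    """Temperature series at ``depth``, m.

    Returns the recorded series when the depth was probed; otherwise
    interpolates linearly between the two nearest recorded depths that
    bracket it.  Depths outside the domain raise a ValueError.
    """
    if depth < 0 or depth > history.node_depths[-1]:
        raise ValueError(f"depth {depth} m outside domain [0, {history.node_depths[-1]}] m")
    depths = np.asarray(history.probe_depths)
    exact = np.flatnonzero(np.isclose(depths, depth, rtol=0, atol=1e-12))
    if exact.size:
        return history.times, history.probe_temperatures[:, exact[0]]
    below = depths[depths < depth]
    above = depths[depths > depth]
    if not below.size or not above.size:
        raise ValueError(
            f"depth {depth} m not bracketed by recorded probes {sorted(depths)}"
        )
    lo, hi = below.max(), above.min()
    w = (depth - lo) / (hi - lo)
    ji = int(np.flatnonzero(depths == lo)[0])
    jk = int(np.flatnonzero(depths == hi)[0])
    temps = (1 - w) * history.probe_temperatures[:, ji] + w * history.probe_temperatures[:, jk]
    return history.times, temps


def _update_coefficients(grid: Grid1D, dt: float):
    """Per-node dt-scaled conduction coefficients cL, cR and surface cS."""
    k = grid.node_conductivity
    rhoc = grid.node_volumetric_heat_capacity
    dx = grid.spacing
    kh = 2.0 * k[:-1] * k[1:] / (k[:-1] + k[1:])  # harmonic mean at cell faces
    n = grid.n_nodes
    cL = np.zeros(n)
    cR = np.zeros(n)
    cL[1:] = dt * kh / (rhoc[1:] * dx**2)
    cR[:-1] = dt * kh / (rhoc[:-1] * dx**2)
    cR[0] *= 2.0  # half cells at both boundaries
    cL[-1] *= 2.0
    cS = 2.0 * dt / (rhoc[0] * dx)
    return cL, cR, cS


def solve(
    grid: Grid1D,
    schedule: ExposureSchedule,
    initial_temperature: float,
    config: SolverConfig,
) -> TemperatureHistory:
    """Advance the temperature field from t = 0 to schedule.t_end.

    The field starts uniform at ``initial_temperature`` (degC).  Phase
    boundaries are rounded to the nearest time step; probe depths that do
    not fall on a node are linearly interpolated from the bracketing
    nodes at recording time.

    Raises a ValueError for an unstable explicit configuration (naming
    the Fourier number) and :class:`NumericalFailure` if the field stops
    being finite, naming the offending time step.
    """
    if abs(grid.spacing - config.dx) > 1e-15:
        raise ValueError(f"grid spacing {grid.spacing} differs from config.dx {config.dx}")
    a_max = float(np.max(grid.node_conductivity / grid.node_volumetric_heat_capacity))
    if config.scheme == "explicit":
        fo, stable = check_stability(a_max, config.dt, grid.spacing)
        if not stable:
            raise ValueError(
                f"explicit scheme unstable: Fo = {fo:.3f} >= 0.5 for dt = {config.dt} s, "
                f"dx = {grid.spacing} m; reduce dt or use the implicit scheme"
            )
    for depth in config.probe_depths:
        grid.node_index(depth)  # raises if out of domain

    dt = config.dt
    n_steps = int(round(schedule.t_end / dt))
    bounds = [int(round(p.end / dt)) for p in schedule.phases]
    starts = [0] + bounds[:-1]
    record_every = max(1, int(round(config.record_interval / dt)))

    # probes -> bracketing node pairs and interpolation weights
    frac = np.array([d / grid.spacing for d in config.probe_depths])
    lo_nodes = np.clip(np.floor(frac).astype(np.int64), 0, grid.n_nodes - 1)
    hi_nodes = np.clip(lo_nodes + 1, 0, grid.n_nodes - 1)
    weights = np.clip(frac - lo_nodes, 0.0, 1.0)
    rec_nodes, inverse = np.unique(np.concatenate([lo_nodes, hi_nodes]), return_inverse=True)
    lo_cols = inverse[: len(frac)]
    hi_cols = inverse[len(frac):]

    n_rows = n_steps // record_every + 1
    tail = n_steps % record_every != 0
    out = np.empty((n_rows + tail, rec_nodes.size))

    T = np.full(grid.n_nodes, float(initial_temperature))
    work = np.empty_like(T)
    cL, cR, cS = _update_coefficients(grid, dt)

    if config.scheme == "implicit":
        lo_d = np.empty_like(T)
        di = np.empty_like(T)
        up = np.empty_like(T)
        cprime = np.empty_like(T)
        dprime = np.empty_like(T)

    for phase, s0, s1 in zip(schedule.phases, starts, bounds):
        kind = _BC_CODE[phase.kind]
        if phase.kind == "convective":
            p1, p2 = phase.heat_transfer_coefficient, phase.fluid_temperature
        elif phase.kind == "fixed_flux":
            p1, p2 = phase.net_flux, 0.0
        else:
            p1, p2 = 0.0, 0.0
        if config.scheme == "explicit":
            bad = _kernels.run_phase_explicit(
                T, work, cL, cR, cS, kind, float(p1), float(p2),
                s0, s1, record_every, rec_nodes, out,
            )
        else:
            bad = _kernels.run_phase_implicit(
                T, work, lo_d, di, up, cprime, dprime, cL, cR, cS, config.theta,
                kind, float(p1), float(p2), s0, s1, record_every, rec_nodes, out,
            )
        if bad >= 0:
            raise NumericalFailure(
                f"non-finite temperature at step {bad} (t = {bad * dt:.6g} s) "
                f"during the {phase.kind} phase [{phase.start}, {phase.end}] s"
            )

    # final state row (the kernels record *before* each update)
    out[-1] = T[rec_nodes]
    times = np.arange(n_rows) * (record_every * dt)
    times = np.append(times, n_steps * dt) if tail else np.append(times[:-1], n_steps * dt)

    probe_temps = (1.0 - weights) * out[:, lo_cols] + weights * out[:, hi_cols]
    return TemperatureHistory(
        times=times,
        probe_depths=tuple(config.probe_depths),
        probe_temperatures=probe_temps,
        final_field=T.copy(),
        node_depths=grid.node_depths.copy(),
    )
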