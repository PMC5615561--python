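"""Scenario configuration: YAML loading, defaults, validation, round-trip.

An empty configuration file reproduces the reference scenario (case A):
the three-layer back-skin stack, 33 degC initial temperature, the
five-phase spray/relax/flame/relax/pool schedule and the two-band
Henriques damage parameters.  Any field can be overridden; unknown keys
are rejected with the offending path so typos cannot silently revert a
run to its defaults.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from . import cases
from .damage import (
    INJURY_THRESHOLD,
    PAIN_THRESHOLD,
    ArrheniusBand,
    classify,
    damage_integral,
    henriques_bands,
    pain_metrics,
)
from .schedule import ExposureSchedule, build_base_schedule
from .solver import SolverConfig, TemperatureHistory, probe_series, solve
from .tissue import LayerStack, SkinLayer, back_skin_stack, build_grid

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "run_scenario"]


class ConfigError(ValueError):
    """A located configuration problem (field path + reason)."""


@dataclass(frozen=True)
class ScheduleParams:
    """Flat parameters of the five-phase schedule."""

    spray_duration: float = 30.0
    spray_h: float = cases.WATER_H
    water_temp: float = 5.0
    relax1: float = cases.RELAX_BEFORE
    flame_segments: tuple[tuple[float, float], ...] = ((0.74, cases.WET_FLUX),)
    relax2: float = cases.RELAX_AFTER
    pool_h: float = cases.WATER_H
    pool_time: float = cases.POOL_TIME

    def build(self) -> ExposureSchedule:
        t_end = (
            self.spray_duration + self.relax1 + sum(d for d, _ in self.flame_segments)
            + self.relax2 + self.pool_time
        )
        return build_base_schedule(
            self.spray_duration, self.spray_h, self.water_temp, self.relax1,
            list(self.flame_segments), self.relax2, self.pool_h, self.water_temp, t_end,
        )


@dataclass(frozen=True)
class DamageParams:
    threshold: float = INJURY_THRESHOLD
    pain_threshold: float = PAIN_THRESHOLD
    evaluation_depth: float = cases.BASAL_DEPTH
    bands: tuple[ArrheniusBand, ...] = field(default_factory=henriques_bands)


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified run."""

    stack: LayerStack = field(default_factory=back_skin_stack)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    damage: DamageParams = field(default_factory=DamageParams)
    initial_temperature: float = cases.INITIAL_SKIN_TEMPERATURE
    case: str | None = None

    def to_dict(self) -> dict[str, Any]:
        """Plain-data form, suitable for YAML dumping and reloading."""
        return {
            "case": self.case,
            "initial_temperature": self.initial_temperature,
            "layers": [asdict(layer) for layer in self.stack.layers],
            "schedule": {
                "spray_duration": self.schedule.spray_duration,
                "spray_h": self.schedule.spray_h,
                "water_temp": self.schedule.water_temp,
                "relax1": self.schedule.relax1,
                "flame_segments": [list(seg) for seg in self.schedule.flame_segments],
                "relax2": self.schedule.relax2,
                "pool_h": self.schedule.pool_h,
                "pool_time": self.schedule.pool_time,
            },
            "solver": {
                "dx": self.solver.dx,
                "dt": self.solver.dt,
                "scheme": self.solver.scheme,
                "theta": self.solver.theta,
                "probe_depths": list(self.solver.probe_depths),
                "record_interval": self.solver.record_interval,
            },
            "damage": {
                "threshold": self.damage.threshold,
                "pain_threshold": self.damage.pain_threshold,
                "evaluation_depth": self.damage.evaluation_depth,
                "bands": [asdict(b) for b in self.damage.bands],
            },
        }


def _require_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def _float(mapping: dict, key: str, default: float, path: str) -> float:
    value = mapping.get(key, default)
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}.{key}: expected a number, got {value!r}") from exc


def from_dict(raw: dict[str, Any] | None) -> ScenarioConfig:
    """Build a ScenarioConfig from plain data, applying defaults."""
    raw = dict(raw or {})
    _require_keys(raw, {"case", "initial_temperature", "layers", "schedule", "solver", "damage"}, "config")

    case_label = raw.get("case")
    sched_kwargs: dict[str, Any] = {}
    if case_label is not None:
        spec = cases.get_case(str(case_label))
        sched_kwargs = {
            "spray_duration": spec.spray_duration,
            "water_temp": spec.water_temp,
            "flame_segments": tuple(
                (frac * spec.exposure_time, flux) for frac, flux in spec.flame_segments
            ),
        }

    sched_raw = dict(raw.get("schedule") or {})
    _require_keys(
        sched_raw,
        {"spray_duration", "spray_h", "water_temp", "relax1", "flame_segments",
         "relax2", "pool_h", "pool_time"},
        "schedule",
    )
    base = ScheduleParams(**sched_kwargs)
    segments = sched_raw.get("flame_segments")
    if segments is not None:
        try:
            segments = tuple((float(d), float(q)) for d, q in segments)
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                "schedule.flame_segments: expected a list of [duration_s, flux_W_m2] pairs"
            ) from exc
    schedule = ScheduleParams(
        spray_duration=_float(sched_raw, "spray_duration", base.spray_duration, "schedule"),
        spray_h=_float(sched_raw, "spray_h", base.spray_h, "schedule"),
        water_temp=_float(sched_raw, "water_temp", base.water_temp, "schedule"),
        relax1=_float(sched_raw, "relax1", base.relax1, "schedule"),
        flame_segments=segments if segments is not None else base.flame_segments,
        relax2=_float(sched_raw, "relax2", base.relax2, "schedule"),
        pool_h=_float(sched_raw, "pool_h", base.pool_h, "schedule"),
        pool_time=_float(sched_raw, "pool_time", base.pool_time, "schedule"),
    )

    layers_raw = raw.get("layers")
    if layers_raw is None:
        stack = back_skin_stack()
    else:
        layers = []
        for i, lr in enumerate(layers_raw):
            path = f"layers[{i}]"
            _require_keys(dict(lr), {"name", "conductivity", "density", "specific_heat", "thickness"}, path)
            try:
                layers.append(
                    SkinLayer(
                        name=str(lr.get("name", f"layer{i}")),
                        conductivity=float(lr["conductivity"]),
                        density=float(lr["density"]),
                        specific_heat=float(lr["specific_heat"]),
                        thickness=float(lr["thickness"]),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"{path}: missing required field {exc.args[0]!r}") from exc
            except ValueError as exc:
                raise ConfigError(f"{path}: {exc}") from exc
        stack = LayerStack(tuple(layers))

    solver_raw = dict(raw.get("solver") or {})
    _require_keys(solver_raw, {"dx", "dt", "scheme", "theta", "probe_depths", "record_interval"}, "solver")
    defaults = SolverConfig()
    probes = solver_raw.get("probe_depths")
    try:
        solver_cfg = SolverConfig(
            dx=_float(solver_raw, "dx", defaults.dx, "solver"),
            dt=_float(solver_raw, "dt", defaults.dt, "solver"),
            scheme=str(solver_raw.get("scheme", defaults.scheme)),
            theta=_float(solver_raw, "theta", defaults.theta, "solver"),
            probe_depths=tuple(float(p) for p in probes) if probes is not None else defaults.probe_depths,
            record_interval=_float(solver_raw, "record_interval", defaults.record_interval, "solver"),
        )
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    damage_raw = dict(raw.get("damage") or {})
    _require_keys(damage_raw, {"threshold", "pain_threshold", "evaluation_depth", "bands"}, "damage")
    bands_raw = damage_raw.get("bands")
    if bands_raw is None:
        bands = henriques_bands()
    else:
        bands = []
        for i, br in enumerate(bands_raw):
            path = f"damage.bands[{i}]"
            _require_keys(dict(br), {"temp_low", "temp_high", "pre_exponential", "activation_energy"}, path)
            try:
                high = br["temp_high"]
                bands.append(
                    ArrheniusBand(
                        temp_low=float(br["temp_low"]),
                        temp_high=math.inf if high in (".inf", "inf", None) else float(high),
                        pre_exponential=float(br["pre_exponential"]),
                        activation_energy=float(br["activation_energy"]),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"{path}: missing required field {exc.args[0]!r}") from exc
            except ValueError as exc:
                raise ConfigError(f"{path}: {exc}") from exc
        bands = tuple(bands)
    damage_params = DamageParams(
        threshold=_float(damage_raw, "threshold", INJURY_THRESHOLD, "damage"),
        pain_threshold=_float(damage_raw, "pain_threshold", PAIN_THRESHOLD, "damage"),
        evaluation_depth=_float(damage_raw, "evaluation_depth", cases.BASAL_DEPTH, "damage"),
        bands=bands,
    )

    return ScenarioConfig(
        stack=stack,
        schedule=schedule,
        solver=solver_cfg,
        damage=damage_params,
        initial_temperature=float(raw.get("initial_temperature", cases.INITIAL_SKIN_TEMPERATURE)),
        case=str(case_label).upper() if case_label is not None else None,
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML scenario file; missing fields fall back to the reference run."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file {path} does not exist")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    return from_dict(raw)


@dataclass(frozen=True)
class ScenarioResult:
    """Everything one scenario run produces."""

    history: TemperatureHistory
    omega: float
    classification: str
    pain_onset: float | None
    pain_duration: float
    evaluation_depth: float
    breakpoints: tuple[float, ...]


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Solve the configured scenario and evaluate damage at the stated depth."""
    solver_cfg = cfg.solver
    if cfg.damage.evaluation_depth not in solver_cfg.probe_depths:
        solver_cfg = replace(
            solver_cfg, probe_depths=tuple(solver_cfg.probe_depths) + (cfg.damage.evaluation_depth,)
        )
    grid = build_grid(cfg.stack, solver_cfg.dx)
    sched = cfg.schedule.build()
    history = solve(grid, sched, cfg.initial_temperature, solver_cfg)
    times, temps = probe_series(history, cfg.damage.evaluation_depth)
    result = damage_integral(times, temps, cfg.damage.bands, cfg.damage.threshold)
    onset, duration = pain_metrics(times, temps, cfg.damage.pain_threshold)
    return ScenarioResult(
        history=history,
        omega=result.omega,
        classification=classify(result.omega),
        pain_onset=onset,
        pain_duration=duration,
        evaluation_depth=cfg.damage.evaluation_depth,
        breakpoints=tuple(sched.breakpoints),
    )
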