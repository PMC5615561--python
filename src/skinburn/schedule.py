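"""Time-ordered surface boundary-condition schedule.

A scenario is a contiguous sequence of phases, each imposing one of three
surface conditions: convective exchange with a fluid (water spray or
pool), a prescribed net heat flux (flame exposure, positive into the
skin), or an adiabatic surface (transport through air, where convective
losses are negligible next to spray cooling and flame heating).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "BoundaryPhase",
    "ExposureSchedule",
    "build_base_schedule",
    "validate_schedule",
]

_KINDS = ("convective", "fixed_flux", "adiabatic")


@dataclass(frozen=True)
class BoundaryPhase:
    """One surface boundary-condition interval.

    ``kind`` selects the condition; the kind-specific parameters must be
    present exactly when required:

    - ``convective``: ``heat_transfer_coefficient`` (W/m^2 K) and
      ``fluid_temperature`` (degC); surface flux is h (T_s - T_fluid) out
      of the skin.
    - ``fixed_flux``: ``net_flux`` (W/m^2, positive into the skin).
    - ``adiabatic``: no parameters.
    """

    kind: str
    start: float
    end: float
    heat_transfer_coefficient: float | None = None
    fluid_temperature: float | None = None
    net_flux: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}; expected one of {_KINDS}")
        if self.end <= self.start:
            raise ValueError(f"phase end ({self.end} s) must exceed start ({self.start} s)")
        if self.kind == "convective":
            if self.heat_transfer_coefficient is None or self.fluid_temperature is None:
                raise ValueError("convective phase needs heat_transfer_coefficient and fluid_temperature")
            if self.heat_transfer_coefficient < 0:
                raise ValueError("heat_transfer_coefficient must be >= 0")
            if self.net_flux is not None:
                raise ValueError("convective phase must not carry net_flux")
        elif self.kind == "fixed_flux":
            if self.net_flux is None:
                raise ValueError("fixed_flux phase needs net_flux")
            if self.heat_transfer_coefficient is not None or self.fluid_temperature is not None:
                raise ValueError("fixed_flux phase must not carry convective parameters")
        else:  # adiabatic
            if any(v is not None for v in (self.heat_transfer_coefficient, self.fluid_temperature, self.net_flux)):
                raise ValueError("adiabatic phase takes no parameters")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ExposureSchedule:
    """Contiguous, ordered surface phases covering [0, t_end]."""

    phases: tuple[BoundaryPhase, ...]
    t_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        violations = validate_schedule(self)
        if violations:
            raise ValueError("invalid schedule: " + "; ".join(violations))

    @property
    def breakpoints(self) -> list[float]:
        """Phase boundary times, starting at 0 and ending at t_end."""
        return [self.phases[0].start] + [p.end for p in self.phases]


def validate_schedule(schedule: "ExposureSchedule") -> list[str]:
    """Check contiguity and coverage; return human-readable violations.

    An empty list means the schedule is valid.  Violations are returned
    rather than raised so configuration checkers can report all problems
    at once.
    """
    violations: list[str] = []
    phases = schedule.phases
    if not phases:
        return ["schedule has no phases"]
    if abs(phases[0].start) > 0:
        violations.append(f"phase 1 starts at {phases[0].start} s, not 0")
    for i, (prev, cur) in enumerate(zip(phases, phases[1:]), start=2):
        if cur.start > prev.end + 1e-12:
            violations.append(f"gap of {cur.start - prev.end:g} s before phase {i}")
        elif cur.start < prev.end - 1e-12:
            violations.append(f"phase {i} overlaps the previous phase by {prev.end - cur.start:g} s")
    if abs(phases[-1].end - schedule.t_end) > 1e-12:
        violations.append(f"last phase ends at {phases[-1].end} s, not t_end = {schedule.t_end} s")
    return violations


def build_base_schedule(
    spray_duration: float,
    spray_h: float,
    spray_temp: float,
    relax1: float,
    flame_segments: Sequence[tuple[float, float]],
    relax2: float,
    pool_h: float,
    pool_temp: float,
    t_end: float,
) -> ExposureSchedule:
    """Assemble the five-phase exposure schedule.

    Phases, in order: convective spray cooling (``spray_duration`` s at
    ``spray_h``, ``spray_temp``), adiabatic relaxation (``relax1`` s), one
    fixed-flux phase per ``(duration, flux)`` flame segment, a second
    adiabatic relaxation (``relax2`` s), then convective pool cooling at
    ``pool_h``, ``pool_temp`` until ``t_end``.  A zero ``spray_duration``,
    ``relax1`` or ``relax2`` drops that phase.

    Raises a ValueError when the phases do not fit within ``t_end``.
    """
    if any(d < 0 for d in (spray_duration, relax1, relax2)):
        raise ValueError("phase durations must be non-negative")
    if any(d <= 0 for d, _ in flame_segments):
        raise ValueError("flame segment durations must be positive")

    phases: list[BoundaryPhase] = []
    t = 0.0
    if spray_duration > 0:
        phases.append(
            BoundaryPhase(
                "convective", t, t + spray_duration,
                heat_transfer_coefficient=spray_h, fluid_temperature=spray_temp,
            )
        )
        t += spray_duration
    if relax1 > 0:
        phases.append(BoundaryPhase("adiabatic", t, t + relax1))
        t += relax1
    for duration, flux in flame_segments:
        phases.append(BoundaryPhase("fixed_flux", t, t + duration, net_flux=flux))
        t += duration
    if relax2 > 0:
        phases.append(BoundaryPhase("adiabatic", t, t + relax2))
        t += relax2
    if t >= t_end:
        raise ValueError(
            f"phases end at {t:g} s leaving no room for pool cooling before t_end = {t_end:g} s"
        )
    phases.append(
        BoundaryPhase(
            "convective", t, t_end,
            heat_transfer_coefficient=pool_h, fluid_temperature=pool_temp,
        )
    )
    return ExposureSchedule(phases=tuple(phases), t_end=t_end)
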