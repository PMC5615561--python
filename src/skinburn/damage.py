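"""Henriques Arrhenius damage integral, burn classification and pain metrics.

Thermal injury is quantified by the damage index Omega = ln(C0 / C_tau),
the log-ratio of undamaged cells before and after the exposure.  Its rate
follows first-order Arrhenius kinetics once the tissue exceeds the injury
threshold of 44 degC:

    dOmega/dt = P exp(-dE / (R T))        for T >= 44 degC, else 0

with a piecewise parameter set: P = 2.185e124 1/s, dE = 7.78e5 J/mol for
44 degC <= T <= 50 degC and P = 1.823e51 1/s, dE = 3.27e5 J/mol for
T > 50 degC.  The band switch makes the rate discontinuous at 50 degC;
the lower band owns that point.  Omega thresholds 0.53 / 1.0 / 1e4 at the
basal layer (0.1 mm) separate no burn, first-, second- and third-degree
burns.  The product P exp(-dE/RT) pairs a ~1e124 prefactor with a
~1e-126 exponential, so the rate is evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GAS_CONSTANT",
    "INJURY_THRESHOLD",
    "PAIN_THRESHOLD",
    "ArrheniusBand",
    "DamageResult",
    "henriques_bands",
    "damage_rate",
    "damage_integral",
    "classify",
    "pain_metrics",
]

GAS_CONSTANT = 8.314  # J/mol K
INJURY_THRESHOLD = 44.0  # degC, onset of protein breakdown
PAIN_THRESHOLD = 44.8  # degC at the 0.1 mm receptor depth
CLASSIFICATION_THRESHOLDS = (0.53, 1.0, 1e4)  # first / second / third degree


@dataclass(frozen=True)
class ArrheniusBand:
    """One temperature band of the piecewise Arrhenius damage rate.

    ``temp_low`` and ``temp_high`` are inclusive degC limits; when bands
    share an endpoint the band listed first in a band list owns it.
    """

    temp_low: float
    temp_high: float
    pre_exponential: float  # P, 1/s
    activation_energy: float  # dE, J/mol

    def __post_init__(self) -> None:
        if self.pre_exponential <= 0 or self.activation_energy <= 0:
            raise ValueError("pre_exponential and activation_energy must be positive")
        if not self.temp_low < self.temp_high:
            raise ValueError("temp_low must be below temp_high")

    def rate(self, temperature_c: float) -> float:
        """P exp(-dE/RT) at ``temperature_c``, evaluated in log space."""
        t_kelvin = temperature_c + 273.15
        return math.exp(
            math.log(self.pre_exponential)
            - self.activation_energy / (GAS_CONSTANT * t_kelvin)
        )


def henriques_bands() -> tuple[ArrheniusBand, ArrheniusBand]:
    """The two-band Henriques parameter set for human skin."""
    return (
        ArrheniusBand(44.0, 50.0, 2.185e124, 7.78e5),
        ArrheniusBand(50.0, math.inf, 1.823e51, 3.27e5),
    )


def damage_rate(
    temperature: float,
    bands: Sequence[ArrheniusBand] | None = None,
    threshold: float = INJURY_THRESHOLD,
) -> float:
    """Instantaneous damage rate dOmega/dt (1/s) at ``temperature`` degC.

    Zero below ``threshold``; above it, the first band whose inclusive
    range contains the temperature supplies P and dE.  A supra-threshold
    temperature covered by no band is a configuration error.
    """
    if bands is None:
        bands = henriques_bands()
    if temperature < threshold:
        return 0.0
    for band in bands:
        if band.temp_low <= temperature <= band.temp_high:
            return band.rate(temperature)
    raise ValueError(
        f"temperature {temperature} degC is above the {threshold} degC threshold "
        "but covered by no Arrhenius band"
    )


@dataclass(frozen=True)
class DamageResult:
    """Accumulated damage with classification and pain metrics."""

    omega: float
    omega_series: np.ndarray = field(repr=False)
    classification: str = "none"
    surviving_fraction: float = 1.0
    pain_onset: float | None = None
    pain_duration: float = 0.0


def damage_integral(
    times: np.ndarray,
    temperatures: np.ndarray,
    bands: Sequence[ArrheniusBand] | None = None,
    threshold: float = INJURY_THRESHOLD,
) -> DamageResult:
    """Trapezoidal time integral of the gated Arrhenius rate.

    ``times`` must be strictly increasing and the same length as
    ``temperatures``.  The returned result carries omega and its
    cumulative series; classification and pain metrics are filled in by
    the caller (see :func:`skinburn.cases.run_case`).
    """
    times = np.asarray(times, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if times.shape != temperatures.shape:
        raise ValueError(f"times {times.shape} and temperatures {temperatures.shape} differ in length")
    if times.size < 2:
        raise ValueError("need at least two samples to integrate")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    rates = np.array([damage_rate(t, bands, threshold) for t in temperatures])
    series = np.concatenate([[0.0], cumulative_trapezoid(rates, times)])
    omega = float(series[-1])
    return DamageResult(
        omega=omega,
        omega_series=series,
        surviving_fraction=math.exp(-omega),
    )


def classify(omega: float) -> str:
    """Burn degree for a damage index at the basal layer.

    none below 0.53, first_degree in [0.53, 1.0), second_degree in
    [1.0, 1e4), third_degree at or above 1e4.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    first, second, third = CLASSIFICATION_THRESHOLDS
    if omega < first:
        return "none"
    if omega < second:
        return "first_degree"
    if omega < third:
        return "second_degree"
    return "third_degree"


def pain_metrics(
    times: np.ndarray,
    temperatures: np.ndarray,
    pain_threshold: float = PAIN_THRESHOLD,
) -> tuple[float | None, float]:
    """Pain onset time and total time above the pain threshold.

    Onset is the first threshold crossing, linearly interpolated between
    samples (or the first sample time when the series starts above the
    threshold); duration sums every supra-threshold stretch with
    interpolated entry and exit times.  Returns ``(None, 0.0)`` when the
    threshold is never reached.
    """
    times = np.asarray(times, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    above = temperatures >= pain_threshold
    if not above.any():
        return None, 0.0

    first = int(np.argmax(above))
    if first == 0:
        onset = float(times[0])
    else:
        t0, t1 = times[first - 1], times[first]
        y0, y1 = temperatures[first - 1], temperatures[first]
        onset = float(t0 + (pain_threshold - y0) / (y1 - y0) * (t1 - t0))

    duration = 0.0
    for i in range(len(times) - 1):
        y0, y1 = temperatures[i], temperatures[i + 1]
        dt = times[i + 1] - times[i]
        a0, a1 = y0 >= pain_threshold, y1 >= pain_threshold
        if a0 and a1:
            duration += dt
        elif a0 != a1:
            frac = (pain_threshold - y0) / (y1 - y0)
            duration += dt * ((1.0 - frac) if a1 else frac)
    return onset, float(duration)
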