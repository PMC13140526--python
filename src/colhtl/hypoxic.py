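"""Hypoxic-dose accounting in kilometre-hours and CO-altitude equivalence.

The kilometre-hour metric multiplies altitude (km) by exposure time (h), so
2100 m for 504 h gives 1058.4 km·h.  For CO exposure, an equivalent altitude
is derived by matching the VO2max decrement: elevated carboxyhaemoglobin
lowers VO2max roughly in proportion to the COHb excess above baseline, and
terrestrial altitude lowers it by about 7% per 1000 m, so equating the two
maps a COHb excess onto metres above sea level.  Integrating that equivalent
altitude over a COHb time course yields an accumulated dose comparable to
altitude-camp prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AltitudeExposure",
    "EquivalenceParams",
    "km_hours",
    "cohb_to_altitude",
    "accumulate_dose",
]


@dataclass(frozen=True)
class AltitudeExposure:
    altitude_m: float
    hours: float

    def __post_init__(self) -> None:
        if self.altitude_m < 0 or self.hours < 0:
            raise ValueError("altitude and hours must be non-negative")


@dataclass(frozen=True)
class EquivalenceParams:
    """Slopes of the VO2max-decrement equivalence.

    vo2_drop_per_cohb: % VO2max lost per % COHb excess (linear reading of
    exercise CO studies; not uniquely fixed by the literature, so exposed).
    vo2_drop_per_1000m: % VO2max lost per 1000 m of terrestrial altitude.
    """

    vo2_drop_per_cohb: float = 1.0
    vo2_drop_per_1000m: float = 7.0

    def __post_init__(self) -> None:
        if self.vo2_drop_per_cohb <= 0 or self.vo2_drop_per_1000m <= 0:
            raise ValueError("equivalence slopes must be positive")


def km_hours(altitude_m: float, hours: float) -> float:
    """Hypoxic dose in kilometre-hours: altitude_m x 0.001 x hours."""
    if altitude_m < 0 or hours < 0:
        raise ValueError("altitude and hours must be non-negative")
    return altitude_m * 0.001 * hours


def cohb_to_altitude(
    cohb_excess: float, params: EquivalenceParams = EquivalenceParams()
) -> float:
    """Altitude (m) whose VO2max decrement matches a COHb excess (%)."""
    if cohb_excess < 0:
        raise ValueError("cohb_excess must be non-negative")
    return cohb_excess * params.vo2_drop_per_cohb / params.vo2_drop_per_1000m * 1000.0


def accumulate_dose(times_h, cohb_pct, baseline: float,
                    params: EquivalenceParams = EquivalenceParams()) -> float:
    """Accumulated km·h over a COHb time course (trapezoidal rule).

    Only the excess above the individual baseline accrues dose; a
    non-smoker's resting COHb of ~1% maps to zero equivalent altitude.

    Parameters
    ----------
    times_h : array-like
        Strictly increasing sample times, hours.
    cohb_pct : array-like
        COHb (%) at those times.
    baseline : float
        The individual's resting COHb (%).
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(cohb_pct, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and cohb must be 1-D arrays of equal length")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    excess = np.clip(c - baseline, 0.0, None)
    alt_km = excess * params.vo2_drop_per_cohb / params.vo2_drop_per_1000m
    return float(np.trapezoid(alt_km, t))
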