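"""Haematological passport markers, urine normalization and lactate metrics.

Covers the OFF-score (an erythropoiesis-withdrawal statistic combining
haemoglobin concentration and reticulocyte percentage), specific-gravity
correction of urinary steroid concentrations, and interpolation of the
swimming speed at a fixed blood-lactate concentration from an exponential
speed-lactate curve.

Unit convention: haemoglobin concentration is stored in g/L throughout the
package; :func:`off_score` takes g/dL at its boundary because the score's
x10 factor assumes that unit — the conversion is explicit at the call site,
never implicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BloodPanel",
    "UrineMarker",
    "LactateTrial",
    "off_score",
    "sg_correct",
    "fit_lactate_curve",
    "speed_at_lactate",
    "ExtrapolationWarning",
]

URINE_ANALYTES = ("T", "EpiT", "A", "Etio", "5aAdiol", "5bAdiol")


class ExtrapolationWarning(UserWarning):
    """The requested lactate threshold lies outside the sampled speed range."""


@dataclass
class BloodPanel:
    """One haematology-analyser panel (Sysmex-style)."""

    hb_conc: float  # g/L
    hct: float  # fraction
    ret_pct: float  # %
    ret_count: float | None = None  # 10^6/uL
    irf: float | None = None  # %
    mfr: float | None = None  # %
    hrf: float | None = None  # %
    mcv: float | None = None  # fL
    mch: float | None = None  # pg
    mchc: float | None = None  # g/dL

    def __post_init__(self) -> None:
        if self.ret_pct < 0:
            raise ValueError("reticulocyte percentage must be non-negative")
        if None not in (self.irf, self.mfr, self.hrf):
            if abs(self.irf - (self.mfr + self.hrf)) > 0.2:
                raise ValueError("IRF must equal MFR + HRF within 0.2 points")


@dataclass(frozen=True)
class UrineMarker:
    analyte: str
    conc_measured: float  # ng/mL
    sg: float  # specific gravity, ~1.000-1.040

    def __post_init__(self) -> None:
        if self.analyte not in URINE_ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.conc_measured < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class LactateTrial:
    """One swim trial with its post-exercise blood-lactate samples."""

    distance_m: float
    speed: float  # m/s
    la_samples: list[tuple[float, float]] = field(default_factory=list)  # (min, mM)
    la_peak: float = math.nan  # mM
    hr_max: float | None = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.la_samples:
            peak = max(v for _, v in self.la_samples)
            if math.isnan(self.la_peak):
                self.la_peak = peak
            elif abs(self.la_peak - peak) > 1e-9:
                raise ValueError("la_peak must equal the maximum sample")


def off_score(hb_g_dl: float, ret_pct: float, sqrt_variant: bool = False) -> float:
    """OFF-score from [Hb] (g/dL!) and reticulocyte %.

    Default form: [Hb] x 10 - 60 x RET%.  ``sqrt_variant=True`` uses
    60 x sqrt(RET%), the form standard in athlete-passport practice; the
    two coincide at RET% = 1.
    """
    if hb_g_dl < 0 or ret_pct < 0:
        raise ValueError("inputs must be non-negative")
    ret_term = math.sqrt(ret_pct) if sqrt_variant else ret_pct
    return hb_g_dl * 10.0 - 60.0 * ret_term


def sg_correct(marker: UrineMarker) -> float:
    """Specific-gravity-corrected urine concentration (ng/mL).

    conc x (1.020 - 1) / ((SG + 0.002) - 1); a reference urine of SG 1.018
    is the fixed point.
    """
    denom = (marker.sg + 0.002) - 1.0
    if denom <= 0:
        raise ValueError(f"specific gravity {marker.sg} too low to correct")
    return marker.conc_measured * (1.020 - 1.0) / denom


def fit_lactate_curve(trials: list[LactateTrial]) -> tuple[float, float]:
    """Fit la_peak = a * exp(b * speed) by least squares on log-lactate.

    Returns (a, b).  Requires >= 2 trials at distinct speeds with positive
    peak lactate.
    """
    speeds = np.array([t.speed for t in trials], dtype=float)
    peaks = np.array([t.la_peak for t in trials], dtype=float)
    if len(trials) < 2 or np.unique(speeds).size < 2:
        raise ValueError("need >= 2 trials at distinct speeds")
    if np.any(peaks <= 0) or np.any(np.isnan(peaks)):
        raise ValueError("peak lactate must be positive for the log-linear fit")
    b, log_a = np.polyfit(speeds, np.log(peaks), 1)
    return float(np.exp(log_a)), float(b)


def speed_at_lactate(trials: list[LactateTrial], threshold: float) -> float:
    """Speed (m/s) at a fixed blood-lactate threshold (mM).

    Inverts the exponential speed-lactate curve: v = (ln thr - ln a) / b.
    A non-increasing fitted curve (b <= 0) is diagnosed as an error;
    extrapolating more than 5% beyond the sampled speed range warns.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a, b = fit_lactate_curve(trials)
    if b <= 0:
        raise ValueError(
            "fitted lactate-speed relation is non-increasing (b <= 0); "
            "cannot invert for a threshold speed"
        )
    v = (math.log(threshold) - math.log(a)) / b
    speeds = [t.speed for t in trials]
    lo, hi = min(speeds), max(speeds)
    span = hi - lo
    if v < lo - 0.05 * span or v > hi + 0.05 * span:
        warnings.warn(
            f"threshold speed {v:.3f} m/s extrapolates >5% beyond the "
            f"sampled range [{lo:.3f}, {hi:.3f}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return v
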