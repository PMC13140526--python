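"""Muscle oxidative capacity from NIRS tissue-saturation traces.

After a bout of muscle work, repeated brief arterial occlusions each reveal
the instantaneous muscle O2 consumption as the down-slope of the tissue
saturation index (TSI).  Plotting the magnitude of those slopes against time
since the end of exercise traces the recovery of muscle VO2, which follows a
monoexponential with rate constant k (per minute) — a non-invasive proxy for
muscle oxidative capacity.

The trace is first rescaled to its physiological range ("physiological
normalization", PN): 0% at the ischaemic plateau reached during a prolonged
occlusion, 100% at the reperfusion-peak TSI.  Occlusion windows come from
annotations recorded with the protocol; slopes are fitted on a sub-window
that skips the cuff-inflation transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TraceAnnotations",
    "TSITrace",
    "PhysiologicalRange",
    "OcclusionSlope",
    "RecoveryFit",
    "PlateauError",
    "normalize_pn",
    "occlusion_slopes",
    "fit_recovery_k",
]

SAMPLING_HZ = 10.0

#: Sub-window for per-occlusion slope fits: skip the first SKIP_S seconds
#: (cuff-inflation transient), fit the following FIT_S seconds.
SKIP_S = 0.5
FIT_S = 2.0

#: |slope| over the final 10 s of the prolonged occlusion must be below this
#: (%TSI/s) for the ischaemic plateau to count as reached.
PLATEAU_SLOPE_TOL = 0.05


class PlateauError(ValueError):
    """The prolonged occlusion did not reach an ischaemic plateau."""


@dataclass(frozen=True)
class TraceAnnotations:
    """Protocol windows of a TSI trace, in seconds from trace start."""

    prolonged_occlusion: tuple[float, float]
    reperfusion: tuple[float, float]
    exercise_end_s: float
    occlusions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.occlusions:
            if e <= s:
                raise ValueError("occlusion window end must follow its start")
            if s < prev_end:
                raise ValueError("occlusion windows overlap or are unordered")
            prev_end = e


@dataclass
class TSITrace:
    """A 10 Hz TSI signal with protocol annotations."""

    time_s: np.ndarray
    tsi: np.ndarray
    annotations: TraceAnnotations

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.tsi = np.asarray(self.tsi, dtype=float)
        if self.time_s.shape != self.tsi.shape:
            raise ValueError("time and TSI must have the same shape")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, 1.0 / SAMPLING_HZ, atol=1e-6):
            raise ValueError("trace must be uniformly sampled at 10 Hz")

    def window(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time_s >= start - 1e-9) & (self.time_s <= end + 1e-9)
        return self.time_s[m], self.tsi[m]


@dataclass(frozen=True)
class PhysiologicalRange:
    tsi_min: float  # ischaemic plateau (deflection point)
    tsi_max: float  # reperfusion peak
    deflection_idx: int = -1

    def __post_init__(self) -> None:
        if self.tsi_max <= self.tsi_min:
            raise ValueError("tsi_max must exceed tsi_min")

    def to_pn(self, value):
        """Map raw TSI to % of the physiological range."""
        return (np.asarray(value) - self.tsi_min) / (self.tsi_max - self.tsi_min) * 100.0


@dataclass(frozen=True)
class OcclusionSlope:
    t_mid: float  # s since end of exercise, midpoint of the fitted sub-window
    slope: float  # TSI units per s (negative while muscle consumes O2)
    r2: float
    mean_tsi_pn: float  # % of physiological range over the fitted sub-window
    flagged: bool  # True when the muscle was not well oxygenated (<=50% PN)


@dataclass(frozen=True)
class RecoveryFit:
    k: float  # min^-1
    amplitude: float  # |slope| units
    asymptote: float  # |slope| units
    ci_k: tuple[float, float]
    rmse: float
    at_bound: bool = False


def normalize_pn(trace: TSITrace) -> tuple[PhysiologicalRange, TSITrace]:
    """Physiological normalization of a TSI trace.

    The minimum over the prolonged occlusion (the deflection point) maps to
    0% PN and the maximum over the reperfusion window to 100% PN.

    Raises
    ------
    PlateauError
        If TSI is still falling over the final 10 s of the prolonged
        occlusion (no ischaemic plateau).
    """
    ann = trace.annotations
    t_occ, y_occ = trace.window(*ann.prolonged_occlusion)
    if t_occ.size < 20:
        raise ValueError("prolonged occlusion window too short")
    t_tail, y_tail = trace.window(ann.prolonged_occlusion[1] - 10.0,
                                  ann.prolonged_occlusion[1])
    tail_slope = np.polyfit(t_tail, y_tail, 1)[0]
    if abs(tail_slope) > PLATEAU_SLOPE_TOL:
        raise PlateauError(
            f"TSI slope {tail_slope:.3f} %/s over the final 10 s of occlusion "
            f"exceeds {PLATEAU_SLOPE_TOL} %/s: plateau not reached"
        )
    i_min = int(np.argmin(y_occ))
    tsi_min = float(y_occ[i_min])
    _, y_rep = trace.window(*ann.reperfusion)
    if y_rep.size == 0:
        raise ValueError("empty reperfusion window")
    tsi_max = float(np.max(y_rep))
    pn = PhysiologicalRange(tsi_min=tsi_min, tsi_max=tsi_max, deflection_idx=i_min)
    scaled = TSITrace(
        time_s=trace.time_s.copy(),
        tsi=pn.to_pn(trace.tsi),
        annotations=ann,
    )
    return pn, scaled


def occlusion_slopes(
    trace: TSITrace,
    pn: PhysiologicalRange | None = None,
    skip_s: float = SKIP_S,
    fit_s: float = FIT_S,
) -> list[OcclusionSlope]:
    """Least-squares TSI down-slope for every annotated occlusion.

    Each slope is fitted over [start + skip_s, start + skip_s + fit_s];
    ``t_mid`` is referenced to the end of exercise.  When ``pn`` is given
    the trace is taken as raw TSI: slopes are fitted on the PN-normalized
    signal (%PN per s), the mean oxygenation over the fit window is
    expressed in % PN, and windows at <=50% PN are flagged as violating
    the well-oxygenated protocol requirement.  With ``pn=None`` slopes are
    fitted in the trace's own units and nothing is flagged.
    """
    ann = trace.annotations
    if len(ann.occlusions) < 4:
        raise ValueError("need at least 4 occlusion windows")
    out: list[OcclusionSlope] = []
    for start, end in ann.occlusions:
        if end - start < skip_s + fit_s:
            raise ValueError(
                f"occlusion [{start}, {end}] shorter than the "
                f"{skip_s + fit_s} s fit sub-window"
            )
        t, y = trace.window(start + skip_s, start + skip_s + fit_s)
        if pn is not None:
            y = pn.to_pn(y)
        res = stats.linregress(t, y)
        mean_pn = float(np.mean(y))
        out.append(
            OcclusionSlope(
                t_mid=float(t.mean() - ann.exercise_end_s),
                slope=float(res.slope),
                r2=float(res.rvalue**2),
                mean_tsi_pn=mean_pn,
                flagged=(pn is not None and mean_pn <= 50.0),
            )
        )
    return out


def _recovery_model(t_min, asymptote, amplitude, k):
    return asymptote + amplitude * np.exp(-k * t_min)


K_BOUNDS = (0.1, 20.0)  # min^-1


def fit_recovery_k(
    slopes: list[OcclusionSlope],
    use_flagged: bool = False,
) -> RecoveryFit:
    """Fit |slope|(t) = asymptote + amplitude * exp(-k t), k per minute.

    Nonlinear least squares with multi-start initialization (a log-linear
    seed plus fixed fallbacks) and k bounded to [0.1, 20] min^-1; the
    confidence interval comes from the asymptotic covariance.  Slopes
    flagged for poor oxygenation are excluded unless ``use_flagged``.
    """
    pts = [s for s in slopes if use_flagged or not s.flagged]
    if len(pts) < 4:
        raise ValueError("need at least 4 accepted slopes")
    t_min = np.array([s.t_mid for s in pts]) / 60.0
    y = np.abs(np.array([s.slope for s in pts]))
    if t_min.max() - t_min.min() <= 0:
        raise ValueError("slopes must span a nonzero time range")

    # log-linear seed for k from the excess over the smallest |slope|
    excess = y - y.min() + 1e-9
    k_seed = -np.polyfit(t_min, np.log(excess), 1)[0]
    starts = {float(np.clip(k_seed, *K_BOUNDS)), 0.5, 2.0, 5.0}

    best = None
    for k0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _recovery_model,
                t_min,
                y,
                p0=[max(y.min(), 1e-6), max(y.max() - y.min(), 1e-6), k0],
                bounds=([0.0, 0.0, K_BOUNDS[0]], [np.inf, np.inf, K_BOUNDS[1]]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = y - _recovery_model(t_min, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise RuntimeError("recovery fit did not converge from any start")
    popt, pcov, sse = best
    asymptote, amplitude, k = popt
    dof = max(len(y) - 3, 1)
    rmse = float(np.sqrt(sse / dof))
    k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    tcrit = stats.t.ppf(0.975, dof)
    at_bound = bool(
        np.isclose(k, K_BOUNDS[0], atol=1e-6) or np.isclose(k, K_BOUNDS[1], atol=1e-6)
    )
    return RecoveryFit(
        k=float(k),
        amplitude=float(amplitude),
        asymptote=float(asymptote),
        ci_k=(float(k - tcrit * k_se), float(k + tcrit * k_se)),
        rmse=rmse,
        at_bound=at_bound,
    )
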