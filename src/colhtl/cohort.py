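"""Synthetic crossover cohort with known ground truth.

Generates an 8-swimmer (4F/4M by default) two-period crossover in which one
period adds chronic low-dose CO inhalation (INCO) on top of sea-level
training and the other is a sea-level control (AIR), separated by a long
washout that resets each subject's physiology to baseline.  Every raw
measurement stream the analysis consumes — CO-rebreathing records, 10 Hz
tissue-saturation traces, lactate-speed trials — is simulated forward from a
subject's true state, so each downstream estimator can be validated as a
round trip and every noise knob can be turned off.

The treatment response is linear in the accumulated hypoxic dose by default
(4% Hb_mass per 1000 km·h), which keeps the ground-truth gain analytic; an
exponential dose-response can be swapped in via ``ResponseModel.form``.

All randomness flows through one numpy Generator passed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .nirs import SAMPLING_HZ, TraceAnnotations, TSITrace
from .rebreathe import HaemConstants, RebreathingRecord, derive_volumes

__all__ = [
    "ParticipantState",
    "CrossoverDesign",
    "ResponseModel",
    "PeriodTruth",
    "Cohort",
    "OcclusionProtocol",
    "generate_cohort",
    "simulate_rebreathing_record",
    "simulate_tsi_trace",
    "simulate_lactate_trials",
    "apply_dropout",
    "default_rebreathing_dose_ml",
]

TREATMENTS = ("INCO", "AIR")

#: Plausibility band for relative haemoglobin mass, g/kg.
REL_HBMASS_BAND = (9.0, 16.0)


@dataclass(frozen=True)
class ParticipantState:
    """A subject's true physiology — the simulation's ground truth.

    The relative-Hb_mass plausibility band screens baseline states built
    from raw inputs; post-treatment states derived by the generator from an
    already-validated baseline set ``check_band=False``, since a response
    draw may legitimately carry a boundary subject just past the screen.
    """

    id: str
    sex: str  # "F" or "M"
    body_mass: float  # kg
    true_hbmass: float  # g
    true_hb_conc: float  # g/L venous
    true_hct: float  # fraction
    true_k: float  # min^-1
    lactate_a: float  # mM; la = a * exp(b * v)
    lactate_b: float  # s/m
    baseline_cohb: float  # %
    check_band: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.true_hbmass <= 0:
            raise ValueError("true_hbmass must be positive")
        if not (0.30 <= self.true_hct <= 0.60):
            raise ValueError("true_hct outside [0.30, 0.60]")
        if self.baseline_cohb >= 2.0:
            raise ValueError("baseline COHb must be <2% (non-smoker)")
        rel = self.true_hbmass / self.body_mass
        if self.check_band and not (
            REL_HBMASS_BAND[0] <= rel <= REL_HBMASS_BAND[1]
        ):
            raise ValueError(
                f"relative Hb_mass {rel:.1f} g/kg outside plausible band "
                f"{REL_HBMASS_BAND}"
            )

    @property
    def rel_hbmass(self) -> float:
        return self.true_hbmass / self.body_mass

    def true_volumes(self, constants: HaemConstants = HaemConstants()):
        """Ground-truth intravascular volumes, consistent with the
        rebreathing derivation (PV + RBCV = BV exactly)."""
        return derive_volumes(
            self.true_hbmass, self.true_hb_conc, self.true_hct,
            constants, body_mass=self.body_mass,
        )


@dataclass(frozen=True)
class CrossoverDesign:
    n_participants: int = 8
    block_length_days: int = 28
    short_block_participant: bool = False  # one subject on a 21-day block
    washout_days: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


@dataclass(frozen=True)
class ResponseModel:
    """Erythropoietic dose-response and measurement-noise configuration.

    gain_per_1000kmh : % Hb_mass gained per 1000 km·h of hypoxic dose.
    response_sd : between-subject SD of the percent response.
    pv_drift_sd : SD (mL) of the treatment-independent plasma-volume drift
        over a training block.
    measurement_te_pct : typical error of a single rebreathing Hb_mass
        measurement, % of the true value.
    nirs_cv_pct : CV of the fitted NIRS recovery constant across repeated
        measurements.
    carryover : % Hb_mass still elevated at the start of period 2 after an
        INCO first period (0 = complete washout).
    form : "linear" or "exponential" dose-response shape.
    """

    gain_per_1000kmh: float = 4.0
    response_sd: float = 1.2
    pv_drift_sd: float = 120.0
    measurement_te_pct: float = 2.0
    nirs_cv_pct: float = 18.0
    lactate_noise_mm: float = 0.5
    carryover: float = 0.0
    form: str = "linear"

    def __post_init__(self) -> None:
        for name in ("response_sd", "pv_drift_sd", "measurement_te_pct",
                     "nirs_cv_pct", "lactate_noise_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gain_per_1000kmh < 0:
            raise ValueError("gain must be non-negative")
        if self.form not in ("linear", "exponential"):
            raise ValueError("form must be 'linear' or 'exponential'")

    def mean_gain_pct(self, dose_kmh: float) -> float:
        """Expected % Hb_mass gain at an accumulated dose (km·h)."""
        if self.form == "linear":
            return self.gain_per_1000kmh * dose_kmh / 1000.0
        # Exponential saturation calibrated to the same gain at 1000 km·h.
        return self.gain_per_1000kmh * (1.0 - math.exp(-dose_kmh / 1000.0)) / (
            1.0 - math.exp(-1.0)
        )


@dataclass(frozen=True)
class PeriodTruth:
    """True pre/post physiology for one participant-period."""

    participant_id: str
    period: int  # 1 or 2
    treatment: str  # "INCO" or "AIR"
    dose_kmh: float
    pre: ParticipantState
    post: ParticipantState


@dataclass
class Cohort:
    participants: list[ParticipantState]
    periods: list[PeriodTruth]
    design: CrossoverDesign
    model: ResponseModel
    dose_kmh: float


# Sex-specific sampling distributions (mean, sd) for baseline physiology,
# matched to a well-trained swimming cohort.
_SEX_PARAMS = {
    "F": dict(body_mass=(75.8, 5.6), rel_hbmass=(11.0, 0.8),
              hb_conc=(150.0, 7.0), hct=(0.44, 0.02)),
    "M": dict(body_mass=(85.9, 10.5), rel_hbmass=(12.6, 0.8),
              hb_conc=(162.0, 7.0), hct=(0.47, 0.02)),
}


def _draw_participant(rng: np.random.Generator, idx: int, sex: str) -> ParticipantState:
    p = _SEX_PARAMS[sex]
    body_mass = max(45.0, rng.normal(*p["body_mass"]))
    rel = float(np.clip(rng.normal(*p["rel_hbmass"]),
                        REL_HBMASS_BAND[0] + 0.2, REL_HBMASS_BAND[1] - 0.2))
    hb_conc = float(np.clip(rng.normal(*p["hb_conc"]), 120.0, 190.0))
    hct = float(np.clip(rng.normal(*p["hct"]), 0.35, 0.55))
    k = float(np.clip(rng.normal(3.0, 0.5), 1.5, 5.0))
    # Lactate curve anchored at the 4 mM threshold speed.
    v4 = rng.normal(1.40, 0.05)
    b = float(np.clip(rng.normal(11.0, 1.0), 8.0, 14.0))
    a = 4.0 * math.exp(-b * v4)
    return ParticipantState(
        id=f"P{idx + 1:02d}",
        sex=sex,
        body_mass=float(body_mass),
        true_hbmass=float(rel * body_mass),
        true_hb_conc=hb_conc,
        true_hct=hct,
        true_k=k,
        lactate_a=a,
        lactate_b=b,
        baseline_cohb=float(rng.uniform(0.5, 1.5)),
    )


def _post_state(
    state: ParticipantState,
    hbmass_factor: float,
    pv_drift_ml: float,
    constants: HaemConstants,
) -> ParticipantState:
    """True state at the end of a block: Hb_mass scaled, RBCV with it
    (constant cell haemoglobin), PV drifted, [Hb]/HCT rederived so the
    volume identities stay exact."""
    vols = state.true_volumes(constants)
    hbmass_new = state.true_hbmass * hbmass_factor
    rbcv_new = vols.rbcv * hbmass_factor
    pv_new = max(vols.pv + pv_drift_ml, 0.3 * vols.pv)
    bv_new = rbcv_new + pv_new
    hb_conc_new = 1000.0 * hbmass_new / (bv_new * constants.fcell)
    hct_new = rbcv_new / (bv_new * constants.fcell)
    return replace(
        state,
        true_hbmass=hbmass_new,
        true_hb_conc=hb_conc_new,
        true_hct=float(np.clip(hct_new, 0.30, 0.60)),
        check_band=False,
    )


def generate_cohort(
    design: CrossoverDesign,
    model: ResponseModel,
    dose_kmh: float = 847.9,
    constants: HaemConstants = HaemConstants(),
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Generate participants and true pre/post states for both periods.

    Under INCO the true Hb_mass multiplies by
    ``1 + mean_gain(dose)/100 + eta`` with eta ~ N(0, response_sd/100);
    under AIR by ``1 + eta``.  The washout resets the pre state of period 2
    to baseline (plus an optional carryover after an INCO first period).
    Treatment order is randomized balanced: half the cohort (rounded) takes
    INCO first.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.n_participants
    participants = [
        _draw_participant(rng, i, "F" if i < n // 2 else "M") for i in range(n)
    ]
    # balanced randomized order
    inco_first = np.zeros(n, dtype=bool)
    inco_first[: n // 2] = True
    rng.shuffle(inco_first)

    periods: list[PeriodTruth] = []
    for i, part in enumerate(participants):
        order = ("INCO", "AIR") if inco_first[i] else ("AIR", "INCO")
        prev_treatment = None
        for period, treatment in enumerate(order, start=1):
            pre = part
            if (
                period == 2
                and prev_treatment == "INCO"
                and model.carryover > 0
            ):
                pre = _post_state(part, 1.0 + model.carryover / 100.0, 0.0, constants)
            dose = dose_kmh if treatment == "INCO" else 0.0
            eta = rng.normal(0.0, model.response_sd / 100.0)
            factor = 1.0 + model.mean_gain_pct(dose) / 100.0 + eta
            pv_drift = rng.normal(0.0, model.pv_drift_sd) if model.pv_drift_sd else 0.0
            post = _post_state(pre, factor, pv_drift, constants)
            periods.append(
                PeriodTruth(
                    participant_id=part.id,
                    period=period,
                    treatment=treatment,
                    dose_kmh=dose,
                    pre=pre,
                    post=post,
                )
            )
            prev_treatment = treatment
    return Cohort(participants=participants, periods=periods,
                  design=design, model=model, dose_kmh=dose_kmh)


def default_rebreathing_dose_ml(state: ParticipantState) -> float:
    """Protocol CO bolus for a rebreathing test: 1.0 mL/kg for women,
    1.2 mL/kg for men."""
    return state.body_mass * (1.0 if state.sex == "F" else 1.2)


def simulate_rebreathing_record(
    state: ParticipantState,
    co_dose_ml: float | None = None,
    te_pct: float = 2.0,
    constants: HaemConstants = HaemConstants(),
    unabsorbed_frac: float = 0.02,
    method: str = "6min",
    rng: np.random.Generator | None = None,
) -> RebreathingRecord:
    """Forward-simulate one CO-rebreathing test.

    The observed ΔCOHb is generated by inverting the same mass balance the
    analysis uses, with a multiplicative error on the implied Hb_mass of SD
    ``te_pct`` % — so duplicate records reproduce the configured typical
    error in expectation and the te=0 round trip is exact.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if co_dose_ml is None:
        co_dose_ml = default_rebreathing_dose_ml(state)
    if co_dose_ml <= 0:
        raise ValueError("CO dose must be positive")
    absorbed = co_dose_ml * (1.0 - unabsorbed_frac)
    delta_true = absorbed * 100.0 / (state.true_hbmass * constants.co_binding)
    if delta_true > 100.0 - state.baseline_cohb:
        raise ValueError(
            f"dose {co_dose_ml} mL implies ΔCOHb {delta_true:.0f} points, "
            "exceeding available haemoglobin"
        )
    eps = rng.normal(0.0, te_pct / 100.0) if te_pct > 0 else 0.0
    delta_obs = absorbed * 100.0 / (state.true_hbmass * (1.0 + eps) * constants.co_binding)
    return RebreathingRecord(
        method=method,
        co_administered=co_dose_ml,
        co_unabsorbed=co_dose_ml * unabsorbed_frac,
        cohb_pre=state.baseline_cohb,
        cohb_post=state.baseline_cohb + delta_obs,
        hb_conc=state.true_hb_conc,
        hct=state.true_hct,
    )


@dataclass(frozen=True)
class OcclusionProtocol:
    """Timing of the NIRS occlusion protocol, seconds from trace start.

    The defaults give a 4-min prolonged occlusion to the ischaemic plateau,
    a reperfusion peak, a short arm-extension exercise, then 10 brief
    occlusions densified early in recovery — enough to resolve rate
    constants in the physiological 2-4 min^-1 range.
    """

    rest_s: float = 30.0
    prolonged_s: float = 240.0
    reperfusion_s: float = 30.0
    recovery_s: float = 30.0
    exercise_s: float = 30.0
    occlusion_offsets_s: tuple[float, ...] = (
        2.0, 10.0, 19.0, 29.0, 41.0, 55.0, 72.0, 92.0, 116.0, 144.0,
    )
    occlusion_len_s: float = 6.0

    def __post_init__(self) -> None:
        if len(self.occlusion_offsets_s) < 4:
            raise ValueError("protocol needs >= 4 occlusions")
        gaps = np.diff(self.occlusion_offsets_s)
        if np.any(gaps < self.occlusion_len_s):
            raise ValueError("occlusions overlap in time")

    @property
    def exercise_end_s(self) -> float:
        return (self.rest_s + self.prolonged_s + self.reperfusion_s
                + self.recovery_s + self.exercise_s)

    def annotations(self) -> TraceAnnotations:
        occ_start = self.rest_s
        rep_start = occ_start + self.prolonged_s
        t0 = self.exercise_end_s
        return TraceAnnotations(
            prolonged_occlusion=(occ_start, rep_start),
            reperfusion=(rep_start, rep_start + self.reperfusion_s),
            exercise_end_s=t0,
            occlusions=tuple(
                (t0 + off, t0 + off + self.occlusion_len_s)
                for off in self.occlusion_offsets_s
            ),
        )


# Raw-TSI landmarks of the simulated trace (percent saturation).
_TSI_REST = 70.0
_TSI_PLATEAU = 40.0
_TSI_PEAK = 80.0
_TSI_EXERCISE_END = 64.0
_SLOPE_AMPLITUDE = 1.0  # %TSI/s of muscle VO2 right at exercise end
_SLOPE_REST = 0.08  # %TSI/s resting asymptote


def simulate_tsi_trace(
    state: ParticipantState,
    protocol: OcclusionProtocol = OcclusionProtocol(),
    k_cv_pct: float = 0.0,
    tsi_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TSITrace:
    """Forward-simulate a 10 Hz TSI trace for the occlusion protocol.

    Muscle VO2 recovers as ``asymptote + amplitude * exp(-k t)``; within
    each brief occlusion the TSI falls linearly at the model slope
    evaluated at the midpoint of the analysis fit sub-window, so the
    noise-free round trip through slope extraction and the recovery fit is
    exact.  ``k_cv_pct`` applies measurement-level variability to the
    trace's realized rate constant; ``tsi_noise_sd`` adds white noise to
    the samples (%TSI).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ann = protocol.annotations()
    t0 = ann.exercise_end_s
    total_s = ann.occlusions[-1][1] + 20.0
    t = np.round(np.arange(0.0, total_s, 1.0 / SAMPLING_HZ), 6)
    tsi = np.full_like(t, _TSI_REST)

    k_real = state.true_k
    if k_cv_pct > 0:
        k_real = float(max(0.3, state.true_k * (1.0 + rng.normal(0.0, k_cv_pct / 100.0))))

    # prolonged occlusion: exponential approach to the ischaemic plateau
    s, e = ann.prolonged_occlusion
    m = (t >= s) & (t < e)
    tsi[m] = _TSI_PLATEAU + (_TSI_REST - _TSI_PLATEAU) * np.exp(-(t[m] - s) / 30.0)
    # reperfusion overshoot then settle back to rest
    s, e = ann.reperfusion
    m = (t >= s) & (t < e)
    tsi[m] = _TSI_PEAK - (_TSI_PEAK - _TSI_PLATEAU) * np.exp(-(t[m] - s) / 1.5)
    m = (t >= e) & (t < e + protocol.recovery_s)
    tsi[m] = _TSI_REST + (_TSI_PEAK - _TSI_REST) * np.exp(-(t[m] - e) / 5.0)
    # exercise: linear dip to the end-exercise level
    ex_start = e + protocol.recovery_s
    m = (t >= ex_start) & (t < t0)
    tsi[m] = _TSI_REST + (_TSI_EXERCISE_END - _TSI_REST) * (t[m] - ex_start) / protocol.exercise_s

    def envelope(tt):
        # slow reoxygenation toward rest between occlusions
        return _TSI_REST - (_TSI_REST - _TSI_EXERCISE_END) * np.exp(-(tt - t0) / 40.0)

    m = t >= t0
    tsi[m] = envelope(t[m])

    from .nirs import FIT_S, SKIP_S  # sub-window convention shared with analysis

    for s, e in ann.occlusions:
        t_mid_min = (s + SKIP_S + FIT_S / 2.0 - t0) / 60.0
        slope = _SLOPE_REST + _SLOPE_AMPLITUDE * math.exp(-k_real * t_mid_min)
        m = (t >= s) & (t < e)
        start_level = float(envelope(np.array([s]))[0])
        tsi[m] = start_level - slope * (t[m] - s)
        end_level = start_level - slope * (e - s)
        # quick reactive recovery back to the envelope after cuff release
        m2 = (t >= e) & (t < e + 4.0)
        env2 = envelope(t[m2])
        tsi[m2] = env2 + (end_level - float(envelope(np.array([e]))[0])) * np.exp(
            -(t[m2] - e) / 1.0
        )

    if tsi_noise_sd > 0:
        tsi = tsi + rng.normal(0.0, tsi_noise_sd, size=tsi.shape)
    return TSITrace(time_s=t, tsi=tsi, annotations=ann)


def simulate_lactate_trials(
    state: ParticipantState,
    speeds: list[float] | None = None,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list:
    """Simulate peak blood lactate for a set of swim trials.

    Default speeds follow the testing protocol: two 400 m trials (low /
    moderate intensity) and two 200 m trials (heavy / maximal), placed
    relative to the subject's true 4 mM threshold speed.  Peak lactate is
    a*exp(b*v) plus truncated Gaussian noise.
    """
    from .markers import LactateTrial

    if rng is None:
        rng = np.random.default_rng(0)
    v4 = (math.log(4.0) - math.log(state.lactate_a)) / state.lactate_b
    if speeds is None:
        speeds = [0.90 * v4, 0.97 * v4, 1.03 * v4, 1.07 * v4]
        distances = [400.0, 400.0, 200.0, 200.0]
    else:
        distances = [200.0] * len(speeds)
    if len(speeds) < 2:
        raise ValueError("need >= 2 trial speeds")
    if any(v <= 0 for v in speeds):
        raise ValueError("speeds must be positive")
    trials = []
    for d, v in zip(distances, speeds):
        la = state.lactate_a * math.exp(state.lactate_b * v)
        if noise_sd > 0:
            la = max(0.1, la + rng.normal(0.0, noise_sd))
        # minimal sampling time course: rise to the peak, then decline
        samples = [(1.0, 0.75 * la), (3.0, la), (5.0, 0.9 * la)]
        trials.append(
            LactateTrial(distance_m=d, speed=float(v), la_samples=samples, la_peak=la)
        )
    return trials


def apply_dropout(
    n_outcomes: int,
    n_participants: int,
    p_missing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded missing-data mask (outcomes x participants); True = observed.

    Real cohorts lose subjects per outcome (instrument failures, missed
    visits), so per-outcome n varies; default pipelines use p_missing = 0.
    """
    if not (0.0 <= p_missing < 1.0):
        raise ValueError("p_missing must be in [0, 1)")
    return rng.random((n_outcomes, n_participants)) >= p_missing
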