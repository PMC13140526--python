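"""TSI normalization, occlusion down-slopes and the recovery-constant fit."""

import math
from dataclasses import replace

import numpy as np
import pytest

from colhtl.cohort import OcclusionProtocol, simulate_tsi_trace
from colhtl.nirs import (
    OcclusionSlope,
    PhysiologicalRange,
    PlateauError,
    TraceAnnotations,
    TSITrace,
    fit_recovery_k,
    normalize_pn,
    occlusion_slopes,
)


def make_slopes(k, t_mid_s, asymptote=0.08, amplitude=1.0):
    return [
        OcclusionSlope(
            t_mid=t,
            slope=-(asymptote + amplitude * math.exp(-k * t / 60.0)),
            r2=1.0,
            mean_tsi_pn=70.0,
            flagged=False,
        )
        for t in t_mid_s
    ]


class TestPhysiologicalRange:
    def test_midpoint_maps_to_50(self):
        pn = PhysiologicalRange(tsi_min=40.0, tsi_max=70.0)
        assert pn.to_pn(55.0) == pytest.approx(50.0)

    def test_max_maps_to_100(self):
        pn = PhysiologicalRange(tsi_min=40.0, tsi_max=70.0)
        assert pn.to_pn(70.0) == pytest.approx(100.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            PhysiologicalRange(tsi_min=50.0, tsi_max=50.0)


class TestNormalizePN:
    def test_synthetic_trace_deflection_and_range(self, swimmer):
        trace = simulate_tsi_trace(swimmer)
        pn, scaled = normalize_pn(trace)
        assert pn.tsi_min == pytest.approx(40.0, abs=0.1)
        assert pn.tsi_max == pytest.approx(80.0, abs=0.1)
        # deflection (minimum) sits at the end of the prolonged occlusion
        t_occ, y_occ = trace.window(*trace.annotations.prolonged_occlusion)
        t_true_min = t_occ[np.argmin(y_occ)]
        assert abs(pn.deflection_idx - np.argmin(y_occ)) <= 2
        assert scaled.tsi.min() >= -1.0

    def test_plateau_not_reached_raises(self, swimmer):
        proto = OcclusionProtocol(prolonged_s=20.0)  # far too short to plateau
        trace = simulate_tsi_trace(swimmer, protocol=proto)
        with pytest.raises(PlateauError):
            normalize_pn(trace)


class TestOcclusionSlopes:
    def linear_trace(self, slope):
        ann = TraceAnnotations(
            prolonged_occlusion=(0.0, 30.0),
            reperfusion=(30.0, 40.0),
            exercise_end_s=50.0,
            occlusions=tuple((50.0 + 10.0 * i, 56.0 + 10.0 * i) for i in range(4)),
        )
        t = np.round(np.arange(0.0, 100.0, 0.1), 6)
        tsi = np.full_like(t, 70.0)
        for s, e in ann.occlusions:
            m = (t >= s) & (t < e)
            tsi[m] = 70.0 + slope * (t[m] - s)
        return TSITrace(time_s=t, tsi=tsi, annotations=ann)

    def test_exact_linear_slope(self):
        slopes = occlusion_slopes(self.linear_trace(-1.2))
        assert all(s.slope == pytest.approx(-1.2, abs=1e-9) for s in slopes)

    def test_pure_noise_slope_near_zero(self, rng):
        trace = self.linear_trace(0.0)
        trace.tsi = trace.tsi + rng.normal(0.0, 0.5, size=trace.tsi.shape)
        slopes = occlusion_slopes(trace)
        assert all(abs(s.slope) < 0.5 for s in slopes)

    def test_poor_oxygenation_flagged(self):
        trace = self.linear_trace(-1.2)
        pn = PhysiologicalRange(tsi_min=60.0, tsi_max=90.0)  # 70 raw -> ~33% PN
        slopes = occlusion_slopes(trace, pn)
        assert all(s.flagged for s in slopes)

    def test_window_too_short_rejected(self):
        trace = self.linear_trace(-1.0)
        with pytest.raises(ValueError, match="sub-window"):
            occlusion_slopes(trace, skip_s=0.5, fit_s=10.0)

    def test_generator_round_trip(self, swimmer):
        trace = simulate_tsi_trace(swimmer)
        slopes = occlusion_slopes(trace)
        t0 = trace.annotations.exercise_end_s
        for (s, _), sl in zip(trace.annotations.occlusions, slopes):
            t_mid_min = (s + 1.5 - t0) / 60.0
            expected = -(0.08 + 1.0 * math.exp(-swimmer.true_k * t_mid_min))
            assert sl.slope == pytest.approx(expected, abs=1e-9)


class TestRecoveryFit:
    def test_exact_recovery(self):
        fit = fit_recovery_k(make_slopes(3.0, [2, 10, 20, 35, 60, 100, 140]))
        assert fit.k == pytest.approx(3.0, abs=1e-3)
        assert fit.rmse < 1e-8
        assert not fit.at_bound

    def test_matches_closed_form_on_equispaced_points(self):
        # for equally spaced t the rate constant has a closed form:
        # k = ln((y0-y1)/(y1-y2)) / dt
        k_true, dt = 2.4, 20.0
        slopes = make_slopes(k_true, [0.0, 20.0, 40.0, 60.0])
        y = [abs(s.slope) for s in slopes]
        k_closed = math.log((y[0] - y[1]) / (y[1] - y[2])) / (dt / 60.0)
        fit = fit_recovery_k(slopes)
        assert fit.k == pytest.approx(k_closed, rel=1e-6)

    def test_affine_tsi_invariance(self, swimmer):
        trace = simulate_tsi_trace(swimmer)
        warped = TSITrace(
            time_s=trace.time_s.copy(),
            tsi=1.7 * trace.tsi + 12.0,
            annotations=trace.annotations,
        )
        ks = []
        for tr in (trace, warped):
            pn, _ = normalize_pn(tr)
            ks.append(fit_recovery_k(occlusion_slopes(tr, pn)).k)
        assert ks[0] == pytest.approx(ks[1], rel=1e-9)

    def test_leave_one_out_stability(self, rng):
        t_mid = [2, 10, 20, 35, 60, 100, 140, 180]
        slopes = make_slopes(3.0, t_mid)
        noisy = [replace(s, slope=s.slope + rng.normal(0, 0.005)) for s in slopes]
        full = fit_recovery_k(noisy)
        ci_width = full.ci_k[1] - full.ci_k[0]
        for i in range(len(noisy)):
            sub = noisy[:i] + noisy[i + 1:]
            assert abs(fit_recovery_k(sub).k - full.k) < ci_width

    def test_flagged_slopes_excluded(self):
        slopes = make_slopes(3.0, [2, 10, 20, 35, 60, 100])
        flagged = [replace(s, flagged=True) for s in make_slopes(3.0, [1, 5])]
        fit = fit_recovery_k(slopes + flagged)
        assert fit.k == pytest.approx(3.0, abs=1e-3)

    def test_too_few_slopes(self):
        with pytest.raises(ValueError):
            fit_recovery_k(make_slopes(3.0, [2, 10, 20]))
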