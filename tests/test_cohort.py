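"""Synthetic-cohort generator: determinism, round trips, noise calibration."""

import math

import numpy as np
import pytest

from colhtl.cohort import (
    CrossoverDesign,
    OcclusionProtocol,
    ParticipantState,
    ResponseModel,
    apply_dropout,
    generate_cohort,
    simulate_lactate_trials,
    simulate_rebreathing_record,
    simulate_tsi_trace,
)
from colhtl.markers import speed_at_lactate
from colhtl.nirs import fit_recovery_k, normalize_pn, occlusion_slopes
from colhtl.rebreathe import HaemConstants, hbmass_from_rebreathing


def inco_gains(cohort):
    return [
        100.0 * (pt.post.true_hbmass / pt.pre.true_hbmass - 1.0)
        for pt in cohort.periods
        if pt.treatment == "INCO"
    ]


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(CrossoverDesign(seed=7), ResponseModel())
        b = generate_cohort(CrossoverDesign(seed=7), ResponseModel())
        assert a.participants == b.participants
        assert a.periods == b.periods

    def test_balanced_crossover(self):
        c = generate_cohort(CrossoverDesign(n_participants=8, seed=3), ResponseModel())
        per_part = {}
        for pt in c.periods:
            per_part.setdefault(pt.participant_id, []).append(pt.treatment)
        assert all(sorted(v) == ["AIR", "INCO"] for v in per_part.values())
        inco_first = sum(1 for v in per_part.values() if v[0] == "INCO")
        assert inco_first == 4

    def test_zero_effect_model(self):
        model = ResponseModel(gain_per_1000kmh=0.0, response_sd=0.0, pv_drift_sd=0.0)
        c = generate_cohort(CrossoverDesign(seed=1), model)
        for pt in c.periods:
            assert pt.post.true_hbmass == pytest.approx(pt.pre.true_hbmass, rel=1e-12)

    def test_noise_free_gain_is_exact(self):
        model = ResponseModel(gain_per_1000kmh=4.0, response_sd=0.0, pv_drift_sd=0.0)
        c = generate_cohort(CrossoverDesign(seed=1), model, dose_kmh=1000.0)
        for pt in c.periods:
            expected = 4.0 if pt.treatment == "INCO" else 0.0
            gain = 100.0 * (pt.post.true_hbmass / pt.pre.true_hbmass - 1.0)
            assert gain == pytest.approx(expected, abs=1e-9)

    def test_mean_gain_matches_model_at_large_n(self):
        model = ResponseModel(gain_per_1000kmh=4.0, response_sd=1.5, pv_drift_sd=0.0)
        c = generate_cohort(
            CrossoverDesign(n_participants=200, seed=7), model, dose_kmh=1000.0
        )
        gains = inco_gains(c)
        se = 1.5 / math.sqrt(len(gains))
        assert abs(np.mean(gains) - 4.0) < 3.0 * se

    def test_dose_scaling_is_linear(self):
        model = ResponseModel(response_sd=0.0, pv_drift_sd=0.0)
        lo = generate_cohort(CrossoverDesign(seed=2), model, dose_kmh=500.0)
        hi = generate_cohort(CrossoverDesign(seed=2), model, dose_kmh=1000.0)
        assert np.mean(inco_gains(hi)) == pytest.approx(
            2.0 * np.mean(inco_gains(lo)), rel=1e-9)

    def test_volume_conservation_at_generation(self):
        c = generate_cohort(CrossoverDesign(seed=5), ResponseModel())
        for pt in c.periods:
            for state in (pt.pre, pt.post):
                v = state.true_volumes()
                assert v.bv == pytest.approx(v.rbcv + v.pv, rel=1e-14)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_cohort(CrossoverDesign(n_participants=1), ResponseModel())
        with pytest.raises(ValueError):
            ResponseModel(response_sd=-1.0)

    def test_participant_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-smoker"):
            ParticipantState("X", "M", 80.0, 960.0, 156.0, 0.46, 3.0,
                             1e-6, 11.0, baseline_cohb=3.0)
        with pytest.raises(ValueError, match="plausible band"):
            ParticipantState("X", "M", 80.0, 2000.0, 156.0, 0.46, 3.0,
                             1e-6, 11.0, baseline_cohb=1.0)


class TestRebreathingSimulation:
    def test_noise_free_round_trip(self, swimmer, rng):
        rec = simulate_rebreathing_record(swimmer, te_pct=0.0, rng=rng)
        assert hbmass_from_rebreathing(rec) == pytest.approx(
            swimmer.true_hbmass, rel=1e-12)

    def test_delta_cohb_matches_forward_mass_balance(self, swimmer, rng):
        consts = HaemConstants()
        rec = simulate_rebreathing_record(
            swimmer, co_dose_ml=100.0, te_pct=0.0, constants=consts,
            unabsorbed_frac=0.02, rng=rng)
        expected = 98.0 * 100.0 / (940.4 * consts.co_binding)
        assert rec.delta_cohb == pytest.approx(expected, rel=1e-12)

    def test_duplicates_reproduce_typical_error(self, swimmer, rng):
        from colhtl.rebreathe import typical_error

        pairs = []
        for _ in range(500):
            pair = [
                hbmass_from_rebreathing(
                    simulate_rebreathing_record(swimmer, te_pct=2.0, rng=rng))
                for _ in range(2)
            ]
            pairs.append(pair)
        _, te = typical_error(pairs)
        target = 0.02 * float(np.mean(pairs))
        assert abs(te - target) / target < 0.15

    def test_excessive_dose_rejected(self, swimmer, rng):
        with pytest.raises(ValueError, match="exceeding"):
            simulate_rebreathing_record(swimmer, co_dose_ml=5000.0, rng=rng)


class TestTSISimulation:
    def fit_k(self, trace):
        pn, _ = normalize_pn(trace)
        return fit_recovery_k(occlusion_slopes(trace, pn)).k

    @pytest.mark.parametrize("true_k", [3.0, 2.9])
    def test_noise_free_k_recovery(self, swimmer, true_k):
        from dataclasses import replace

        state = replace(swimmer, true_k=true_k)
        trace = simulate_tsi_trace(state)
        assert self.fit_k(trace) == pytest.approx(true_k, abs=1e-3)

    def test_replicate_cv_matches_configured(self, swimmer, rng):
        ks = [
            self.fit_k(simulate_tsi_trace(swimmer, k_cv_pct=18.0, rng=rng))
            for _ in range(200)
        ]
        cv = 100.0 * np.std(ks, ddof=1) / np.mean(ks)
        assert 13.0 <= cv <= 23.0

    def test_overlapping_occlusions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            OcclusionProtocol(occlusion_offsets_s=(2.0, 4.0, 20.0, 30.0))

    def test_protocol_needs_four_occlusions(self):
        with pytest.raises(ValueError):
            OcclusionProtocol(occlusion_offsets_s=(2.0, 10.0, 20.0))


class TestLactateSimulation:
    def test_curve_through_threshold(self, swimmer, rng):
        trials = simulate_lactate_trials(swimmer, noise_sd=0.0, rng=rng)
        assert speed_at_lactate(trials, 4.0) == pytest.approx(1.4, abs=1e-9)

    def test_peak_lactate_at_maximal_speed(self, rng):
        c = generate_cohort(CrossoverDesign(seed=11), ResponseModel())
        peaks = []
        for p in c.participants:
            trials = simulate_lactate_trials(p, noise_sd=0.0, rng=rng)
            peaks.append(max(t.la_peak for t in trials))
        assert 8.0 <= np.mean(peaks) <= 16.0

    def test_noise_truncated_at_zero(self, swimmer, rng):
        trials = simulate_lactate_trials(
            swimmer, speeds=[0.5, 0.6, 0.7], noise_sd=5.0, rng=rng)
        assert all(t.la_peak > 0 for t in trials)

    def test_negative_speed_rejected(self, swimmer, rng):
        with pytest.raises(ValueError):
            simulate_lactate_trials(swimmer, speeds=[-1.0, 1.2], rng=rng)


class TestDropout:
    def test_seeded_and_shaped(self):
        m1 = apply_dropout(9, 8, 0.3, np.random.default_rng(4))
        m2 = apply_dropout(9, 8, 0.3, np.random.default_rng(4))
        assert m1.shape == (9, 8)
        assert np.array_equal(m1, m2)

    def test_no_dropout_default(self):
        m = apply_dropout(3, 8, 0.0, np.random.default_rng(0))
        assert m.all()
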