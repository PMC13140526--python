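"""Crossover statistics: change scores, paired tests, ANCOVA, change ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from colhtl.stats import (
    ancova_treatment,
    change_anova,
    change_scores,
    paired_time_test,
    summarize_changes,
    validate_crossover_table,
)


def make_table(pre_inco, post_inco, pre_air, post_air, outcome="hbmass_g"):
    rows = []
    n = len(pre_inco)
    for i in range(n):
        rows.append(dict(participant=f"P{i}", treatment="INCO", period=1,
                         outcome=outcome, pre=pre_inco[i], post=post_inco[i]))
        rows.append(dict(participant=f"P{i}", treatment="AIR", period=2,
                         outcome=outcome, pre=pre_air[i], post=post_air[i]))
    return pd.DataFrame(rows)


class TestChangeScores:
    def test_zero_change(self):
        t = make_table([900.0, 950.0], [900.0, 950.0], [910.0, 940.0],
                       [910.0, 940.0])
        ch = change_scores(t, "hbmass_g")
        assert (ch["change"] == 0).all()
        assert (ch["pct_change"] == 0).all()

    def test_absolute_and_percent(self):
        t = make_table([940.4], [994.0], [990.7], [991.5])
        ch = change_scores(t, "hbmass_g")
        inco = ch[ch["treatment"] == "INCO"].iloc[0]
        assert inco["change"] == pytest.approx(53.6)
        assert inco["pct_change"] == pytest.approx(5.7, abs=0.05)

    def test_zero_pre_rejected(self):
        t = make_table([0.0, 1.0], [1.0, 2.0], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="pre = 0"):
            change_scores(t, "hbmass_g")

    def test_duplicate_rows_rejected(self):
        t = make_table([1.0], [2.0], [1.0], [2.0])
        with pytest.raises(ValueError, match="duplicate"):
            validate_crossover_table(pd.concat([t, t]))

    def test_summary_shape(self):
        t = make_table([900.0, 950.0], [930.0, 990.0], [910.0, 940.0],
                       [905.0, 945.0])
        s = summarize_changes(change_scores(t, "hbmass_g"))
        assert set(s.index) == {"INCO", "AIR"}
        assert (s["n"] == 2).all()


class TestPairedTimeTest:
    def test_all_zero_changes(self):
        assert paired_time_test(np.zeros(5)) == (0.0, 1.0)

    def test_constant_nonzero_degenerate(self):
        t, p = paired_time_test(np.array([1.0, 1.0, 1.0, 1.0]))
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_oracle(self, rng):
        d = rng.normal(0.5, 1.0, size=12)
        t, p = paired_time_test(d)
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_type_i_error_calibrated(self, rng):
        rejections = sum(
            paired_time_test(rng.normal(0.0, 1.0, size=8))[1] < 0.05
            for _ in range(2000)
        )
        lo, hi = sps.binom.interval(0.95, 2000, 0.05)
        assert lo <= rejections <= hi


class TestAncova:
    def test_post_equals_baseline_gives_zero(self, rng):
        pre = rng.normal(950.0, 100.0, size=8)
        t = make_table(pre[:4], pre[:4], pre[4:], pre[4:])
        eff = ancova_treatment(t, "hbmass_g")
        assert eff.effect == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_additive_effect(self, rng):
        pre = rng.normal(950.0, 100.0, size=8)
        t = make_table(pre, pre + 50.0, pre, pre.copy())
        eff = ancova_treatment(t, "hbmass_g")
        assert eff.effect == pytest.approx(50.0, abs=1e-9)
        assert eff.n_inco == eff.n_air == 8

    def test_subject_diff_variant_recovers_effect(self, rng):
        pre = rng.normal(950.0, 100.0, size=8)
        t = make_table(pre, pre + 50.0, pre, pre.copy())
        eff = ancova_treatment(t, "hbmass_g", subject_diff=True)
        assert eff.effect == pytest.approx(50.0, abs=1e-9)

    def test_shift_invariance(self, rng):
        pre = rng.normal(950.0, 100.0, size=8)
        post_i = pre + rng.normal(40.0, 10.0, size=8)
        post_a = pre + rng.normal(0.0, 10.0, size=8)
        t1 = make_table(pre, post_i, pre, post_a)
        t2 = make_table(pre + 500.0, post_i + 500.0, pre + 500.0, post_a + 500.0)
        e1 = ancova_treatment(t1, "hbmass_g")
        e2 = ancova_treatment(t2, "hbmass_g")
        assert e1.effect == pytest.approx(e2.effect, rel=1e-9)

    def test_zero_slope_equals_mean_change_difference(self, rng):
        pre = rng.normal(950.0, 100.0, size=8)
        post_i = pre + rng.normal(40.0, 15.0, size=8)
        post_a = pre + rng.normal(0.0, 15.0, size=8)
        t = make_table(pre, post_i, pre, post_a)
        eff = ancova_treatment(t, "hbmass_g", baseline_covariate=False)
        ch = change_scores(t, "hbmass_g")
        means = ch.groupby("treatment")["change"].mean()
        assert eff.effect == pytest.approx(means["INCO"] - means["AIR"], rel=1e-9)

    def test_collinear_baseline_rejected(self):
        t = make_table([900.0] * 4, [910.0] * 4, [900.0] * 4, [905.0] * 4)
        with pytest.raises(ValueError, match="zero variance"):
            ancova_treatment(t, "hbmass_g")

    def test_single_treatment_rejected(self):
        t = make_table([900.0, 950.0], [910.0, 960.0], [900.0, 950.0],
                       [905.0, 955.0])
        with pytest.raises(ValueError, match="both treatments"):
            ancova_treatment(t[t["treatment"] == "INCO"], "hbmass_g")

    def test_power_at_study_conditions(self, rng):
        """ANCOVA detects a positive Hb_mass effect in most replicates at
        the default dose-response (4%/1000 km·h, ~850 km·h, n=8)."""
        from colhtl.cohort import (
            CrossoverDesign, ResponseModel, generate_cohort,
            simulate_rebreathing_record,
        )
        from colhtl.rebreathe import hbmass_from_rebreathing

        positives = 0
        reps = 500
        for r in range(reps):
            c = generate_cohort(
                CrossoverDesign(seed=r), ResponseModel(), dose_kmh=847.9,
                rng=np.random.default_rng(r),
            )
            rows = []
            for pt in c.periods:
                vals = {}
                for label, state in (("pre", pt.pre), ("post", pt.post)):
                    hb = [
                        hbmass_from_rebreathing(
                            simulate_rebreathing_record(state, te_pct=2.0, rng=rng))
                        for _ in range(2)
                    ]
                    vals[label] = 0.5 * (hb[0] + hb[1])
                rows.append(dict(participant=pt.participant_id,
                                 treatment=pt.treatment, period=pt.period,
                                 outcome="hbmass_g", **vals))
            eff = ancova_treatment(pd.DataFrame(rows), "hbmass_g")
            positives += eff.effect > 0
        assert positives / reps > 0.80


class TestChangeAnova:
    def test_identical_arms(self):
        t = make_table([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                       [1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        f, p = change_anova(t, "hbmass_g")
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_equals_squared_two_sample_t(self, rng):
        pre = rng.normal(950.0, 100.0, size=10)
        t = make_table(pre, pre + rng.normal(40, 20, 10),
                       pre, pre + rng.normal(0, 20, 10))
        f, p = change_anova(t, "hbmass_g")
        ch = change_scores(t, "hbmass_g")
        a = ch[ch["treatment"] == "INCO"]["change"]
        b = ch[ch["treatment"] == "AIR"]["change"]
        tt = sps.ttest_ind(a, b)
        assert f == pytest.approx(tt.statistic**2, rel=1e-9)
        assert p == pytest.approx(tt.pvalue, rel=1e-9)

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        for _ in range(2000):
            pre = rng.normal(950.0, 50.0, size=16)
            t = make_table(pre[:8], pre[:8] + rng.normal(0, 10, 8),
                           pre[8:], pre[8:] + rng.normal(0, 10, 8))
            rejections += change_anova(t, "hbmass_g")[1] < 0.05
        lo, hi = sps.binom.interval(0.95, 2000, 0.05)
        assert lo <= rejections <= hi
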