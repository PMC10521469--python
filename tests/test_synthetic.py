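import numpy as np
import pandas as pd
import pytest

import accelbalance as ab
from accelbalance import pipeline as pl
from accelbalance import synthetic as syn


@pytest.fixture(scope="module")
def two_day_schedule():
    return syn.gen_schedule(2, seed=3)


@pytest.fixture(scope="module")
def two_day_features(two_day_schedule):
    trace = syn.render_trace(two_day_schedule, sample_rate=20, seed=3)
    return pl.extract_features(trace)


class TestGenSchedule:
    def test_deterministic_given_seed(self):
        a = syn.gen_schedule(3, seed=9)
        b = syn.gen_schedule(3, seed=9)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, syn.gen_schedule(3, seed=10).states)

    def test_zero_nonwear_profile(self):
        profile = syn.ScheduleProfile(nonwear_prob_per_day=0.0)
        sched = syn.gen_schedule(5, profile=profile, seed=1)
        assert (sched.wear_states() != "non_wear").all()

    def test_daily_sleep_within_envelope(self):
        sched = syn.gen_schedule(14, seed=2)
        mask = sched.wear_states()
        daily_sleep = (
            (mask == "sleep").groupby(mask.index.normalize()).sum() / 60.0
        )
        assert ((daily_sleep - 8.6).abs() <= 1.0).all()

    def test_states_tile_whole_days(self):
        sched = syn.gen_schedule(2, seed=0)
        assert len(sched.states) == 2 * 1440
        assert set(np.unique(sched.states)) <= set(syn.SIM_STATES)

    def test_infeasible_proportions_rejected(self):
        profile = syn.ScheduleProfile(walk_bouts=40, walk_bout_min=60)
        with pytest.raises(ValueError, match="1440"):
            syn.gen_schedule(1, profile=profile, seed=0)


class TestRenderTrace:
    def test_all_sedentary_keeps_hildebrand_at_floor(self):
        sched = syn.ActivitySchedule(
            pd.Timestamp("2024-01-01"),
            np.full(30, "sedentary", dtype=object),
            syn.DEFAULT_STATE_PARAMS,
        )
        trace = syn.render_trace(sched, sample_rate=20, seed=0)
        enmo_1s, _, _ = pl.extract_features(trace)
        assert ab.hildebrand_linear(enmo_1s.values) == pytest.approx(
            np.full(len(enmo_1s), 3.0)
        )

    def test_walk_seconds_select_cwr_branch(self, two_day_schedule, two_day_features):
        enmo_1s, cv_1s, _ = two_day_features
        sec_state = np.repeat(two_day_schedule.states, 60)
        walk = sec_state == "walk"
        assert walk.sum() > 0
        cwr = (enmo_1s.values > 45.6) & (cv_1s.values <= 19.4)
        assert cwr[walk].mean() > 0.95

    def test_intermittent_seconds_have_high_cv(self, two_day_schedule, two_day_features):
        enmo_1s, cv_1s, _ = two_day_features
        sec_state = np.repeat(two_day_schedule.states, 60)
        ia = sec_state == "intermittent"
        assert (cv_1s.values[ia] > 19.4).mean() > 0.9

    def test_state_enmo_calibration(self, two_day_schedule, two_day_features):
        enmo_1s, _, _ = two_day_features
        sec_state = np.repeat(two_day_schedule.states, 60)
        for state, target in (("walk", 200.0), ("run", 700.0)):
            got = enmo_1s.values[sec_state == state].mean()
            assert got == pytest.approx(target, rel=0.05)
        assert enmo_1s.values[sec_state == "sedentary"].mean() < 44.8
        if (sec_state == "non_wear").any():
            assert enmo_1s.values[sec_state == "non_wear"].max() == 0.0

    def test_deterministic_and_chunk_consistent(self, two_day_schedule):
        t1 = syn.render_trace(two_day_schedule, 20, seed=3, minute_range=(0, 10))
        t2 = syn.render_trace(two_day_schedule, 20, seed=3, minute_range=(0, 10))
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.z, t2.z)

    def test_nonwear_blocks_recovered_by_detector(self):
        profile = syn.ScheduleProfile(nonwear_prob_per_day=1.0)
        sched = syn.gen_schedule(3, profile=profile, seed=5)
        truth = sched.states == "non_wear"
        assert truth.sum() >= 90
        enmo_min = syn.simulate_minute_enmo(sched, sample_rate=20, seed=5)
        detected = ab.choi_nonwear(enmo_min)
        assert (detected == truth).mean() >= 0.99


class TestInvertDeltaES:
    def test_zero_target(self):
        assert syn.invert_delta_es(0.0, 14, 0.3) == (0.0, 0.0)

    def test_recovers_dxa_example_split(self):
        # energy split chosen so that ΔFFM comes out at 0.2625 kg
        target = (1020 * 0.2625 + 9500 * 0.214) / 14
        frac = 1020 * 0.2625 / (target * 14)
        d_ffm, d_fm = syn.invert_delta_es(target, 14, frac)
        assert d_ffm == pytest.approx(0.2625, abs=1e-9)
        assert d_fm == pytest.approx(0.214, abs=1e-3)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            syn.invert_delta_es(100.0, 14, 1.5)


class TestValidityCohort:
    def test_degenerate_cohort_is_exact_offset(self):
        df = syn.gen_validity_cohort(5, 2, bias_mean=100.0, sd_between=0.0,
                                     sd_resid=0.0, seed=0)
        assert (df["predicted_ei"] - df["criterion_ei"]).to_numpy() == pytest.approx(
            np.full(10, 100.0)
        )

    def test_deterministic_given_seed(self):
        a = syn.gen_validity_cohort(10, 2, seed=4)
        b = syn.gen_validity_cohort(10, 2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_validity_cohort(1, 2, seed=0)
        with pytest.raises(ValueError):
            syn.gen_validity_cohort(5, 2, sd_between=-1.0, seed=0)

    def test_zero_slope_recovered_near_zero(self):
        df = syn.gen_validity_cohort(200, 2, bias_mean=150, sd_between=300,
                                     sd_resid=200, slope=0.0, seed=6)
        err = ab.occasion_errors(df["predicted_ei"].to_numpy(),
                                 df["criterion_ei"].to_numpy(),
                                 df["participant"].to_numpy(), method="m")
        s = ab.bland_altman_rm(err)
        assert abs(s.ba_slope) < 0.06


class TestTruthConservation:
    def test_truth_substituted_pipeline_reproduces_true_ei(self):
        sched = syn.gen_schedule(4, seed=7)
        p = ab.Participant("P0", "female", 30, 73.7, 171.8)
        bmr = ab.schofield_bmr(p)
        truth = syn.summarize_truth(sched, p, bmr, target_delta_es=-117.0)

        kcal = syn.true_minute_kcal(sched, p)
        minute_ee = ab.MinuteEE(kcal.to_frame("truth"))
        daily = ab.impute_and_total(minute_ee, sched.wear_states(), bmr)
        mean_ee = ab.period_mean_ee(daily, ("truth",))["truth"]
        est = ab.estimate_ei(mean_ee, ab.delta_es(truth.body_comp))
        assert est.ei == pytest.approx(truth.ei, rel=1e-12)

    def test_truth_identity_holds(self):
        sched = syn.gen_schedule(2, seed=8)
        p = ab.Participant("P1", "male", 40, 80.7, 176.7)
        truth = syn.summarize_truth(sched, p, ab.schofield_bmr(p))
        assert truth.ei == pytest.approx(truth.mean_ee + truth.delta_es, rel=1e-12)

    def test_period_ee_tracks_truth_across_participants(self):
        """Hibbing-left period EE should rank simulated participants like
        their true EE (a sanity, not accuracy, check)."""
        means_model, means_truth = [], []
        for seed in range(4):
            profile = syn.ScheduleProfile(
                walk_bouts=seed, run_bouts=seed % 2, intermittent_bouts=1
            )
            sched = syn.gen_schedule(1, profile=profile, seed=20 + seed)
            p = ab.Participant(f"S{seed}", "female", 30, 70.0, 170.0)
            bmr = ab.schofield_bmr(p)
            trace = syn.render_trace(sched, sample_rate=20, seed=20 + seed)
            enmo_1s, cv_1s, feats = pl.extract_features(trace)
            minute_ee = ab.predict_minute_ee(enmo_1s, cv_1s, feats, p.weight,
                                             ("hibbing_left",))
            daily = ab.impute_and_total(minute_ee, sched.wear_states(), bmr)
            means_model.append(daily["hibbing_left"].mean())
            means_truth.append(syn.summarize_truth(sched, p, bmr).daily_ee.mean())
        r = np.corrcoef(means_model, means_truth)[0, 1]
        assert r > 0.5
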