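import numpy as np
import pandas as pd
import pytest

from accelbalance import (
    ChoiParams,
    MinuteEE,
    Participant,
    build_minute_mask,
    choi_nonwear,
    impute_and_total,
    period_mean_ee,
    schofield_bmr,
    screen_valid,
)
from accelbalance.wear_screening import KCAL_PER_MJ, fixed_sleep_window
from oracles import choi_oracle

MINUTES_DAY = pd.date_range("2024-01-01", periods=1440, freq="min")


class TestChoiNonwear:
    def test_full_day_of_zeros_is_all_nonwear(self):
        assert choi_nonwear(np.zeros(1440)).all()

    def test_active_day_has_no_nonwear(self):
        assert not choi_nonwear(np.full(1440, 50.0)).any()

    def test_short_spike_tolerated_long_spike_splits(self):
        v = np.full(1440, 10.0)
        v[100:220] = 0.0
        v[160] = 50.0  # 1-min interruption, 60/59-min zero flanks
        out = choi_nonwear(v)
        assert out[100:220].all() and out.sum() == 120

        v2 = np.full(1440, 10.0)
        v2[100:220] = 0.0
        v2[155:160] = 50.0  # 5-min interruption splits the run
        assert not choi_nonwear(v2).any()

    def test_unflanked_spike_not_tolerated(self):
        v = np.full(1440, 10.0)
        v[100:220] = 0.0
        v[110] = 50.0  # only 10 zero minutes on the left
        out = choi_nonwear(v)
        # the 109-min run after the spike still qualifies on its own
        assert out[111:220].all() and not out[100:111].any()

    @pytest.mark.parametrize("seed", range(12))
    def test_random_series_match_rule_checker(self, seed):
        rng = np.random.default_rng(seed)
        pieces = []
        while sum(len(p) for p in pieces) < 420:
            if rng.random() < 0.5:
                pieces.append(np.zeros(rng.integers(5, 120)))
            else:
                pieces.append(rng.uniform(5, 100, rng.integers(1, 5)))
        v = np.concatenate(pieces)
        assert np.array_equal(choi_nonwear(v), choi_oracle(v))

    def test_translation_invariance_and_gap_detection(self):
        v = np.full(300, 10.0)
        v[50:190] = 0.0
        base = choi_nonwear(pd.Series(v, index=MINUTES_DAY[:300]))
        shifted = choi_nonwear(pd.Series(v, index=MINUTES_DAY[:300] + pd.Timedelta("3h")))
        assert np.array_equal(base, shifted)

        gappy = pd.Series(v, index=MINUTES_DAY[:300]).drop(MINUTES_DAY[100])
        with pytest.raises(ValueError, match="gaps"):
            choi_nonwear(gappy)

    def test_custom_zero_threshold(self):
        v = np.full(1440, 0.5)
        assert choi_nonwear(v).all()  # below the 1 milli-g default
        assert not choi_nonwear(v, ChoiParams(zero_threshold=0.2)).any()


class TestMinuteMask:
    def test_empty_sets_are_all_awake(self):
        mask = build_minute_mask(MINUTES_DAY, set(), set())
        assert (mask == "awake_wear").all()

    def test_nonwear_takes_precedence_over_sleep(self):
        flags = np.zeros(1440, dtype=bool)
        flags[10] = True
        mask = build_minute_mask(MINUTES_DAY, flags, flags)
        assert mask.iloc[10] == "non_wear"

    def test_disjoint_sleep_and_nonwear_counts(self):
        sleep = np.zeros(1440, dtype=bool)
        sleep[:480] = True  # 8 h
        nonwear = np.zeros(1440, dtype=bool)
        nonwear[600:660] = True  # 1 h
        mask = build_minute_mask(MINUTES_DAY, nonwear, sleep)
        counts = mask.value_counts()
        assert counts["awake_wear"] == 15 * 60
        assert counts["sleep"] == 480 and counts["non_wear"] == 60
        assert counts.sum() == 1440

    def test_fixed_sleep_window_wraps_midnight(self):
        sleep = fixed_sleep_window(MINUTES_DAY, "23:00", "07:00")
        assert sleep.sum() == 8 * 60


class TestScreenValid:
    def make_mask(self, awake_minutes_per_day):
        parts = []
        for d, n_awake in enumerate(awake_minutes_per_day):
            idx = MINUTES_DAY + pd.Timedelta(days=d)
            state = np.where(np.arange(1440) < n_awake, "awake_wear", "sleep")
            parts.append(pd.Series(state, index=idx))
        return pd.concat(parts)

    def test_600_minute_day_is_valid_599_is_not(self):
        daily, _ = screen_valid(self.make_mask([600, 599]))
        assert daily["valid"].tolist() == [True, False]

    def test_participant_needs_four_valid_days(self):
        _, ok3 = screen_valid(self.make_mask([700] * 3))
        _, ok4 = screen_valid(self.make_mask([700] * 4))
        assert not ok3 and ok4

    def test_state_counts_cover_full_days(self):
        daily, _ = screen_valid(self.make_mask([700, 650]))
        totals = daily[[c for c in daily.columns if c.endswith("_minutes")]].sum(axis=1)
        assert (totals == 1440).all()


class TestSchofield:
    def test_male_25y_matches_hand_table_evaluation(self):
        # 0.063*80 - 0.042*1.80 + 2.953 MJ/day, converted at 239.006 kcal/MJ
        p = Participant("a", "male", 25, 80.0, 180.0)
        expected = (0.063 * 80 - 0.042 * 1.80 + 2.953) * KCAL_PER_MJ
        assert schofield_bmr(p) == pytest.approx(expected)

    def test_sex_specific_coefficients_differ(self):
        m = schofield_bmr(Participant("a", "male", 25, 80.0, 180.0))
        f = schofield_bmr(Participant("b", "female", 25, 80.0, 180.0))
        expected_f = (0.057 * 80 + 1.184 * 1.80 + 0.411) * KCAL_PER_MJ
        assert f == pytest.approx(expected_f)
        assert m != pytest.approx(f)

    @pytest.mark.parametrize("sex", ["female", "male"])
    @pytest.mark.parametrize("age", [2, 5, 12, 25, 45, 70])
    def test_heavier_always_higher_within_band(self, sex, age):
        light = schofield_bmr(Participant("a", sex, age, 60.0, 170.0))
        heavy = schofield_bmr(Participant("a", sex, age, 75.0, 170.0))
        assert heavy > light


class TestImputeAndTotal:
    def make_ee(self, kcal_per_min, minutes=MINUTES_DAY):
        return MinuteEE(pd.DataFrame({"m": np.full(len(minutes), kcal_per_min)},
                                     index=minutes))

    def test_all_sleep_day_totals_to_bmr(self):
        mask = pd.Series("sleep", index=MINUTES_DAY)
        daily = impute_and_total(self.make_ee(2.0), mask, bmr=1618.0,
                                 valid_day_minutes=0)
        assert daily["m"].iloc[0] == pytest.approx(1618.0)

    def test_hand_arithmetic_example(self):
        state = np.where(np.arange(1440) < 600, "awake_wear", "sleep")
        mask = pd.Series(state, index=MINUTES_DAY)
        daily = impute_and_total(self.make_ee(2.0), mask, bmr=1618.0)
        assert daily["m"].iloc[0] == pytest.approx(1200 + 840 * 1618 / 1440, abs=0.01)
        assert daily["awake_wear_minutes"].iloc[0] == 600
        assert daily["imputed_minutes"].iloc[0] == 840

    def test_zero_awake_ee_recovers_bmr(self):
        mask = pd.Series("awake_wear", index=MINUTES_DAY)
        daily = impute_and_total(self.make_ee(0.0), mask, bmr=1500.0)
        assert daily["m"].iloc[0] == pytest.approx(0.0)
        mask_all_imputed = pd.Series("non_wear", index=MINUTES_DAY)
        daily2 = impute_and_total(self.make_ee(0.0), mask_all_imputed, bmr=1500.0,
                                  valid_day_minutes=0)
        assert daily2["m"].iloc[0] == pytest.approx(1500.0)

    def test_invalid_day_excluded(self):
        state = np.where(np.arange(1440) < 599, "awake_wear", "sleep")
        mask = pd.Series(state, index=MINUTES_DAY)
        daily = impute_and_total(self.make_ee(2.0), mask, bmr=1618.0)
        assert daily.empty

    def test_missing_awake_ee_raises(self):
        mask = pd.Series("awake_wear", index=MINUTES_DAY)
        short = self.make_ee(2.0, MINUTES_DAY[:100])
        with pytest.raises(ValueError, match="lack EE"):
            impute_and_total(short, mask, bmr=1618.0)

    def test_total_at_least_imputed_share_of_bmr(self, rng):
        state = rng.choice(["awake_wear", "sleep", "non_wear"], size=1440)
        mask = pd.Series(state, index=MINUTES_DAY)
        ee = MinuteEE(pd.DataFrame({"m": rng.uniform(0, 5, 1440)}, index=MINUTES_DAY))
        daily = impute_and_total(ee, mask, bmr=1600.0, valid_day_minutes=0)
        floor = daily["imputed_minutes"] / 1440 * 1600.0
        assert (daily["m"] + 1e-9 >= floor).all()


class TestPeriodMean:
    def test_examples(self):
        daily = pd.DataFrame({"m": [2000.0, 2200.0]})
        assert period_mean_ee(daily, ("m",))["m"] == pytest.approx(2100.0)
        assert period_mean_ee(daily.iloc[:1], ("m",))["m"] == pytest.approx(2000.0)
        equal = pd.DataFrame({"m": [2400.0] * 14})
        assert period_mean_ee(equal, ("m",))["m"] == pytest.approx(2400.0)

    def test_no_valid_days_raises(self):
        with pytest.raises(ValueError, match="no valid days"):
            period_mean_ee(pd.DataFrame({"m": []}), ("m",))
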