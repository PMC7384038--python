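"""Onset detection, phase classification, and the slope-comparison test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import statsmodels.formula.api as smf

from fluctlight import (
    DroughtEffects,
    DroughtNoise,
    DroughtPhaseClassifier,
    OnsetDetector,
    classify_phases,
    detect_onsets,
    npq_par_slope_test,
    simulate_drought_timecourse,
)


def make_slope_records(slope_a, slope_b, n=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    par = rng.uniform(300.0, 1400.0, 2 * n)
    group = np.repeat(["WW", "DS"], n)
    slope = np.where(group == "WW", slope_a, slope_b)
    npq = 0.5 + slope * par + rng.normal(0, noise, 2 * n)
    return pd.DataFrame({"par": par, "npq": npq, "group": group})


class TestSlopeComparison:
    def test_null_gives_flat_difference(self):
        df = make_slope_records(0.001, 0.001, seed=1)
        res = npq_par_slope_test(df)
        assert abs(res.slope_diff_) < 5e-4
        assert res.p_value_ > 0.001  # not spuriously tiny on one null draw

    def test_ci_covers_true_difference(self):
        """Slopes 0.001 vs 0.003: the interaction CI covers the true
        difference in >= 90% of seeds."""
        cover = 0
        n_rep = 100
        for seed in range(n_rep):
            df = make_slope_records(0.001, 0.003, seed=seed)
            res = npq_par_slope_test(df)
            ci = res.model_.conf_int().loc["_x:C(_g)[T.WW]"]
            # WW is the non-reference level here; true WW - DS slope diff
            if ci[0] <= (0.001 - 0.003) <= ci[1]:
                cover += 1
        assert cover >= 90

    def test_interaction_p_equals_nested_f_test(self):
        """The interaction Wald p-value equals the explicit F-test comparing
        common-slope and separate-slope models."""
        df = make_slope_records(0.001, 0.002, seed=3)
        res = npq_par_slope_test(df)
        full = smf.ols("npq ~ par * C(group)", data=df).fit()
        reduced = smf.ols("npq ~ par + C(group)", data=df).fit()
        f_p = full.compare_f_test(reduced)[1]
        assert res.p_value_ == pytest.approx(f_p, rel=1e-8)

    def test_par_range_restriction(self):
        df = make_slope_records(0.001, 0.003, seed=2)
        res = npq_par_slope_test(df, par_range=(300.0, 800.0))
        assert res.x_range_ == (300.0, 800.0)

    def test_degenerate_covariate_rejected(self):
        df = make_slope_records(0.001, 0.001)
        df.loc[df["group"] == "DS", "par"] = 700.0
        with pytest.raises(ValueError, match="degenerate"):
            npq_par_slope_test(df)

    def test_too_few_records_rejected(self):
        df = make_slope_records(0.001, 0.001).iloc[:42]  # 40 WW + 2 DS
        with pytest.raises(ValueError, match=">= 3"):
            npq_par_slope_test(df)


class TestOnsetDetection:
    def test_near_noise_free_onsets_exact(self):
        """In the vanishing-noise limit onsets land exactly on the
        generating days."""
        tiny = DroughtNoise(1e-6, 1e-6, 1e-6, 1e-6, 1e-6)
        tc = simulate_drought_timecourse(onsets=(8, 13, 18), noise=tiny, seed=0)
        ons = detect_onsets(tc)
        assert ons == {"transpiration": 8, "npq": 13, "fl_photodamage": 18}

    def test_default_noise_onsets_within_one_day(self):
        """Default replicate noise, 20 seeds: every onset within +/- 1 day."""
        hits = 0
        for seed in range(20):
            tc = simulate_drought_timecourse(seed=seed)
            ons = detect_onsets(tc)
            ok = all(
                ons[k] is not None and abs(ons[k] - d) <= 1
                for k, d in (("transpiration", 8), ("npq", 13), ("fl_photodamage", 18))
            )
            hits += ok
        assert hits >= 18

    def test_null_timecourse_mostly_silent(self):
        null = DroughtEffects().null()
        false_onsets = 0
        for seed in range(20):
            tc = simulate_drought_timecourse(effects=null, seed=seed)
            ons = detect_onsets(tc)
            false_onsets += any(v is not None for v in ons.values())
        assert false_onsets <= 2

    def test_fvfm_damage_channel_mode(self):
        tc = simulate_drought_timecourse(seed=1)
        det = OnsetDetector(
            parameters=("transpiration", "npq", "damage"), damage_channel="fvfm"
        ).fit(tc)
        assert abs(det.onsets_["fvfm"] - 18) <= 1

    def test_missing_days_rejected(self):
        tc = simulate_drought_timecourse(seed=0)
        holey = tc[tc["day"] != 5]
        with pytest.raises(ValueError, match="contiguous"):
            detect_onsets(holey)

    def test_single_replicate_falls_back_with_warning(self):
        tc = simulate_drought_timecourse(
            n_reps=1, cultivars=("UK",), seed=0
        )
        det = OnsetDetector(
            effect_thresholds={"transpiration": 5.0, "npq": 0.3,
                               "fl_photodamage": 0.15},
        )
        with pytest.warns(UserWarning, match="single replicate"):
            det.fit(tc)
        assert abs(det.onsets_["transpiration"] - 8) <= 1


class TestPhaseClassification:
    def test_reference_phase_day_assignment(self):
        """Onsets (8, 13, 18) over 24 days give Phase I on days 1-7, II on
        8-12, III on 13-17 and IV on 18-24."""
        call = classify_phases((8, 13, 18), n_days=24)
        assert call.phase_days("I") == list(range(1, 8))
        assert call.phase_days("II") == list(range(8, 13))
        assert call.phase_days("III") == list(range(13, 18))
        assert call.phase_days("IV") == list(range(18, 25))

    def test_no_onsets_all_phase_one(self):
        call = classify_phases((None, None, None), n_days=10)
        assert (call.phases == "I").all()

    def test_collapsed_onsets(self):
        call = classify_phases((5, 5, 5), n_days=8)
        assert call.phase_days("I") == [1, 2, 3, 4]
        assert call.phase_days("IV") == [5, 6, 7, 8]
        assert call.phase_days("II") == [] and call.phase_days("III") == []

    def test_out_of_order_onsets_named(self):
        with pytest.raises(ValueError, match="npq.*precedes.*transpiration"):
            classify_phases((10, 5, 18), n_days=24)

    @given(
        st.tuples(st.integers(1, 8), st.integers(0, 8), st.integers(0, 8)).map(
            lambda x: (x[0], x[0] + x[1], x[0] + x[1] + x[2])
        )
    )
    def test_phase_sequence_non_decreasing(self, onsets):
        call = classify_phases(onsets, n_days=30)
        order = {"I": 0, "II": 1, "III": 2, "IV": 3}
        codes = call.phases.map(order).to_numpy()
        assert (np.diff(codes) >= 0).all()

    def test_classifier_estimator_roundtrip(self):
        tc = simulate_drought_timecourse(seed=4)
        clf = DroughtPhaseClassifier().fit(tc)
        pred = clf.predict([1, 9, 14, 20])
        assert list(pred) == ["I", "II", "III", "IV"]
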