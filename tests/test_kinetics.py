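"""Trace segmentation, biexponential NPQ-decay fitting, and the FL statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import biexp_grid_oracle
from fluctlight import (
    LightProtocol,
    NPQDecayFitter,
    QuenchingParams,
    analyze_fl_trace,
    fit_npq_decay,
    fl_photodamage,
    qz_metrics,
    segment_end_values,
    segment_trace,
    simulate_pam_trace,
    fl_protocol,
)
from fluctlight.kinetics import MissingSegmentError


def biexp(t, a_f=1.2, tau_f=25.0, a_s=0.8, tau_s=400.0, off=0.2):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + off


class TestSegmentation:
    def test_all_four_segments_present(self, default_pam_trace):
        seg = segment_trace(default_pam_trace)
        assert list(pd.unique(seg["segment"])) == ["VLL", "LL1", "HL", "LL2"]
        assert len(seg) == len(default_pam_trace.data)

    def test_truncated_trace_names_missing_segments(self, default_pam_trace):
        tr = default_pam_trace
        short = tr.data[tr.data["t"] <= 900].copy()  # ends inside LL1
        from fluctlight import PAMTrace

        truncated = PAMTrace(short, tr.protocol, tr.f0_dark, tr.fm_dark)
        with pytest.raises(MissingSegmentError, match="HL"):
            segment_trace(truncated)

    def test_segment_end_value_of_constant_series(self):
        df = pd.DataFrame({"segment": ["A"] * 3 + ["B"] * 3, "npq": [0.5] * 6})
        assert segment_end_values(df) == {"A": 0.5, "B": 0.5}


class TestNPQDecayFitter:
    def test_constant_series_degenerate(self):
        t = np.arange(0, 600, 30.0)
        fit = fit_npq_decay(t, np.full_like(t, 0.5))
        assert fit.degenerate_
        assert fit.a_fast_ == 0.0 and fit.a_slow_ == 0.0
        assert fit.offset_ == pytest.approx(0.5)

    def test_noise_free_recovery_and_oracle_agreement(self):
        """Slow component and offset recovered within 1%; residual matches the
        brute-force grid-search oracle within 1%."""
        t = np.arange(0, 1801, 30.0)
        y = biexp(t)
        fit = fit_npq_decay(t, y)
        assert fit.converged_ and not fit.censored_
        assert fit.a_fast_ == pytest.approx(1.2, rel=0.01)
        assert fit.a_slow_ == pytest.approx(0.8, rel=0.01)
        assert fit.tau_slow_ == pytest.approx(400.0, rel=0.01)
        assert fit.offset_ == pytest.approx(0.2, rel=0.01)
        assert fit.tau_fast_bounds[0] <= fit.tau_fast_ <= fit.tau_fast_bounds[1]
        *_, oracle_norm = biexp_grid_oracle(t, y)
        assert fit.residual_norm_ <= oracle_norm * 1.01 + 1e-12

    def test_noisy_recovery_median_error_below_10pct(self):
        """1% multiplicative noise, 50 seeds: median relative error of the
        slow amplitude and lifetime stays below 10%."""
        t = np.arange(0, 1801, 30.0)
        y0 = biexp(t)
        errs_a, errs_tau = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_npq_decay(t, y0 * (1 + rng.normal(0, 0.01, len(t))))
            errs_a.append(abs(fit.a_slow_ - 0.8) / 0.8)
            errs_tau.append(abs(fit.tau_slow_ - 400.0) / 400.0)
        assert np.median(errs_a) < 0.10
        assert np.median(errs_tau) < 0.10

    def test_recovery_bias_across_lifetime_grid(self):
        """Median bias of the slow component < 5% over a generator grid at
        2% noise (30 seeds per cell)."""
        t = np.arange(0, 2401, 30.0)
        for tau_s in (120.0, 400.0, 1200.0):
            for a_s in (0.4, 0.8):
                rec_a, rec_tau = [], []
                for seed in range(30):
                    rng = np.random.default_rng(seed)
                    y = biexp(t, a_s=a_s, tau_s=tau_s)
                    fit = fit_npq_decay(t, y * (1 + rng.normal(0, 0.02, len(t))))
                    rec_a.append(fit.a_slow_)
                    rec_tau.append(fit.tau_slow_)
                assert abs(np.median(rec_a) - a_s) / a_s < 0.05
                assert abs(np.median(rec_tau) - tau_s) / tau_s < 0.05

    def test_tau_fast_always_reported_with_interval(self):
        t = np.arange(0, 1801, 30.0)
        fit = fit_npq_decay(t, biexp(t))
        assert fit.tau_fast_interval_ == (10.0, 40.0)
        assert "tau_fast_interval" in fit.summary()

    def test_censoring_flag_at_upper_bound(self):
        t = np.arange(0, 901, 30.0)
        y = 0.5 * np.exp(-t / 20000.0) + 0.1  # effectively unresolvable lifetime
        fit = fit_npq_decay(t, y, tau_slow_bounds=(60.0, 3000.0))
        assert fit.censored_

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8"):
            fit_npq_decay(np.arange(0, 150, 30.0), np.ones(5))

    def test_fixed_tau_fast_mode(self):
        t = np.arange(0, 1801, 30.0)
        fit = fit_npq_decay(t, biexp(t), fix_tau_fast=25.0)
        assert fit.tau_fast_ == 25.0
        assert fit.a_slow_ == pytest.approx(0.8, rel=0.01)

    def test_sklearn_params_round_trip(self):
        f = NPQDecayFitter(n_starts=4)
        assert NPQDecayFitter(**f.get_params()).n_starts == 4


class TestFLStatistics:
    def test_photodamage_recovers_generating_qi(self):
        for qi, tol in ((0.1, 0.005), (0.3, 0.015)):
            tr = simulate_pam_trace(QuenchingParams(qI=qi))
            res = analyze_fl_trace(tr)
            assert res.fl_photodamage == pytest.approx(qi, abs=tol)

    def test_photodamage_zero_without_qi(self, default_pam_trace):
        res = analyze_fl_trace(default_pam_trace)
        assert abs(res.fl_photodamage) < 5e-3

    def test_photodamage_shift_invariance(self):
        """Adding a constant to the whole NPQ series leaves the statistic
        unchanged (both the LL1 end value and the fitted offset shift by c)."""
        tr = simulate_pam_trace(QuenchingParams())
        seg = segment_trace(tr)
        proto = tr.protocol
        ll2 = seg[seg["segment"] == "LL2"]
        t_rel = ll2["t"].to_numpy() - proto.segment_start("LL2")

        base_fit = fit_npq_decay(t_rel, ll2["npq"].to_numpy())
        base = fl_photodamage(seg, base_fit)
        shifted = seg.copy()
        shifted["npq"] = shifted["npq"] + 0.7
        shift_fit = fit_npq_decay(
            t_rel, shifted.loc[shifted["segment"] == "LL2", "npq"].to_numpy()
        )
        assert fl_photodamage(shifted, shift_fit) == pytest.approx(base, abs=5e-3)

    def test_last_k_steady_state_option(self, default_pam_trace):
        seg = segment_trace(default_pam_trace)
        proto = default_pam_trace.protocol
        ll2 = seg[seg["segment"] == "LL2"]
        fit = fit_npq_decay(
            ll2["t"].to_numpy() - proto.segment_start("LL2"), ll2["npq"].to_numpy()
        )
        a = fl_photodamage(seg, fit, steady="offset")
        b = fl_photodamage(seg, fit, steady="last-k")
        assert a == pytest.approx(b, abs=0.02)

    def test_qz_amplitude_matches_generator_split(self):
        """A 40% qZ share of HL-induced NPQ is read back as ~40%."""
        tr = simulate_pam_trace(QuenchingParams(A_qE=1.2, A_qZ=0.8))
        res = analyze_fl_trace(tr)
        assert res.qz_amplitude_pct == pytest.approx(40.0, abs=2.0)
        assert res.qz_lifetime == res.fit.tau_slow_  # pass-through

    def test_qz_amplitude_full_share_boundary(self):
        """If the slow amplitude equals the whole HL-induced NPQ the share is 100%."""
        seg = pd.DataFrame(
            {"segment": ["LL1", "HL", "LL2"], "npq": [0.5, 1.5, 0.5], "t": [1, 2, 3]}
        )
        fit = NPQDecayFitter()
        fit._set_degenerate(0.5)
        fit.a_slow_ = 1.0
        pct, _ = qz_metrics(seg, fit)
        assert pct == pytest.approx(100.0)

    def test_nonpositive_hl_induced_npq_flagged(self):
        seg = pd.DataFrame(
            {"segment": ["LL1", "HL", "LL2"], "npq": [1.0, 0.8, 0.5], "t": [1, 2, 3]}
        )
        fit = NPQDecayFitter()
        fit._set_degenerate(0.5)
        with pytest.warns(UserWarning, match="HL-induced"):
            pct, tau = qz_metrics(seg, fit)
        assert np.isnan(pct) and tau > 0
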