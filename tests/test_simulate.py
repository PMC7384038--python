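"""Generator correctness: kinetic limits, round-trip identities, determinism."""

import numpy as np
import pandas as pd
import pytest

from fluctlight import (
    LightProtocol,
    QuenchingParams,
    compute_npq,
    compute_phi2,
    dirk_protocol,
    fl_protocol,
    simulate_drought_timecourse,
    simulate_ecs_trace,
    simulate_gas_exchange,
    simulate_pam_trace,
    simulate_spectrum_77k,
)


class TestProtocol:
    def test_default_fl_protocol_segments(self):
        p = fl_protocol()
        assert p.labels == ["VLL", "LL1", "HL", "LL2"]
        assert [s.intensity for s in p.segments[:3]] == [57.0, 166.0, 1466.0]
        assert p.pulse_interval == 30.0 and p.pulse_intensity == 8000.0

    def test_hl_segment_contains_seven_pulses(self):
        p = fl_protocol()
        pulses = p.pulse_times()
        hl = [(t, p.segment_at(t).label) for t in pulses]
        n_hl = sum(1 for _, lab in hl if lab == "HL")
        assert n_hl == 7  # floor(210 / 30)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LightProtocol(segments=(("A", 100, 60), ("A", 200, 60)))

    def test_dirk_protocol_clock_covers_i535_window(self):
        p = dirk_protocol()
        assert p.segment_start("LL2") == 810.0
        assert p.segment_end("LL2") == 1110.0  # window 900-1100 s inside LL2


class TestPAMSimulator:
    def test_no_quenching_gives_zero_npq(self):
        params = QuenchingParams(A_qE=0, A_qZ=0, qI=0, noise_sd=0)
        tr = simulate_pam_trace(params)
        npq = compute_npq(tr.fm_dark, tr.data["fmprime"].to_numpy())
        assert np.allclose(npq, 0.0, atol=1e-12)

    def test_npq_round_trip_identity(self, default_pam_trace):
        """Noise-free NPQ reconstructed from Fm' equals the generating NPQ."""
        tr = default_pam_trace
        npq = compute_npq(tr.fm_dark, tr.data["fmprime"].to_numpy())
        np.testing.assert_allclose(npq, tr.truth["npq_true"], rtol=1e-9, atol=1e-12)

    def test_phi2_round_trip_identity(self, default_pam_trace):
        tr = default_pam_trace
        phi2 = compute_phi2(tr.data["fprime"].to_numpy(), tr.data["fmprime"].to_numpy())
        np.testing.assert_allclose(phi2, tr.truth["phi2_true"], rtol=1e-9, atol=1e-12)

    def test_steady_state_matches_closed_form_target(self):
        """Under long constant light each component converges to A*I/(I+K)."""
        params = QuenchingParams(A_qE=1.5, A_qZ=0.6, light_half_sat=250.0)
        proto = LightProtocol(segments=(("LL", 166.0, 6000.0),))
        tr = simulate_pam_trace(params, proto)
        expect = (1.5 + 0.6) * 166.0 / (166.0 + 250.0)
        assert tr.truth["npq_true"].iloc[-1] == pytest.approx(expect, rel=1e-6)

    def test_qi_step_raises_ll2_steady_state(self):
        """With a qI increment, LL2 steady NPQ exceeds LL1-end NPQ by ~qI."""
        params = QuenchingParams(qI=0.3, noise_sd=0)
        tr = simulate_pam_trace(params, fl_protocol(ll2_duration=3000))
        truth = tr.truth
        ll1_end = truth.loc[truth["segment"] == "LL1", "npq_true"].iloc[-1]
        ll2_end = truth.loc[truth["segment"] == "LL2", "npq_true"].iloc[-1]
        assert ll2_end - ll1_end == pytest.approx(0.3, abs=5e-3)

    def test_pulse_ordering_invariants(self, default_pam_trace):
        d = default_pam_trace.data
        assert (d["fprime"] > 0).all()
        assert (d["fprime"] <= d["fmprime"]).all()
        assert (np.diff(d["t"]) > 0).all()
        assert (default_pam_trace.fm_dark >= d["fmprime"] - 1e-12).all()

    def test_short_protocol_rejected(self):
        proto = LightProtocol(segments=(("X", 100.0, 10.0),), pulse_interval=30.0)
        with pytest.raises(ValueError, match="pulse"):
            simulate_pam_trace(QuenchingParams(), proto)

    def test_seeded_determinism(self):
        a = simulate_pam_trace(QuenchingParams(noise_sd=0.02, seed=11))
        b = simulate_pam_trace(QuenchingParams(noise_sd=0.02, seed=11))
        pd.testing.assert_frame_equal(a.data, b.data)

    @pytest.mark.parametrize("bad", [
        dict(A_qE=-1), dict(tau_qZ_on=0), dict(F0_dark=1.2, Fm_dark=1.0),
        dict(noise_sd=-0.1),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            QuenchingParams(**bad)


class TestECSSimulator:
    def test_pure_dph_partition_boundary(self):
        """f_dpH = 1: the quasi-stable dark level sits a full pmf below baseline."""
        tr = simulate_ecs_trace(f_dpH=1.0, pmf=0.8)
        dark = tr.data[~tr.data["light_state"] & (tr.data["t"] > 0)]
        assert dark["ecs"].iloc[-1] == pytest.approx(-0.8, abs=1e-6)

    def test_light_steady_level_is_dpsi_share(self):
        tr = simulate_ecs_trace(f_dpH=0.6, pmf=1.0)
        lit = tr.data[tr.data["light_state"]]
        assert lit["ecs"].iloc[-1] == pytest.approx(0.4, abs=1e-6)

    def test_undersampled_rate_rejected(self):
        with pytest.raises(ValueError, match="sampl"):
            simulate_ecs_trace(gH_plus=50.0, sampling_rate=100.0)

    def test_seeded_determinism(self):
        a = simulate_ecs_trace(noise_sd=0.01, seed=5)
        b = simulate_ecs_trace(noise_sd=0.01, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestDroughtSimulator:
    def test_ground_truth_phase_structure(self):
        tc = simulate_drought_timecourse(onsets=(8, 13, 18), n_days=24)
        assert tc.attrs["truth"]["transpiration_onset"] == 8
        assert set(tc["day"]) == set(range(0, 25))

    def test_ds_soil_water_declines(self):
        tc = simulate_drought_timecourse(seed=2)
        means = (
            tc[tc["treatment"] == "DS"].groupby("day")["soil_water"].mean()
        )
        # monotone apart from replicate noise
        assert means.iloc[0] > means.iloc[10] > means.iloc[-1]

    def test_null_effects_match_ww(self):
        from fluctlight import DroughtEffects

        tc = simulate_drought_timecourse(effects=DroughtEffects().null(), seed=3)
        ds = tc[tc["treatment"] == "DS"].groupby("day")["transpiration"].mean()
        ww = tc[tc["treatment"] == "WW"].groupby("day")["transpiration"].mean()
        assert np.abs(ds - ww).max() < 3.0  # noise only, no systematic gap
        assert tc.attrs["truth"]["transpiration_onset"] is None

    def test_bad_onset_order_rejected(self):
        with pytest.raises(ValueError, match="onsets"):
            simulate_drought_timecourse(onsets=(13, 8, 18))

    def test_seeded_determinism(self):
        a = simulate_drought_timecourse(seed=9)
        b = simulate_drought_timecourse(seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestOtherGenerators:
    def test_gas_exchange_truth_and_shape(self):
        gx = simulate_gas_exchange(seed=0)
        assert set(gx["condition"]) == {"WW", "DS"}
        assert gx.attrs["truth"]["slopes"]["WW"] == 0.10
        for _, grp in gx.groupby("condition"):
            assert grp["par"].is_monotonic_increasing

    def test_spectrum_peaks_at_nominal_positions(self):
        sp = simulate_spectrum_77k(f685_height=2.0, f741_height=1.0)
        wl = sp["wavelength"].to_numpy()
        peak = wl[np.argmax(sp["intensity"].to_numpy())]
        assert abs(peak - 685.0) < 1.0
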