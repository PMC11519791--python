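"""Generator correctness: waveform construction, restitution dynamics,
movie/ground-truth consistency, AF traces, and dose-response tables."""

import numpy as np
import pytest

import atriamap as am
from atriamap.synthgen import DI_FLOOR

from conftest import FAST_CAT, uniform_tissue


class TestApWaveform:
    @pytest.mark.parametrize("apd90,rise", [(50.0, 10.0), (85.42, 26.21)])
    def test_apd90_exact_by_construction(self, apd90, rise, frame_period):
        w = am.make_ap_waveform(apd90, rise, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        d90 = am.duration_at_level(w.values, None, act.value, 0.9, frame_period)
        assert abs(act.value - w.t_activation) <= 0.5 * frame_period
        assert abs(d90.value - apd90) <= frame_period

    def test_duration_is_amplitude_invariant(self, frame_period):
        w = am.make_ap_waveform(50.0, 10.0, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        d1 = am.duration_at_level(w.values, None, act.value, 0.9, frame_period)
        d3 = am.duration_at_level(3.0 * w.values, None, act.value, 0.9, frame_period)
        assert d1.value == pytest.approx(d3.value, abs=1e-12)

    def test_unique_upstroke_velocity_maximum(self, frame_period):
        w = am.make_ap_waveform(60.0, 12.0, 0.1)
        d = np.diff(w.values)
        top = np.sort(d)[-3:]
        assert top[-1] > top[-3]  # no flat plateau of maxima

    @pytest.mark.parametrize("apd90,rise,fp", [(10.0, 12.0, 1.0), (50.0, 1.5, 1.0)])
    def test_invalid_parameters_raise(self, apd90, rise, fp):
        with pytest.raises(am.InvalidParameterError):
            am.make_ap_waveform(apd90, rise, fp)


class TestCatWaveform:
    @pytest.mark.parametrize("tau,cat90", [(0.08, 250.0), (0.01, 60.0)])
    def test_decay_tau_recovered_by_refit(self, tau, cat90, frame_period):
        w = am.make_cat_waveform(cat90, 10.0, tau, frame_period)
        fit = am.decay_tau(w.values, None, frame_period)
        assert not fit.flagged
        assert fit.value == pytest.approx(tau, rel=0.02)

    def test_cat90_exact_by_construction(self, frame_period):
        w = am.make_cat_waveform(80.0, 10.0, 0.01, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        d90 = am.duration_at_level(w.values, None, act.value, 0.9, frame_period)
        assert abs(d90.value - 80.0) <= frame_period

    def test_unreachable_cat90_raises(self, frame_period):
        # 90% recovery takes rise/2 + tau*ln(10) = 5 + 184 ms at tau = 80 ms
        with pytest.raises(am.InvalidParameterError):
            am.make_cat_waveform(50.0, 10.0, 0.08, frame_period)


class TestIterateRestitution:
    def test_flat_restitution_gives_constant_apd_and_no_alternans(self):
        p = am.RestitutionParams(apd_max=40.0, tau_rest=1e-9)
        seq = am.iterate_restitution(p, 200.0, 20, 25.0)
        assert np.allclose(seq[1:], 40.0)
        assert am.steady_alternans_amplitude(p, 200.0) < 1e-9

    def test_linearized_perturbation_decays_by_slope_factor(self):
        # pick CL so the fixed-point slope is ~0.5, then check geometric decay
        p = am.RestitutionParams(apd_max=100.0, tau_rest=30.0)
        lo, hi = 100.0, 400.0
        for _ in range(60):
            cl = 0.5 * (lo + hi)
            _, slope = am.restitution_fixed_point(p, cl)
            if slope > 0.5:
                lo = cl
            else:
                hi = cl
        apd_star, slope = am.restitution_fixed_point(p, cl)
        assert slope == pytest.approx(0.5, abs=1e-3)
        seq = am.iterate_restitution(p, cl, 12, apd_star + 1.0)
        devs = np.abs(seq - apd_star)
        ratios = devs[1:6] / devs[0:5]
        assert np.allclose(ratios, 0.5, atol=0.05)

    def test_period_two_orbit_matches_brute_force_iteration(self):
        p = am.RestitutionParams(apd_max=120.0, tau_rest=40.0)
        _, slope = am.restitution_fixed_point(p, 80.0)
        assert slope > 1.0
        # independent brute-force oracle: raw 10_000-step iteration
        apd = 90.0
        orbit = []
        for k in range(10_000):
            apd = 120.0 * (1.0 - np.exp(-max(80.0 - apd, DI_FLOOR) / 40.0))
            if k >= 9_900:
                orbit.append(apd)
        oracle_amp = abs(np.mean(orbit[0::2]) - np.mean(orbit[1::2]))
        assert oracle_amp > 1.0
        assert am.steady_alternans_amplitude(p, 80.0) == pytest.approx(oracle_amp, rel=1e-6)

    def test_too_few_beats_raise(self):
        with pytest.raises(am.InvalidParameterError):
            am.iterate_restitution(am.RestitutionParams(), 200.0, 1, 30.0)


class TestSimulateMovie:
    def test_corner_to_corner_activation_delay_matches_geometry(self, frame_period):
        ts = uniform_tissue(16, 16, FAST_CAT, conduction_velocity=0.5,
                            pixel_pitch=0.1, pacing_site=(0, 0))
        pr = am.ProtocolSpec(mode="fixed_rate", s1_cycle_length=200.0, s1_count=3)
        _, _, truth = am.simulate_movie(ts, pr)
        diag_ms = np.hypot(15, 15) * 0.1 / 0.5
        delay = truth.activation_times[1, 15, 15] - truth.activation_times[1, 0, 0]
        assert delay == pytest.approx(diag_ms, abs=frame_period)

    def test_noiseless_duration_maps_equal_truth(self, frame_period):
        ts = uniform_tissue(8, 8, FAST_CAT)
        pr = am.ProtocolSpec(mode="fixed_rate", s1_cycle_length=1000.0 / 6.0, s1_count=4)
        v, _, truth = am.simulate_movie(ts, pr)
        feats = am.measure_beats(v)
        apd90 = am.feature_stack(feats, v.shape, "apd90")
        assert np.nanmax(np.abs(apd90[2] - truth.apd90[2])) <= frame_period

    def test_s2_below_aerp_is_omitted_and_flagged(self):
        ts = uniform_tissue(8, 8, FAST_CAT, aerp_ms=45.0)
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=4,
                             s2_intervals=(40.0, 60.0))
        _, _, truth = am.simulate_movie(ts, pr)
        assert truth.s2_captured == {40.0: False, 60.0: True}
        s2_beats = sorted(truth.s2_interval_of_beat)
        assert np.all(np.isnan(truth.activation_times[s2_beats[0]]))
        assert np.all(np.isfinite(truth.activation_times[s2_beats[1]]))

    def test_s2_cat_amplitude_monotone_in_coupling_interval(self):
        ts = uniform_tissue(8, 8, FAST_CAT, aerp_ms=20.0)
        intervals = (30.0, 60.0, 90.0, 120.0, 150.0)
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=4,
                             s2_intervals=intervals)
        _, _, truth = am.simulate_movie(ts, pr)
        amps = [truth.cat_amplitudes[b, 4, 4]
                for b in sorted(truth.s2_interval_of_beat)]
        order = np.argsort([truth.s2_interval_of_beat[b]
                            for b in sorted(truth.s2_interval_of_beat)])
        sorted_amps = np.asarray(amps)[order]
        assert np.all(np.diff(sorted_amps) >= 0)

    def test_seed_determinism(self):
        ts = uniform_tissue(8, 8, FAST_CAT)
        pr = am.ProtocolSpec(mode="fixed_rate", s1_cycle_length=200.0, s1_count=3)
        v1, c1, _ = am.simulate_movie(ts, pr, am.NoiseSpec(sigma=0.05, seed=7))
        v2, c2, _ = am.simulate_movie(ts, pr, am.NoiseSpec(sigma=0.05, seed=7))
        v3, _, _ = am.simulate_movie(ts, pr, am.NoiseSpec(sigma=0.05, seed=8))
        assert np.array_equal(v1.frames, v2.frames)
        assert np.array_equal(c1.frames, c2.frames)
        assert not np.array_equal(v1.frames, v3.frames)

    def test_infeasible_propagation_raises(self):
        ts = uniform_tissue(16, 16, FAST_CAT, conduction_velocity=0.05)
        pr = am.ProtocolSpec(mode="fixed_rate", s1_cycle_length=25.0, s1_count=3)
        with pytest.raises(am.InvalidParameterError):
            am.simulate_movie(ts, pr)

    def test_regions_must_partition_grid(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        with pytest.raises(am.InvalidParameterError):
            am.TissueSpec(grid_rows=8, grid_cols=8,
                          regions=(am.Region(mask=mask),))


class TestAfTrace:
    def test_no_episodes_gives_constant_cycle_lengths(self):
        times, truth = am.simulate_af_trace(200.0, [], 5000.0, seed=0)
        assert truth == []
        assert np.allclose(np.diff(times), 200.0)

    def test_overlapping_episodes_raise(self):
        with pytest.raises(am.InvalidParameterError):
            am.simulate_af_trace(200.0, [(0, 2000, 80, 15), (1500, 3000, 80, 15)],
                                 5000.0)

    def test_seeded_runs_are_identical(self):
        eps = [(1000.0, 6000.0, 80.0, 20.0)]
        t1, _ = am.simulate_af_trace(200.0, eps, 10_000.0, seed=3)
        t2, _ = am.simulate_af_trace(200.0, eps, 10_000.0, seed=3)
        t3, _ = am.simulate_af_trace(200.0, eps, 10_000.0, seed=4)
        assert np.array_equal(t1, t2)
        assert not np.array_equal(t1, t3)


class TestDoseResponse:
    def test_response_at_ic50_is_half_maximal(self):
        table = am.make_dose_response(10.0, 1.3, [10.0], top=100.0, bottom=0.0)
        assert table.response.iloc[0] == pytest.approx(50.0)

    def test_steep_hill_approaches_step_function(self):
        table = am.make_dose_response(10.0, 200.0, [5.0, 20.0])
        assert table.response.iloc[0] < 1e-6
        assert table.response.iloc[1] > 100.0 - 1e-6

    def test_noiseless_refit_recovers_ic50(self):
        table = am.make_dose_response(8.666, 1.3, [1.0, 3.0, 10.0, 30.0])
        fit = am.fit_hill(table.concentration, table.response, n_boot=0)
        assert fit.ic50 == pytest.approx(8.666, rel=0.01)
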