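"""Feature extraction: activation, durations, rise time, decay, transition
points, conduction velocity, heterogeneity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atriamap as am
from atriamap.synthgen import RISE_CALIBRATION

from conftest import FAST_CAT, uniform_tissue


class TestActivationTime:
    def test_linear_ramp_tie_resolves_to_earliest_and_flags(self):
        trace = np.concatenate([np.zeros(5), np.linspace(0, 1, 10), np.ones(5)])
        act = am.activation_time(trace, None, 1.0)
        assert act.flagged
        assert act.value == pytest.approx(5.5, abs=1e-9)

    def test_generator_truth_recovered_within_half_frame(self, frame_period):
        w = am.make_ap_waveform(60.0, 12.0, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        assert abs(act.value - w.t_activation) <= 0.5 * frame_period

    def test_time_shift_equivariance(self, frame_period):
        w = am.make_ap_waveform(60.0, 12.0, frame_period)
        shifted = np.concatenate([np.zeros(7), w.values])
        a0 = am.activation_time(w.values, None, frame_period)
        a7 = am.activation_time(shifted, None, frame_period)
        assert a7.value - a0.value == pytest.approx(7 * frame_period, abs=1e-9)


class TestDurationAtLevel:
    def test_construction_value_recovered(self, frame_period):
        w = am.make_ap_waveform(50.0, 10.0, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        d = am.duration_at_level(w.values, None, act.value, 0.9, frame_period)
        assert d.value == pytest.approx(50.0, abs=frame_period)

    @given(apd90=st.floats(30.0, 110.0), rise=st.floats(5.0, 25.0))
    @settings(max_examples=30, deadline=None)
    def test_level_monotonicity_across_random_waveforms(self, apd90, rise):
        if apd90 <= rise + 5.0:
            return
        fp = 1000.0 / 900.0
        w = am.make_ap_waveform(apd90, rise, fp)
        act = am.activation_time(w.values, None, fp)
        d30 = am.duration_at_level(w.values, None, act.value, 0.3, fp).value
        d80 = am.duration_at_level(w.values, None, act.value, 0.8, fp).value
        d90 = am.duration_at_level(w.values, None, act.value, 0.9, fp).value
        assert d30 <= d80 <= d90

    def test_model_like_beat_has_apd3080_below_one(self, frame_period):
        w = am.make_ap_waveform(70.50, 25.0, frame_period)
        act = am.activation_time(w.values, None, frame_period)
        d30 = am.duration_at_level(w.values, None, act.value, 0.3, frame_period).value
        d80 = am.duration_at_level(w.values, None, act.value, 0.8, frame_period).value
        truth30 = am.ap_duration_truth(70.50, 25.0, 0.3)
        truth80 = am.ap_duration_truth(70.50, 25.0, 0.8)
        assert d30 / d80 < 1.0
        assert d30 / d80 == pytest.approx(truth30 / truth80, rel=0.05)

    def test_cut_off_beat_flags_missing(self, frame_period):
        w = am.make_ap_waveform(50.0, 10.0, frame_period)
        cut = w.values[: int(30 / frame_period)]  # truncate before 90% recovery
        act = am.activation_time(cut, None, frame_period)
        d = am.duration_at_level(cut, None, act.value, 0.9, frame_period)
        assert d.flagged and math.isnan(d.value)


class TestRiseTime:
    def test_linear_upstroke_of_10ms_gives_8ms(self):
        trace = np.concatenate([np.zeros(5), np.linspace(0, 1, 11), np.ones(5)])
        rt = am.rise_time(trace, None, 1.0)
        assert rt.value == pytest.approx(8.0, abs=0.01)

    def test_step_upstroke_is_at_most_one_frame(self):
        trace = np.concatenate([np.zeros(10), np.ones(10)])
        rt = am.rise_time(trace, None, 1.0)
        assert rt.value <= 1.0

    def test_generator_rise_parameter_times_family_calibration(self, frame_period):
        w = am.make_ap_waveform(80.0, 20.0, frame_period)
        rt = am.rise_time(w.values, None, frame_period)
        assert rt.value == pytest.approx(20.0 * RISE_CALIBRATION, abs=frame_period)


class TestDecayTau:
    def test_linear_decay_is_flagged_unreliable(self):
        trace = np.concatenate([np.zeros(3), [1.0], np.linspace(1, 0, 60)])
        fit = am.decay_tau(trace, None, 1.0)
        assert fit.flagged

    def test_pure_exponential_recovered_to_one_percent(self, frame_period):
        for tau in (0.08, 0.01):
            w = am.make_cat_waveform(60.0 if tau == 0.01 else 250.0, 10.0, tau,
                                     frame_period)
            fit = am.decay_tau(w.values, None, frame_period)
            assert fit.value == pytest.approx(tau, rel=0.01)


class TestTransitionPoints:
    def test_generator_truth_within_one_frame(self, frame_period):
        w = am.make_cat_waveform(80.0, 10.0, 0.01, frame_period)
        pts = am.transition_points(w.values, None, frame_period)
        # construction truth: 5% upstroke crossing, peak time, recovery crossings
        assert pts["t0"].value == pytest.approx(
            10.0 / math.pi * math.acos(0.9), abs=frame_period)
        assert pts["t_on"].value == pytest.approx(10.0, abs=frame_period)
        assert pts["t_off"].value == pytest.approx(5.0 + 80.0, abs=frame_period)
        plateau = 80.0 - 5.0 - 10.0 * math.log(10.0)
        t30 = 10.0 + plateau + 10.0 * math.log(1.0 / 0.7)
        assert pts["t30_off"].value == pytest.approx(t30, abs=frame_period)

    def test_all_points_shift_equally(self, frame_period):
        w = am.make_cat_waveform(80.0, 10.0, 0.01, frame_period)
        shifted = np.concatenate([np.zeros(9), w.values])
        p0 = am.transition_points(w.values, None, frame_period)
        p9 = am.transition_points(shifted, None, frame_period)
        for key in ("t0", "t_on", "t30_off", "t_off"):
            assert p9[key].value - p0[key].value == pytest.approx(
                9 * frame_period, abs=0.5 * frame_period)

    def test_monotone_trace_flags_missing_recovery(self):
        trace = np.linspace(0, 1, 50)
        pts = am.transition_points(trace, None, 1.0)
        assert pts["t30_off"].flagged and pts["t_off"].flagged


class TestConductionVelocity:
    def _plane_map(self, speed, rows=12, cols=12, pitch=0.1):
        cc = np.arange(cols) * pitch
        return np.tile(cc / speed, (rows, 1))

    @pytest.mark.parametrize("speed", [0.3, 0.5, 1.0])
    def test_plane_wave_speed_recovered(self, speed):
        res = am.conduction_velocity(self._plane_map(speed), 0.1)
        assert res.mean_speed == pytest.approx(speed, rel=0.05)
        assert res.direction_coherence > 0.99

    def test_doubling_pixel_pitch_doubles_speed(self):
        tmap = self._plane_map(0.5)
        r1 = am.conduction_velocity(tmap, 0.1)
        r2 = am.conduction_velocity(tmap, 0.2)
        assert r2.mean_speed == pytest.approx(2.0 * r1.mean_speed, rel=1e-6)

    def test_point_source_gives_radial_directions_and_speed(self):
        pitch, speed = 0.1, 0.5
        rr, cc = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        tmap = np.hypot(rr - 7, cc - 7) * pitch / speed
        res = am.conduction_velocity(tmap, pitch)
        # away from the source the speed approaches truth; directions radial
        ring = np.isfinite(res.speed) & (np.hypot(rr - 7, cc - 7) >= 4)
        assert np.nanmean(res.speed[ring]) == pytest.approx(speed, rel=0.05)
        r, c = 2, 7
        direction = res.direction[r, c]
        radial = np.array([r - 7, c - 7], dtype=float)
        radial /= np.linalg.norm(radial)
        assert abs(np.dot(direction, radial)) > 0.98


class TestHeterogeneityIqr:
    def test_quantile_convention_on_1_to_100(self):
        assert am.heterogeneity_iqr(np.arange(1.0, 101.0).reshape(10, 10)) == 49.5

    def test_constant_map_is_zero(self):
        assert am.heterogeneity_iqr(np.full((4, 4), 7.0)) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 6))
        assert am.heterogeneity_iqr(vals + 3.3) == pytest.approx(
            am.heterogeneity_iqr(vals))

    def test_too_few_pixels_raise(self):
        with pytest.raises(am.InvalidParameterError):
            am.heterogeneity_iqr(np.array([[1.0, 2.0], [np.nan, np.nan]]))


class TestAmplitudeInvariance:
    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_time_features_unchanged_under_scaling(self, scale):
        fp = 1000.0 / 900.0
        w = am.make_ap_waveform(55.0, 12.0, fp)
        act0 = am.activation_time(w.values, None, fp)
        act1 = am.activation_time(scale * w.values, None, fp)
        assert act1.value == pytest.approx(act0.value, abs=1e-9)
        d0 = am.duration_at_level(w.values, None, act0.value, 0.9, fp)
        d1 = am.duration_at_level(scale * w.values, None, act0.value, 0.9, fp)
        assert d1.value == pytest.approx(d0.value, abs=1e-9)
        r0 = am.rise_time(w.values, None, fp)
        r1 = am.rise_time(scale * w.values, None, fp)
        assert r1.value == pytest.approx(r0.value, abs=1e-9)


class TestFullPipelineRecovery:
    def test_noisy_map_means_within_two_percent(self, frame_period):
        ts = uniform_tissue(10, 10, FAST_CAT)
        pr = am.ProtocolSpec(mode="fixed_rate", s1_cycle_length=1000.0 / 6.0,
                             s1_count=5)
        v, _, truth = am.simulate_movie(ts, pr, am.NoiseSpec(sigma=0.05, seed=0))
        v = am.spatial_gaussian3(v)
        feats = am.measure_beats(v, temporal_smooth=5)
        apd90 = am.feature_stack(feats, v.shape, "apd90")
        assert np.nanmean(apd90[3]) == pytest.approx(np.nanmean(truth.apd90[3]),
                                                     rel=0.02)
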