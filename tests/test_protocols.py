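"""Protocol analysis: S2/S1 restitution, AERP, SNRT, AF episodes, flux rates."""

import math

import numpy as np
import pytest

import atriamap as am
from atriamap.wavemetrics import upstroke_amplitude

from conftest import FAST_CAT, uniform_tissue


def movie_beat_amplitudes(ca_movie, truth):
    """(n_beats, R, C) upstroke amplitudes from stimulus-aligned windows."""
    fp = ca_movie.frame_period
    bounds = [int(round(t / fp)) for t in truth.stimulus_times] + [ca_movie.n_frames]
    R, C = ca_movie.shape
    out = np.full((len(truth.stimulus_times), R, C), np.nan)
    for k in range(len(truth.stimulus_times)):
        seg = ca_movie.frames[bounds[k] : bounds[k + 1]]
        for r in range(R):
            for c in range(C):
                out[k, r, c] = upstroke_amplitude(seg[:, r, c])
    return out


class TestS2S1Ratio:
    def test_direct_ratio(self):
        amps = np.concatenate([np.ones((4, 4, 4)), np.full((1, 4, 4), 0.5)])
        res = am.s2s1_ratio(amps, ["s1"] * 4 + ["s2"], interval=100.0,
                            sites=[(1, 1)])
        assert res.field_ratio == pytest.approx(0.5)
        assert res.site_ratios == [pytest.approx(0.5)]

    def test_generator_closed_form_at_tau(self):
        # release recovery constant 60 ms at a 60-ms coupling interval
        ts = uniform_tissue(8, 8, FAST_CAT, aerp_ms=20.0)
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=5,
                             s2_intervals=(60.0,))
        _, ca, truth = am.simulate_movie(ts, pr)
        amps = movie_beat_amplitudes(ca, truth)
        res = am.s2s1_ratio(amps, truth.beat_labels, interval=60.0, sites=[(4, 4)])
        assert res.field_ratio == pytest.approx(1.0 - math.exp(-1.0), abs=0.02)

    def test_full_recovery_limit(self):
        params = am.RestitutionParams(apd_max=30.0, tau_rest=10.0,
                                      cat_decay_tau=0.008, cat_amp_tau_refr=30.0,
                                      rise_time=10.0, cat90_offset=5.0)
        ts = uniform_tissue(8, 8, params, aerp_ms=20.0)
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=5,
                             s2_intervals=(150.0,))
        _, ca, truth = am.simulate_movie(ts, pr)
        amps = movie_beat_amplitudes(ca, truth)
        res = am.s2s1_ratio(amps, truth.beat_labels, interval=150.0)
        assert res.field_ratio == pytest.approx(1.0, abs=0.02)

    def test_ratio_monotone_in_coupling_interval(self):
        ts = uniform_tissue(8, 8, FAST_CAT, aerp_ms=20.0)
        intervals = [30.0, 50.0, 70.0, 90.0, 120.0, 150.0]
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=5,
                             s2_intervals=tuple(intervals))
        _, ca, truth = am.simulate_movie(ts, pr)
        amps = movie_beat_amplitudes(ca, truth)
        ratios = []
        for i, s2 in enumerate(intervals):
            train = slice(i * 6, i * 6 + 6)
            res = am.s2s1_ratio(amps[train], truth.beat_labels[train.start:train.stop],
                                interval=s2)
            ratios.append(res.field_ratio)
        assert all(b >= a - 0.02 for a, b in zip(ratios, ratios[1:]))


class TestFitRestitution:
    def test_noiseless_tau_recovered_within_one_percent(self):
        d = np.array([40.0, 60.0, 80.0, 100.0, 120.0, 150.0])
        r = 1.0 * (1.0 - np.exp(-(d - 20.0) / 60.0))
        fit = am.fit_restitution(d, r)
        assert not fit.flagged
        assert fit.tau_r == pytest.approx(60.0, rel=0.01)

    def test_flat_curve_is_flagged_unidentifiable(self):
        fit = am.fit_restitution([40.0, 60.0, 80.0, 100.0], [0.8] * 4)
        assert fit.flagged
        assert math.isnan(fit.tau_r)

    def test_steeper_generator_gives_larger_steepness(self):
        d = np.linspace(40, 150, 8)
        steep = am.fit_restitution(d, 1 - np.exp(-(d - 20) / 40.0)).steepness
        shallow = am.fit_restitution(d, 1 - np.exp(-(d - 20) / 80.0)).steepness
        assert steep > shallow

    def test_too_few_points_raise(self):
        with pytest.raises(am.InvalidParameterError):
            am.fit_restitution([50.0, 60.0, 70.0], [0.5, 0.6, 0.7])


class TestAerp:
    def test_definition_longest_failing_interval(self):
        outcomes = {100.0: True, 90.0: True, 80.0: True, 70.0: True,
                    60.0: False, 50.0: False}
        res = am.aerp_from_s1s2(outcomes, apd90=40.0)
        assert res.aerp == 60.0
        assert res.aerp_apd_ratio == pytest.approx(1.5)

    def test_all_capture_reports_upper_bound(self):
        res = am.aerp_from_s1s2({i: True for i in (30.0, 50.0, 70.0)})
        assert res.aerp is None
        assert res.upper_bound == 30.0

    def test_generator_truth_recovered_within_one_step(self):
        ts = uniform_tissue(8, 8, FAST_CAT, aerp_ms=55.0)
        intervals = tuple(np.arange(30.0, 101.0, 5.0))
        pr = am.ProtocolSpec(mode="S1S2_extrastimulus", s1_count=5,
                             s2_intervals=intervals)
        _, ca, truth = am.simulate_movie(ts, pr)
        fp = ca.frame_period
        bounds = [int(round(t / fp)) for t in truth.stimulus_times] + [ca.n_frames]
        capture = {}
        for i, s2 in enumerate(intervals):
            sl = slice(i * 6, i * 6 + 6)
            seg_amps = []
            for k in range(sl.start, sl.stop):
                seg = ca.frames[bounds[k] : bounds[k + 1]]
                seg_amps.append([[upstroke_amplitude(seg[:, r, c])
                                  for c in range(8)] for r in range(8)])
            seg_amps = np.asarray(seg_amps)
            s1_ref = seg_amps[2:5].mean(axis=0)
            capture[s2] = am.detect_capture(seg_amps[5], s1_ref)
        res = am.aerp_from_s1s2(capture)
        assert res.aerp is not None
        assert abs(res.aerp - 55.0) <= 5.0


class TestSnrt:
    def test_raw_and_corrected(self):
        assert am.snrt([350.0, 550.0], 0.0, 200.0) == (350.0, 150.0)

    def test_first_beat_at_baseline_gives_zero_corrected(self):
        raw, corr = am.snrt([1200.0], 1000.0, 200.0)
        assert corr == pytest.approx(0.0)

    def test_no_spontaneous_beat_is_missing(self):
        assert am.snrt([100.0], 1000.0, 200.0, window_ms=500.0) is None


class TestDetectEpisodes:
    def test_regular_rhythm_yields_empty_report(self):
        times = np.arange(0.0, 10_000.0, 200.0)
        report = am.detect_episodes(times, 200.0)
        assert report.n_episodes == 0 and not report.induced

    def test_labeled_episode_recovered(self):
        times, truth = am.simulate_af_trace(
            200.0, [(3_000.0, 8_000.0, 70.0, 20.0)], 15_000.0, seed=5)
        report = am.detect_episodes(times, 200.0)
        assert report.n_episodes == 1
        onset, offset = report.episodes[0]
        assert abs(onset - 3_000.0) <= 2 * 200.0
        assert abs(offset - 8_000.0) <= 2 * 200.0
        assert report.total_duration_s == pytest.approx(5.0, abs=0.5)

    def test_three_rapid_cycles_are_below_threshold(self):
        times = list(np.arange(0.0, 4_000.0, 200.0))
        insert = times[10]
        rapid = [insert + 60.0, insert + 110.0, insert + 175.0]
        merged = np.sort(np.concatenate([times, rapid]))
        report = am.detect_episodes(merged, 200.0)
        assert report.n_episodes == 0

    def test_sensitivity_and_false_rate_over_seeded_runs(self):
        detected, false_runs = 0, 0
        for seed in range(200):
            times, truth = am.simulate_af_trace(
                180.0, [(5_000.0, 10_000.0, 70.0, 20.0)], 20_000.0, seed=seed)
            report = am.detect_episodes(times, 180.0)
            hit = any(abs(a - 5_000.0) < 1_000.0 for a, b in report.episodes)
            detected += hit
            false_runs += (report.n_episodes - int(hit)) > 0
        assert detected / 200.0 >= 0.95
        assert false_runs / 200.0 <= 0.05


class TestFluxRates:
    def test_linear_caffeine_upstroke_rate(self):
        t = np.linspace(0.0, 0.02, 21)
        v = np.linspace(0.0, 1.0, 21)
        t_full = np.concatenate([[-0.01, -0.005], t, [0.025, 0.03]])
        v_full = np.concatenate([[0.0, 0.0], v, [1.0, 1.0]])
        rec_t = np.linspace(0.0, 20.0, 15)
        rec = 1.0 - np.exp(-rec_t / 4.0)
        rates = am.flux_rates(t_full, v_full, rec_t, rec)
        assert rates.ryr2_rate == pytest.approx(50.0, rel=0.05)

    def test_recovery_time_constant_recovered(self):
        rec_t = np.linspace(0.0, 20.0, 25)
        rec = 0.9 * (1.0 - np.exp(-rec_t / 4.0)) + 0.05
        t = np.linspace(0, 0.05, 30)
        v = 1.0 / (1.0 + np.exp(-(t - 0.02) / 0.004))
        rates = am.flux_rates(t, v, rec_t, rec)
        assert rates.serca_rate_inv == pytest.approx(4.0, rel=0.02)

    def test_flat_caffeine_response_is_flagged(self):
        t = np.linspace(0, 0.05, 30)
        rates = am.flux_rates(t, np.zeros_like(t), t, np.zeros_like(t))
        assert rates.flagged
        assert rates.ryr2_rate is None

    def test_recovery_within_five_percent_at_noise(self):
        rng = np.random.default_rng(1)
        rec_t = np.linspace(0.0, 20.0, 25)
        rec = 1.0 - np.exp(-rec_t / 4.0) + rng.normal(0, 0.02, rec_t.size)
        t = np.linspace(0, 0.05, 40)
        v = 1.0 / (1.0 + np.exp(-(t - 0.02) / 0.004)) + rng.normal(0, 0.02, t.size)
        rates = am.flux_rates(t, v, rec_t, rec)
        assert rates.serca_rate_inv == pytest.approx(4.0, rel=0.05)
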