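"""Pupil preprocessing and tonic/phasic deconvolution."""

import numpy as np
import pandas as pd
import pytest

from wandertap import pupil as pp


def make_trace(fs=100.0, duration=30.0, level=1000.0):
    t = np.arange(0, duration, 1 / fs)
    return pp.PupilTrace(fs, t, np.full_like(t, level))


def insert_dropout(trace, on, off, floor=10.0):
    """Steep dip-and-rebound artifact mimicking an eye blink."""
    x = trace.size.copy()
    t = trace.time
    env = np.interp(t, [on, on + 0.25 * (off - on), off - 0.25 * (off - on), off],
                    [1.0, floor / x.max(), floor / x.max(), 1.0], left=1.0, right=1.0)
    return pp.PupilTrace(trace.fs, t, x * env)


class TestBlinkDetection:
    def test_single_dropout_found(self):
        tr = insert_dropout(make_trace(), 10.0, 10.3)
        iv = pp.detect_blinks(tr)
        assert len(iv) == 1
        on, off = iv[0]
        assert on == pytest.approx(10.0, abs=0.05)
        assert off == pytest.approx(10.3, abs=0.05)

    def test_constant_trace_no_blinks(self):
        assert len(pp.detect_blinks(make_trace())) == 0

    def test_close_dropouts_merged(self):
        tr = insert_dropout(insert_dropout(make_trace(), 10.0, 10.2), 10.35, 10.55)
        merged = pp.merge_blinks(pp.detect_blinks(tr), merge_distance=0.2)
        assert len(merged) == 1
        assert merged[0][0] == pytest.approx(10.0, abs=0.06)
        assert merged[0][1] == pytest.approx(10.55, abs=0.06)

    def test_missing_runs_always_included(self):
        tr = make_trace()
        tr.mask[500:550] = False
        iv = pp.detect_blinks(tr)
        assert any(on <= tr.time[500] <= off for on, off in iv)


class TestInterpolation:
    def test_flat_signal_stays_flat(self):
        tr = insert_dropout(make_trace(), 12.0, 12.3)
        out = pp.interpolate_blinks(tr, [(12.0, 12.3)], margin=0.1)
        np.testing.assert_allclose(out.size, 1000.0, atol=1e-9)

    def test_linear_ramp_reproduced_exactly(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        ramp = 900 + 10 * t
        tr = pp.PupilTrace(fs, t, ramp.copy())
        tr.size[800:830] = 0.0
        out = pp.interpolate_blinks(tr, [(8.0, 8.3)], margin=0.1)
        np.testing.assert_allclose(out.size, ramp, atol=1e-6)

    def test_mask_fraction_counts_gap_plus_margins(self):
        tr = make_trace(duration=100.0)
        out = pp.interpolate_blinks(tr, [(50.0, 50.5)], margin=0.1)
        frac = 1.0 - out.mask.mean()
        assert frac == pytest.approx((0.5 + 0.2) / 100.0, abs=2 / tr.fs / 100.0 * 100)

    def test_edge_interval_filled_with_nearest_value(self):
        tr = make_trace()
        tr.size[:30] = 0.0
        out = pp.interpolate_blinks(tr, [(0.0, 0.3)], margin=0.1)
        np.testing.assert_allclose(out.size[:30], out.size[60])


class TestFiltering:
    def test_dc_preserved(self):
        out = pp.lowpass(make_trace(), 5.0)
        np.testing.assert_allclose(out.size, 1000.0, atol=1e-6)

    def test_stopband_attenuation(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        tr = pp.PupilTrace(fs, t, np.sin(2 * np.pi * 20 * t))
        out = pp.lowpass(tr, 5.0)
        inner = slice(int(fs), int(9 * fs))
        assert np.abs(out.size[inner]).max() < 0.1  # > 90% attenuation at 20 Hz

    def test_passband_amplitude_and_zero_phase(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        out = pp.lowpass(pp.PupilTrace(fs, t, x), 5.0)
        inner = slice(int(5 * fs), int(55 * fs))
        assert np.abs(out.size[inner]).max() == pytest.approx(1.0, rel=0.01)
        lag = np.argmax(np.correlate(out.size[inner], x[inner], "full")) - (x[inner].size - 1)
        assert lag == 0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            pp.lowpass(make_trace(fs=100.0), 60.0)


class TestDownsampling:
    def test_quarter_sample_count(self):
        tr = make_trace(fs=1000.0, duration=10.0)
        out = pp.downsample(tr, 250.0)
        assert out.size.size == tr.size.size // 4
        np.testing.assert_allclose(out.size, 1000.0)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            pp.downsample(make_trace(fs=1000.0), 300.0)

    def test_mask_conserved_any_masked_rule(self):
        tr = make_trace(fs=1000.0, duration=10.0)
        tr.mask[1000:1500] = False
        out = pp.downsample(tr, 250.0)
        frac_in, frac_out = 1 - tr.mask.mean(), 1 - out.mask.mean()
        assert abs(frac_in - frac_out) < 1.0 / 250.0

    def test_event_alignment_error_bounded(self):
        tr = make_trace(fs=1000.0, duration=10.0)
        onset = 5.5511
        out = pp.downsample(tr, 250.0)
        nearest = out.time[np.argmin(np.abs(out.time - onset))]
        assert abs(nearest - onset) < 1.0 / 250.0


class TestPrf:
    def test_zero_at_origin_and_negative_times(self):
        assert pp.prf(0.0) == 0.0
        assert pp.prf(-0.5) == 0.0

    def test_peak_location_and_height(self):
        t = np.linspace(0, 4, 40001)
        h = pp.prf(t)
        assert t[np.argmax(h)] == pytest.approx(0.9, abs=1e-3)
        assert h.max() == pytest.approx(1.0, abs=1e-9)

    def test_half_peak_ratio_closed_form(self):
        n, tmax = 10, 0.9
        expected = 0.5 ** n * np.exp(n * 0.5)
        assert pp.prf(tmax / 2) / pp.prf(tmax) == pytest.approx(expected)


class TestTonicEstimation:
    def test_sine_plus_bumps_recovered(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        tonic_true = 100 + 10 * np.sin(2 * np.pi * t / 40)
        events = np.arange(2, 58, 4.0)
        sig = tonic_true + pp.prf(t[:, None] - events[None, :]) @ np.full(events.size, 5.0)
        est = pp.estimate_tonic(pp.PupilTrace(fs, t, sig), events)
        # 5% of the 10-unit sine amplitude
        assert np.abs(est - tonic_true).max() < 0.5

    def test_zero_phasic_content_tracks_signal(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        x = 100 + 10 * np.sin(2 * np.pi * t / 40)
        est = pp.estimate_tonic(pp.PupilTrace(fs, t, x))
        assert np.sqrt(np.mean((est - x) ** 2)) < 0.1

    def test_tonic_never_exceeds_signal(self):
        rng = np.random.default_rng(0)
        fs = 50.0
        t = np.arange(0, 40, 1 / fs)
        x = 100 + np.cumsum(rng.standard_normal(t.size)) * 0.3
        est = pp.estimate_tonic(pp.PupilTrace(fs, t, x), np.arange(2, 38, 3.0))
        assert np.all(est <= x + 1e-9)


class TestPhasicEstimation:
    def test_single_event_roundtrip(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        sig = 500 + 7.0 * pp.prf(t - 5.0)
        coef = pp.estimate_phasic(pp.PupilTrace(fs, t, sig), np.full_like(t, 500.0), [5.0])
        assert coef[0] == pytest.approx(7.0, abs=1e-6)

    def test_pure_tonic_gives_zero_coefficients(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        coef = pp.estimate_phasic(pp.PupilTrace(fs, t, np.full_like(t, 500.0)),
                                  np.full_like(t, 500.0), [3.0, 9.0])
        np.testing.assert_allclose(coef, 0.0, atol=1e-9)

    def test_negative_artifact_keeps_coefficients_nonnegative(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        sig = 500 - 20.0 * pp.prf(t - 5.0)
        coef = pp.estimate_phasic(pp.PupilTrace(fs, t, sig), np.full_like(t, 500.0), [5.0, 10.0])
        assert np.all(coef >= 0)


class TestTrialFeatures:
    def _decomp(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        onsets = np.array([5.0, 5.1, 10.0, 10.3])  # stim, tap, stim, late tap
        amps = np.array([2.0, 3.0, 4.0, 5.0])
        sig = 100 + pp.prf(t[:, None] - onsets[None, :]) @ amps
        tr = pp.PupilTrace(fs, t, sig)
        dec = pp.TonicPhasicDecomposition(np.full_like(t, 100.0), onsets, amps, np.zeros_like(t))
        return dec, tr

    def test_window_sums_coefficients(self):
        dec, tr = self._decomp()
        rows = pp.trial_features(dec, tr, [5.0, 10.0])
        assert rows["phasic"].iloc[0] == pytest.approx(2.0 + 3.0)  # tap 100 ms later included
        assert rows["phasic"].iloc[1] == pytest.approx(4.0)        # tap 300 ms later excluded

    def test_tonic_sampled_at_onset(self):
        dec, tr = self._decomp()
        rows = pp.trial_features(dec, tr, [5.0])
        assert rows["tonic"].iloc[0] == pytest.approx(100.0)

    def test_missing_fraction_over_trial_span(self):
        dec, tr = self._decomp()
        tr.mask[int(5.0 * tr.fs):int(5.0 * tr.fs) + 25] = False  # 0.25 s of 0.75 s
        rows = pp.trial_features(dec, tr, [5.0])
        assert rows["missing_fraction"].iloc[0] == pytest.approx(1 / 3, abs=0.02)


class TestStandardization:
    def test_within_subject_moments(self):
        df = pd.DataFrame({
            "subject": [0] * 10 + [1] * 10,
            "tonic": np.r_[np.random.default_rng(0).normal(5, 2, 10),
                           np.random.default_rng(1).normal(50, 9, 10)],
            "phasic": np.random.default_rng(2).normal(0, 1, 20),
        })
        out = pp.zscore_within_subject(df)
        for _, g in out.groupby("subject"):
            assert g["tonic"].mean() == pytest.approx(0, abs=1e-12)
            assert np.std(g["tonic"]) == pytest.approx(1)

    def test_differs_from_grand_z_when_scales_differ(self):
        from wandertap.behavior import zscore_grand

        df = pd.DataFrame({"subject": [0] * 5 + [1] * 5,
                           "tonic": [1, 2, 3, 4, 5, 10, 20, 30, 40, 50],
                           "phasic": np.arange(10.0)})
        within = pp.zscore_within_subject(df)["tonic"].to_numpy()
        grand = zscore_grand(df["tonic"])
        assert not np.allclose(within, grand)


class TestProbePupilFeatures:
    def _trials(self, n=60, missing=None):
        df = pd.DataFrame({
            "onset": 0.75 * np.arange(n),
            "tonic": np.arange(n, dtype=float),
            "phasic": np.ones(n),
            "missing_fraction": np.zeros(n),
        })
        if missing:
            for i, f in missing.items():
                df.loc[i, "missing_fraction"] = f
        return df

    def test_plain_25_trial_means(self):
        df = self._trials()
        out = pp.probe_pupil_features(df, [0.75 * 60])
        assert out["tonic"].iloc[0] == pytest.approx(np.mean(np.arange(35, 60)))
        assert out["n_valid_trials"].iloc[0] == 25

    def test_half_missing_trial_dropped(self):
        df = self._trials(missing={50: 0.5})
        out = pp.probe_pupil_features(df, [0.75 * 60])
        expected = np.mean([v for v in range(35, 60) if v != 50])
        assert out["tonic"].iloc[0] == pytest.approx(expected)
        assert out["n_valid_trials"].iloc[0] == 24

    def test_window_duration_is_18_75_s(self):
        # 25 trials at the 750-ms SOA span 18.75 s
        df = self._trials()
        probe = 0.75 * 60
        window_start = df["onset"].iloc[60 - 25]
        assert probe - window_start == pytest.approx(18.75)

    def test_all_invalid_window_excludes_probe(self):
        df = self._trials(missing={i: 1.0 for i in range(35, 60)})
        out = pp.probe_pupil_features(df, [0.75 * 60])
        assert bool(out["excluded"].iloc[0])


class TestFullPipelineRoundtrip:
    def test_generated_trace_recovers_truth(self):
        """Correlated tonic recovery and accurate phasic amplitudes on a
        noiseless generated trace with events >= 750 ms apart."""
        from wandertap import synth

        cfg = synth.SimConfig(pupil_fs=100.0)
        gen = synth.PupilGenParams(drift_sd=8.0, drift_tau=15.0, noise_sd=0.0,
                                   decoupling=0.0, phasic_amp=25.0)
        sub = synth.SubjectParams(blink_rate=0.0, pupil_params=gen)
        state = synth.simulate_latent_state(120, synth.LatentParams(), np.random.default_rng(5))
        onsets = np.arange(3.0, 117.0, 3.0)
        events = pd.DataFrame({"onset": onsets, "kind": "stimulus"})
        tr = synth.simulate_pupil(state, events, sub, cfg, np.random.default_rng(5))
        tonic_true = tr.size - pp.prf(tr.time[:, None] - onsets[None, :]) @ np.full(onsets.size, 25.0)
        dec = pp.deconvolve(tr, onsets)
        inner = (tr.time > 5) & (tr.time < 115)
        assert np.corrcoef(dec.tonic[inner], tonic_true[inner])[0, 1] > 0.95
        assert np.all(dec.coefficients >= 0)
        assert np.all(dec.tonic <= tr.size + 1e-9)
        rmse = np.sqrt(np.mean((dec.coefficients - 25.0) ** 2))
        assert rmse < 0.05 * 25.0
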