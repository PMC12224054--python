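import numpy as np
import pytest
from scipy.stats import norm

from gradspike import (
    Recording, detect_spikes, estimate_thresholds, extract_waveforms,
)


def make_recording(noise_std=1.0, duration=1.0, fs=24000.0, n_channels=1, seed=0):
    rng = np.random.default_rng(seed)
    samples = rng.normal(0, noise_std, (n_channels, int(duration * fs)))
    return Recording(samples, fs), rng


def inject(rec, channel, time_s, template):
    start = int(round(time_s * rec.sampling_rate))
    rec.samples[channel, start:start + len(template)] += template


def spike_template(fs, amp=-120.0, width_ms=0.3):
    t = np.arange(int(2e-3 * fs)) / fs * 1e3
    return amp * np.exp(-0.5 * ((t - 1.0) / width_ms) ** 2)


class TestEstimateThresholds:
    def test_definition_multiplier_times_std(self, rng):
        samples = rng.normal(0, 2.0, (1, 200_000))
        rec = Recording(samples, 24000.0)
        thr = estimate_thresholds(rec, multiplier=5.0)
        assert thr[0] == pytest.approx(5.0 * samples.std(), rel=1e-12)

    def test_zero_variance_channel_flagged(self):
        rec = Recording(np.zeros((1, 1000)), 24000.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            thr = estimate_thresholds(rec)
        assert thr[0] == 0.0

    def test_gaussian_crossing_rate_monte_carlo(self):
        """|x| > 5 sigma on 10^6 Gaussian samples: ~2 Phi(-5) 10^6 ~ 0.57."""
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(1_000_000)
            counts.append(np.sum(np.abs(x) > 5.0 * x.std()))
        expected = 2 * norm.cdf(-5.0) * 1e6
        assert expected == pytest.approx(0.57, abs=0.01)
        assert np.mean(counts) == pytest.approx(expected, abs=1.0)

    def test_robust_estimator_ignores_spikes(self):
        rec, _ = make_recording(noise_std=1.0, seed=3)
        for t in np.arange(0.05, 0.95, 0.01):
            inject(rec, 0, t, spike_template(rec.sampling_rate, amp=-300.0))
        plain = estimate_thresholds(rec)[0]
        robust = estimate_thresholds(rec, robust=True)[0]
        assert robust < plain  # MAD shrugs off the spike outliers


class TestDetectSpikes:
    def test_single_injected_spike_found(self):
        rec, _ = make_recording(noise_std=1.0, seed=1)
        inject(rec, 0, 0.5, spike_template(rec.sampling_rate))
        det = detect_spikes(rec, thresholds=np.array([5.0]))
        assert det.n_events == 1
        # trough of the template sits 1 ms after its start
        assert det.event_times[0] == pytest.approx(0.501, abs=5e-4)

    def test_pure_noise_at_10_sigma_is_silent(self):
        for seed in range(20):
            rec, _ = make_recording(noise_std=1.0, seed=seed, duration=0.5)
            thr = estimate_thresholds(rec, multiplier=10.0)
            assert detect_spikes(rec, thr).n_events == 0

    def test_close_spikes_merge_within_refractory(self):
        rec, _ = make_recording(noise_std=0.5, seed=2)
        tpl = spike_template(rec.sampling_rate)
        inject(rec, 0, 0.5, tpl)
        inject(rec, 0, 0.5003, tpl * 0.8)  # 0.3 ms apart
        det = detect_spikes(rec, thresholds=np.array([5.0]), refractory=1e-3)
        assert det.n_events == 1

    def test_translation_equivariance(self):
        rec, _ = make_recording(noise_std=0.5, seed=4, duration=0.5)
        inject(rec, 0, 0.2, spike_template(rec.sampling_rate))
        shift = 240  # 10 ms
        shifted = Recording(np.roll(rec.samples, shift, axis=1), rec.sampling_rate)
        d1 = detect_spikes(rec, thresholds=np.array([5.0]))
        d2 = detect_spikes(shifted, thresholds=np.array([5.0]))
        assert np.allclose(d2.event_times, d1.event_times + shift / rec.sampling_rate)

    def test_scale_invariance_with_matched_thresholds(self):
        rec, _ = make_recording(noise_std=1.0, seed=5, duration=0.5)
        inject(rec, 0, 0.2, spike_template(rec.sampling_rate))
        scaled = Recording(rec.samples * 7.0, rec.sampling_rate)
        d1 = detect_spikes(rec, thresholds=np.array([5.0]))
        d2 = detect_spikes(scaled, thresholds=np.array([35.0]))
        assert np.array_equal(d1.event_times, d2.event_times)

    def test_refractory_longer_than_recording_rejected(self):
        rec, _ = make_recording(duration=0.1)
        with pytest.raises(ValueError, match="refractory"):
            detect_spikes(rec, thresholds=np.array([5.0]), refractory=1.0)

    def test_positive_polarity_finds_positive_spikes(self):
        rec, _ = make_recording(noise_std=0.5, seed=6, duration=0.5)
        inject(rec, 0, 0.2, -spike_template(rec.sampling_rate))  # positive bump
        assert detect_spikes(rec, thresholds=np.array([5.0]), polarity="pos").n_events == 1
        assert detect_spikes(rec, thresholds=np.array([5.0]), polarity="neg").n_events == 0


class TestExtractWaveforms:
    def test_alignment_of_extreme_sample(self):
        rec, _ = make_recording(noise_std=0.5, seed=7)
        inject(rec, 0, 0.5, spike_template(rec.sampling_rate))
        det = detect_spikes(rec, thresholds=np.array([5.0]))
        ws = extract_waveforms(rec, det, window=(20, 44), align="sample")
        assert ws.n_samples == 65
        assert np.argmin(ws.waveforms[0]) == 20

    def test_edge_event_dropped_and_counted(self):
        rec, _ = make_recording(noise_std=0.0, duration=0.01)
        rec.samples[0, 3] = -100.0
        det = detect_spikes(rec, thresholds=np.array([5.0]))
        ws = extract_waveforms(rec, det, window=(20, 44))
        assert ws.n_spikes == 0
        assert ws.n_dropped == 1

    def test_extracted_snippet_matches_template(self):
        rec, _ = make_recording(noise_std=1.0, seed=8)
        tpl = spike_template(rec.sampling_rate)
        inject(rec, 0, 0.5, tpl)
        det = detect_spikes(rec, thresholds=np.array([5.0]))
        ws = extract_waveforms(rec, det, window=(10, 15))
        trough = np.argmin(tpl)
        ref = tpl[trough - 10:trough + 16]
        r = np.corrcoef(ws.waveforms[0], ref)[0, 1]
        assert r > 0.99

    def test_interpolated_alignment_reduces_phase_jitter(self):
        """Sub-sample offsets between repeats shrink under spline alignment."""
        fs = 24000.0
        rng = np.random.default_rng(9)
        samples = rng.normal(0, 1.0, (1, int(2.0 * fs)))
        rec = Recording(samples, fs)
        tpl = spike_template(fs, width_ms=0.5)
        # inject at off-grid times so the true trough lies between samples
        times = np.arange(0.1, 1.9, 0.05) + rng.uniform(0, 1 / fs, 36)
        for t in times:
            start = t * fs
            frac = start - int(start)
            n = len(tpl)
            shifted = np.interp(np.arange(n) + frac, np.arange(n), tpl)
            rec.samples[0, int(start):int(start) + n] += shifted
        det = detect_spikes(rec, thresholds=np.array([5.0]))
        ws_raw = extract_waveforms(rec, det, window=(20, 27), align="sample")
        ws_int = extract_waveforms(rec, det, window=(20, 27), align="interpolated")
        spread_raw = np.linalg.norm(ws_raw.waveforms - ws_raw.waveforms.mean(0), axis=1).mean()
        spread_int = np.linalg.norm(ws_int.waveforms - ws_int.waveforms.mean(0), axis=1).mean()
        assert spread_int < spread_raw
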