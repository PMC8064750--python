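import numpy as np
import pytest
from scipy import signal

from conftest import pink_with_bursts, silent_burst
from swrlab.ripples import (
    RippleEvent,
    RippleParams,
    annotate_events,
    bandpass_ripple,
    detect_ripples,
    exclude_artifact_events,
    multitaper_psd,
    ripple_envelope,
    ripple_peak_frequency,
    swr_incidence,
)
from swrlab.sigprep import ArtifactMask

FS = 1250.0


def brute_force_scan(filtered, fs, params=RippleParams()):
    """Independent oracle: sample-by-sample threshold walk over the
    envelope, an explicit gap-merge pass, then duration and peak gates."""
    env = ripple_envelope(filtered, fs, params.smooth_ms)
    sd = env.std()
    raw = []
    i = 0
    n = env.size
    while i < n:
        if env[i] > params.onset_sd * sd:
            j = i
            while j < n and env[j] > params.onset_sd * sd:
                j += 1
            raw.append([i, j])
            i = j
        else:
            i += 1
    strong = [(i, j) for i, j in raw if env[i:j].max() > params.peak_sd * sd]
    merged = []
    for i, j in strong:
        if merged and (i - merged[-1][1]) < params.merge_gap_ms / 1000 * fs:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    events = []
    for i, j in merged:
        dur_ms = (j - i) / fs * 1000
        if params.dur_ms_range[0] <= dur_ms <= params.dur_ms_range[1]:
            events.append((i / fs, j / fs))
    return events


class TestBandpass:
    def test_zero_in_zero_out(self):
        assert np.all(bandpass_ripple(np.zeros(5000), FS) == 0)

    @pytest.mark.parametrize(
        "freq, check",
        [(50.0, "stop"), (170.0, "pass"), (300.0, "stop")],
    )
    def test_frequency_response(self, freq, check):
        """Frequency-response oracle: out-of-band tones attenuated by at
        least the stopband spec (20 dB), in-band gain within 1 dB."""
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_ripple(x, FS)
        core = slice(2000, -2000)
        gain_db = 20 * np.log10(y[core].std() / x[core].std())
        if check == "pass":
            assert abs(gain_db) < 1.0
        else:
            assert gain_db < -20.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_ripple(np.zeros(100), 400.0)


class TestDetect:
    def test_single_burst_recovered_once(self):
        """A clearly suprathreshold 50 ms burst on a 1/f background comes
        back as one event of roughly its own duration in nearly all
        realisations (in-band background interference can occasionally
        fragment the envelope)."""
        clean = 0
        for seed in range(10):
            diff, truth = pink_with_bursts([(10.0, 170.0, 50.0, 10.0)], seed=seed)
            filt = bandpass_ripple(diff, FS)
            events = detect_ripples(filt, FS)
            overlapping = [
                e for e in events if e.start_s < truth[0][1] and truth[0][0] < e.end_s
            ]
            assert len(overlapping) >= 1
            assert all(e.peak_sd_units > 7 for e in overlapping)
            if len(overlapping) == 1 and 30 <= overlapping[0].duration_ms <= 90:
                clean += 1
        assert clean >= 9

    @pytest.mark.parametrize(
        "dur_ms, trace_s",
        [(10.0, 0.5), (10.0, 0.75), (10.0, 1.0), (350.0, 30.0), (350.0, 60.0)],
    )
    def test_duration_gate_rejects(self, dur_ms, trace_s):
        """Bursts outside the 20-300 ms gate never yield events
        (deterministic noise-free fixtures at study-typical SD units)."""
        for phase in np.linspace(0, 2 * np.pi, 7):
            trace, truth = silent_burst(dur_ms, trace_s, phase=phase)
            events = detect_ripples(bandpass_ripple(trace, FS), FS)
            assert not any(
                e.start_s < truth[1] and truth[0] < e.end_s for e in events
            )

    def test_in_gate_burst_retained_on_silent_background(self):
        trace, truth = silent_burst(50.0, 5.0)
        events = detect_ripples(bandpass_ripple(trace, FS), FS)
        assert len(events) == 1
        assert truth[0] < events[0].peak_time_s < truth[1]

    def test_matches_brute_force_oracle(self):
        """Detected intervals equal an independent sample-by-sample
        envelope scan on short fixtures."""
        for seed in range(5):
            specs = [(3.0, 160.0, 40.0, 9.0), (6.5, 180.0, 30.0, 12.0)]
            diff, _ = pink_with_bursts(specs, duration_s=10.0, seed=seed)
            filt = bandpass_ripple(diff, FS)
            got = [(e.start_s, e.end_s) for e in detect_ripples(filt, FS)]
            expected = brute_force_scan(filt, FS)
            assert got == pytest.approx(expected)

    def test_amplitude_equivariance(self):
        diff, _ = pink_with_bursts([(10.0, 170.0, 50.0, 10.0)])
        filt = bandpass_ripple(diff, FS)
        ev1 = detect_ripples(filt, FS)
        ev2 = detect_ripples(3.7 * filt, FS)
        assert [(e.start_s, e.end_s) for e in ev1] == [
            (e.start_s, e.end_s) for e in ev2
        ]

    def test_threshold_monotonicity(self):
        diff, _ = pink_with_bursts(
            [(3.0, 160.0, 40.0, 8.0), (8.0, 170.0, 50.0, 12.0)], seed=4
        )
        filt = bandpass_ripple(diff, FS)
        lo = detect_ripples(filt, FS, RippleParams(peak_sd=7.0))
        hi = detect_ripples(filt, FS, RippleParams(peak_sd=9.0))
        assert len(hi) <= len(lo)
        narrow = detect_ripples(filt, FS, RippleParams(dur_ms_range=(30.0, 100.0)))
        wide = detect_ripples(filt, FS, RippleParams(dur_ms_range=(20.0, 300.0)))
        assert len(wide) >= len(narrow)

    def test_white_noise_false_positive_rate(self):
        """Monte-Carlo: pure white noise rarely produces retained events
        (< 0.01 events/s)."""
        total_events = 0
        total_s = 0.0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(60 * FS))
            filt = bandpass_ripple(x, FS)
            total_events += len(detect_ripples(filt, FS))
            total_s += 60.0
        assert total_events / total_s < 0.01

    def test_duration_parameter_recovery(self):
        """Detected durations track injected durations (r > 0.9) across
        ~100 events spanning the 25-250 ms range."""
        from swrlab import synth

        rng = np.random.default_rng(3)
        r = np.random.default_rng(7)
        a = synth.generate_aperiodic(1.0, 2.0, 1000.0, FS, r) / 2
        (a2, b2), events_true = synth.inject_ripples(
            (a, -a), FS, 0.1, 170.0, (25.0, 250.0), 10.0, rng
        )
        filt = bandpass_ripple(a2 - b2, FS)
        events = detect_ripples(filt, FS)
        pairs = []
        for s, e, _, _ in events_true:
            hits = [ev for ev in events if ev.start_s < e and s < ev.end_s]
            if hits:
                pairs.append(((e - s) * 1000, hits[0].duration_ms))
        assert len(pairs) > 0.8 * len(events_true) and len(events_true) > 80
        inj, det = np.array(pairs).T
        assert np.corrcoef(inj, det)[0, 1] > 0.9


class TestPeakFrequency:
    def test_injected_frequency_recovered(self):
        diff, truth = pink_with_bursts([(10.0, 170.0, 50.0, 10.0)])
        filt = bandpass_ripple(diff, FS)
        events = annotate_events(detect_ripples(filt, FS), diff, FS)
        ev = [e for e in events if e.start_s < truth[0][1] and truth[0][0] < e.end_s][0]
        # resolution: fs/nfft = 1250/256 ~ 4.9 Hz, plus taper bandwidth
        assert ev.peak_freq_hz == pytest.approx(170.0, abs=15.0)
        assert ev.is_swr

    def test_low_frequency_burst_not_swr(self):
        """A 120 Hz burst (long enough for the taper bandwidth to resolve
        it from the 140 Hz gate) reads ~120 Hz and is not an SWR."""
        for seed in range(5):
            diff, truth = pink_with_bursts([(10.0, 120.0, 150.0, 10.0)], seed=seed)
            filt = bandpass_ripple(diff, FS)
            events = annotate_events(detect_ripples(filt, FS), diff, FS)
            ev = [
                e for e in events if e.start_s < truth[0][1] and truth[0][0] < e.end_s
            ][0]
            assert ev.peak_freq_hz == pytest.approx(120.0, abs=15.0)
            assert not ev.is_swr

    def test_swr_gate_boundary_inclusive_at_140(self):
        """The classification gate is >= 140 Hz, inclusive."""
        params = RippleParams()
        for freq, expected in [(139.99, False), (140.0, True), (140.01, True)]:
            ev = RippleEvent(0.0, 0.05, 0.02, 9.0, peak_freq_hz=freq)
            ev.is_swr = ev.peak_freq_hz >= params.swr_min_freq_hz
            assert ev.is_swr is expected

    def test_multitaper_grid_resolves_pure_tone(self):
        t = np.arange(256) / FS
        freqs, psd = multitaper_psd(np.sin(2 * np.pi * 170 * t), FS)
        assert freqs[np.argmax(psd)] == pytest.approx(170, abs=1250 / 512)

    def test_too_short_segment_raises(self):
        ev = RippleEvent(0.0, 0.002, 0.001, 8.0)
        with pytest.raises(ValueError, match="short"):
            ripple_peak_frequency(np.zeros(1000), ev, FS)


class TestExclusionAndIncidence:
    def _events(self, times):
        return [RippleEvent(t, t + 0.04, t + 0.02, 9.0, 170.0, True) for t in times]

    def test_empty_mask_keeps_all(self):
        evs = self._events([1.0, 2.0])
        assert exclude_artifact_events(evs, ArtifactMask([])) == evs

    def test_event_inside_mask_excluded(self):
        evs = self._events([5.0])
        kept = exclude_artifact_events(evs, ArtifactMask([(4.9, 5.2)]))
        assert kept == []
        assert evs[0].artifact_overlap

    def test_ground_truth_bookkeeping(self):
        """EMG bursts coincident with 3 of 10 events leave 7 survivors."""
        times = [float(t) for t in range(1, 11)]
        evs = self._events(times)
        mask = ArtifactMask([(t - 0.1, t + 0.1) for t in (2.0, 5.0, 9.0)])
        kept = exclude_artifact_events(evs, mask)
        assert len(kept) == 7
        assert sum(e.artifact_overlap for e in evs) == 3

    def test_incidence_arithmetic(self):
        assert swr_incidence([], 30.0) == 0.0
        evs = self._events([1, 2, 3, 4, 5, 6])
        assert swr_incidence(evs, 30.0) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            swr_incidence(evs, 0.0)

    def test_non_swr_events_not_counted(self):
        evs = self._events([1.0, 2.0])
        evs[0].is_swr = False
        assert swr_incidence(evs, 10.0) == pytest.approx(0.1)


class TestParams:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RippleParams(onset_sd=8.0, peak_sd=7.0)
        with pytest.raises(ValueError):
            RippleParams(dur_ms_range=(300.0, 20.0))
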