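import warnings

import numpy as np
import pytest

from swrlab import synth

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def short_session():
    """One 300 s default-condition session with ground truth (cached)."""
    cfg = synth.SimConfig(epoch_plan=synth.sleep_epoch_plan(5), seed=11)
    rec, truth = synth.generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def pink_with_bursts(
    burst_specs,  # list of (start_s, freq_hz, dur_ms, snr_sd)
    duration_s=20.0,
    fs=1250.0,
    seed=0,
):
    """Pink-noise differential trace with bursts injected at given times.

    Amplitudes are calibrated against the background's detection-envelope
    SD exactly as the generator does; returns (diff_trace, truth_list)
    with truth entries (start_s, end_s, freq_hz).
    """
    from swrlab.ripples import RippleParams, bandpass_ripple, ripple_envelope

    r = np.random.default_rng(seed)
    diff = synth.generate_aperiodic(1.0, 2.0, duration_s, fs, r)
    params = RippleParams()
    sd = float(np.std(ripple_envelope(bandpass_ripple(diff, fs, params), fs)))
    truth = []
    for start_s, freq_hz, dur_ms, snr_sd in burst_specs:
        wave = synth._burst_waveform(freq_hz, dur_ms / 1000.0, fs, phase=0.3)
        peak_unit = synth._envelope_peak_unit(wave, fs, params.smooth_ms)
        amp = np.sqrt(snr_sd * sd / peak_unit)
        i0 = int(round(start_s * fs))
        diff[i0 : i0 + wave.size] += amp * wave
        truth.append((start_s, start_s + dur_ms / 1000.0, freq_hz))
    return diff, truth


def silent_burst(dur_ms, trace_s, freq_hz=170.0, phase=0.3, fs=1250.0):
    """One noiseless burst in an otherwise silent trace.

    With no background, the detection envelope's SD is set entirely by the
    burst's duty cycle, so trace_s controls the burst's effective SD units
    deterministically — ~10 SD for a 10 ms burst in 0.75 s, ~16 SD for a
    350 ms burst in 60 s.  Used for exact (noise-free) gate tests.
    """
    x = np.zeros(int(trace_s * fs))
    w = synth._burst_waveform(freq_hz, dur_ms / 1000.0, fs, phase)
    i0 = int(trace_s / 2 * fs)
    x[i0 : i0 + w.size] = w
    return x, (trace_s / 2, trace_s / 2 + dur_ms / 1000.0)
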