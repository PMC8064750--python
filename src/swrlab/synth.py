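"""Ground-truthed synthetic LFP sessions.

Generates paired "staggered" CA1 LFP channels, an EMG channel, and epoch
annotations with the statistical structure the analysis pipeline assumes:

* a 1/f (pink-noise) aperiodic background with configurable exponent and
  offset, synthesized by exact spectral shaping of white noise;
* narrowband theta (5–12 Hz) and slow-gamma (25–45 Hz) oscillations,
  modelled as Gaussian-spectrum band-limited noise so their PSD peaks are
  smooth bumps rather than line spectra;
* transient ripple bursts (100–250 Hz, 20–300 ms) injected with *opposite*
  sign on the two LFP channels — the phase-reversed, locally generated
  signal the differential montage is designed to enhance;
* common-mode movement transients added *identically* to both channels
  (cancelled exactly by the differential) with coincident EMG bursts;
* EMG bursts that let the artifact-masking stage exercise its rejection
  rule.

Every injected event is returned in a :class:`GroundTruth` record, so the
detection and spectral stages can be scored against known truth.  The
default configuration reproduces the sleep stimulation protocol the
pipeline targets: 30 s laser-on epochs alternating with laser-off
intervals, ripple incidence 0.21 Hz off vs 0.03 Hz on, theta at 7.7 Hz off
shifting to 7.2 Hz with ~1.5x relative power when on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .sigprep import Recording
from .ripples import RippleParams, bandpass_ripple, ripple_envelope

__all__ = [
    "OscillationSpec",
    "EpochCondition",
    "SimConfig",
    "GroundTruth",
    "generate_aperiodic",
    "generate_oscillation",
    "inject_ripples",
    "generate_session",
    "sleep_epoch_plan",
]

ANALYSIS_FS_HZ = 1250.0


@dataclass(frozen=True)
class OscillationSpec:
    """A narrowband oscillation, specified the way the spectral
    decomposition measures it: centre frequency, peak height above the
    aperiodic background in log10-power units (``rel_height_log10``; the
    linear relative power is ``10**rel_height_log10``), and the SD of the
    Gaussian spectral bump in Hz.  Height 0 means no oscillation."""

    freq_hz: float
    rel_height_log10: float
    spectral_width_hz: float = 0.75


@dataclass(frozen=True)
class EpochCondition:
    """Signal statistics during one epoch label (laser off or on)."""

    ripple_incidence_hz: float
    theta: OscillationSpec
    gamma: OscillationSpec
    aperiodic_offset: float | None = None  # None -> SimConfig default


def sleep_epoch_plan(
    n_cycles: int = 10, off_s: float = 30.0, on_s: float = 30.0
) -> tuple[tuple[str, float], ...]:
    """Alternating laser-off / laser-on plan, off first."""
    plan: list[tuple[str, float]] = []
    for _ in range(n_cycles):
        plan += [("off", off_s), ("on", on_s)]
    return tuple(plan)


def _default_conditions() -> dict[str, EpochCondition]:
    # Laser-on: ripples largely suppressed, theta slows 7.7 -> 7.2 Hz and
    # its relative power rises 1.51x (log10 height +log10(1.51)).
    theta_h = 1.4
    return {
        "off": EpochCondition(
            ripple_incidence_hz=0.21,
            theta=OscillationSpec(7.7, theta_h, 0.75),
            gamma=OscillationSpec(35.0, 1.15, 1.5),
        ),
        "on": EpochCondition(
            ripple_incidence_hz=0.03,
            theta=OscillationSpec(7.2, theta_h + np.log10(1.51), 0.75),
            gamma=OscillationSpec(35.0, 1.15, 1.5),
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic session.

    ``epoch_plan`` is a sequence of ``(label, duration_s)`` pairs; the
    session duration is their sum.  Oscillation and ripple statistics per
    label come from ``conditions``.  Voltages are in arbitrary µV-like
    units; ``aperiodic_offset`` is log10 power at 1 Hz on that scale.
    """

    epoch_plan: tuple[tuple[str, float], ...] = field(
        default_factory=sleep_epoch_plan
    )
    fs_hz: float = ANALYSIS_FS_HZ
    aperiodic_exponent: float = 1.0
    aperiodic_offset: float = 2.0
    conditions: dict[str, EpochCondition] = field(
        default_factory=_default_conditions
    )
    ripple_freq_hz: float = 168.0
    ripple_dur_ms_range: tuple[float, float] = (25.0, 55.0)
    ripple_snr_sd: float = 10.0
    ripple_snr_jitter: float = 0.2  # per-event uniform amplitude scatter
    emg_artifact_rate_hz: float = 0.05
    common_artifact_rate_hz: float = 0.02
    emg_baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch plan must have positive total duration")
        if self.fs_hz < 2 * max(250.0, self.ripple_freq_hz):
            raise ValueError("fs_hz below twice the highest generated frequency")
        for rate in (self.emg_artifact_rate_hz, self.common_artifact_rate_hz):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for label, _ in self.epoch_plan:
            if label not in self.conditions:
                raise ValueError(f"epoch label {label!r} missing from conditions")
            if self.conditions[label].ripple_incidence_hz < 0:
                raise ValueError("ripple incidence must be >= 0")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.epoch_plan))


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery scoring."""

    ripple_times: list[tuple[float, float, float, float]]  # start, end, freq, amp
    emg_burst_times: list[float]
    common_artifact_times: list[float]
    spectral_params: dict[str, dict]
    duration_s: float

    def ripples_in(self, start_s: float, end_s: float) -> list[tuple]:
        return [r for r in self.ripple_times if start_s <= (r[0] + r[1]) / 2 < end_s]


def generate_aperiodic(
    exponent: float,
    offset: float,
    duration_s: float,
    fs_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^exponent background via exact spectral shaping of white noise.

    The one-sided PSD of the output is 10**offset / f**exponent, so the
    Welch estimate is a straight line of slope -exponent on log-log axes;
    exponent 0 reduces to white noise of density 10**offset.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration_s and fs_hz must be positive")
    n = int(round(duration_s * fs_hz))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = np.zeros_like(freqs)
    nz = freqs > 0
    # unit-variance white noise has one-sided PSD 2/fs
    gain[nz] = np.sqrt(10.0**offset * fs_hz / 2.0) * freqs[nz] ** (-exponent / 2.0)
    return np.fft.irfft(spec * gain, n=n)


def generate_oscillation(
    spec: OscillationSpec,
    aperiodic_exponent: float,
    aperiodic_offset: float,
    duration_s: float,
    fs_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited noise whose PSD is a Gaussian bump in *log-relative*
    power above the 1/f background.

    The oscillation's PSD is ``ap(f) * (10**(h*g(f)) - 1)`` with ``ap`` the
    aperiodic background, ``h`` the configured height and ``g`` a unit
    Gaussian around the centre frequency: added to an independent
    background realisation, the total PSD sits exactly ``h`` log10 units
    above the aperiodic line at the centre — the quantity the spectral
    decomposition reports as relative power.
    """
    n = int(round(duration_s * fs_hz))
    if spec.rel_height_log10 == 0:
        return np.zeros(n)
    if spec.rel_height_log10 < 0:
        raise ValueError("rel_height_log10 must be >= 0")
    white = rng.standard_normal(n)
    w = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    g = np.exp(-((freqs - spec.freq_hz) ** 2) / (2 * spec.spectral_width_hz**2))
    ap = np.zeros_like(freqs)
    nz = freqs > 0
    ap[nz] = 10.0**aperiodic_offset / freqs[nz] ** aperiodic_exponent
    psd = ap * (10.0 ** (spec.rel_height_log10 * g) - 1.0)
    return np.fft.irfft(w * np.sqrt(psd * fs_hz / 2.0), n=n)


def _burst_waveform(
    freq_hz: float, dur_s: float, fs_hz: float, phase: float
) -> np.ndarray:
    """Unit-amplitude ripple burst: sine under a flat-topped Tukey envelope.

    The flat top keeps the burst's suprathreshold extent close to its
    nominal duration, which makes the downstream 20–300 ms duration gate
    meaningful against ground truth.
    """
    n = max(2, int(round(dur_s * fs_hz)))
    t = np.arange(n) / fs_hz
    # alpha kept small: wider tapers shrink the suprathreshold extent well
    # below the nominal duration (a 350 ms burst would read as ~295 ms)
    env = signal.windows.tukey(n, alpha=0.1)
    return np.sin(2 * np.pi * freq_hz * t + phase) * env


def _envelope_peak_unit(wave: np.ndarray, fs_hz: float, smooth_ms: float) -> float:
    sq = wave**2
    k = max(1, int(round(smooth_ms / 1000.0 * fs_hz)))
    return float(np.convolve(sq, np.ones(k) / k, mode="same").max())


def _place_bursts(
    n_samples: int,
    fs_hz: float,
    windows: list[tuple[float, float, float]],  # (start_s, end_s, incidence)
    freq_hz: float,
    dur_range_ms: tuple[float, float],
    snr_sd: float,
    baseline_sd: float,
    rng: np.random.Generator,
    snr_jitter: float,
    min_gap_s: float,
    max_retries: int,
    params: RippleParams,
) -> tuple[np.ndarray, list[list]]:
    """Sample non-overlapping bursts into a differential track."""
    track = np.zeros(n_samples)
    placed: list[tuple[float, float]] = []
    events: list[list] = []
    margin = 0.05
    for w_start, w_end, rate in windows:
        span = w_end - w_start
        if rate == 0 or span <= 0:
            continue
        if not (0 < dur_range_ms[0] <= dur_range_ms[1] < span * 1000):
            raise ValueError("dur_range_ms must lie within (0, window duration)")
        n_events = int(rng.poisson(rate * span))
        for _ in range(n_events):
            for _attempt in range(max_retries + 1):
                dur_s = rng.uniform(*dur_range_ms) / 1000.0
                start = rng.uniform(w_start + margin, w_end - dur_s - margin)
                end = start + dur_s
                if all(
                    end + min_gap_s <= s or e + min_gap_s <= start for s, e in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_events} non-overlapping ripples in "
                    f"{span:.1f} s after {max_retries} retries"
                )
            placed.append((start, end))
            snr = snr_sd * (1.0 + snr_jitter * rng.uniform(-1.0, 1.0))
            wave = _burst_waveform(
                freq_hz, dur_s, fs_hz, phase=rng.uniform(0, 2 * np.pi)
            )
            peak_unit = _envelope_peak_unit(wave, fs_hz, params.smooth_ms)
            amp = float(np.sqrt(snr * baseline_sd / peak_unit))
            i0 = int(round(start * fs_hz))
            seg = slice(i0, min(n_samples, i0 + wave.size))
            track[seg] += amp * wave[: seg.stop - seg.start]
            events.append([start, end, freq_hz, amp])
    events.sort()
    return track, events


def _inject_windows(
    trace_pair: tuple[np.ndarray, np.ndarray],
    fs_hz: float,
    windows: list[tuple[float, float, float]],
    freq_hz: float,
    dur_range_ms: tuple[float, float],
    snr_sd: float,
    rng: np.random.Generator,
    snr_jitter: float,
    min_gap_s: float,
    max_retries: int,
    params: RippleParams,
) -> tuple[tuple[np.ndarray, np.ndarray], list[tuple[float, float, float, float]]]:
    a, b = (np.array(trace_pair[0], dtype=float), np.array(trace_pair[1], dtype=float))
    if a.shape != b.shape:
        raise ValueError("trace pair length mismatch")
    if freq_hz >= fs_hz / 2:
        raise ValueError("ripple frequency at or above Nyquist")

    def env_sd(diff: np.ndarray) -> float:
        filt = bandpass_ripple(diff, fs_hz, params)
        return float(np.std(ripple_envelope(filt, fs_hz, params.smooth_ms)))

    baseline_sd = env_sd(a - b)
    if baseline_sd == 0:
        # silent background: calibrate against an arbitrary unit baseline
        baseline_sd = 1.0
    track, events = _place_bursts(
        a.size, fs_hz, windows, freq_hz, dur_range_ms, snr_sd, baseline_sd,
        rng, snr_jitter, min_gap_s, max_retries, params,
    )
    if events:
        # The detector normalises by the SD of the *event-containing*
        # envelope, which the bursts themselves inflate; rescale once so
        # the delivered peaks hit snr_sd in the detector's own units.
        inflated_sd = env_sd(a - b + track)
        k = np.sqrt(inflated_sd / baseline_sd)
        track *= k
        for ev in events:
            ev[3] *= k
    a += track / 2.0
    b -= track / 2.0
    return (a, b), [tuple(ev) for ev in events]


def inject_ripples(
    trace_pair: tuple[np.ndarray, np.ndarray],
    fs_hz: float,
    incidence_hz: float,
    freq_hz: float,
    dur_range_ms: tuple[float, float],
    snr_sd: float,
    rng: np.random.Generator,
    snr_jitter: float = 0.0,
    min_gap_s: float = 0.25,
    max_retries: int = 2000,
    params: RippleParams = RippleParams(),
) -> tuple[tuple[np.ndarray, np.ndarray], list[tuple[float, float, float, float]]]:
    """Add phase-reversed ripple bursts to a channel pair.

    Event count is Poisson(incidence × duration); start times are uniform
    with events redrawn on overlap (closer than ``min_gap_s``).  Burst
    amplitude is calibrated so the peak of the smoothed squared
    (detection) envelope of the *differential* burst reaches ``snr_sd``
    SDs of that envelope, measured with the events in place — the same
    normalisation the detector applies.  Each channel receives half the
    burst with opposite sign, so the differential carries the full
    amplitude while the common mode carries none.

    Returns the modified pair and a sorted event list of
    ``(start_s, end_s, freq_hz, amplitude)``.
    """
    if incidence_hz < 0:
        raise ValueError("incidence must be >= 0")
    a = np.asarray(trace_pair[0], dtype=float)
    if incidence_hz == 0:
        return (a.copy(), np.array(trace_pair[1], dtype=float)), []
    duration_s = a.size / fs_hz
    return _inject_windows(
        trace_pair, fs_hz, [(0.0, duration_s, incidence_hz)], freq_hz,
        dur_range_ms, snr_sd, rng, snr_jitter, min_gap_s, max_retries, params,
    )


def _common_artifact_waveform(fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """A large, slow movement transient (Gaussian-windowed 3 Hz wiggle)."""
    dur_s = 0.3
    n = int(round(dur_s * fs_hz))
    t = np.arange(n) / fs_hz - dur_s / 2
    return 800.0 * np.sin(2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi)) * np.exp(
        -(t**2) / (2 * (dur_s / 6) ** 2)
    )


def generate_session(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Build one annotated session plus its complete ground truth.

    Construction: each epoch's *local* (phase-reversed) content — 1/f
    background, theta, gamma, ripples — is split ±half between the two LFP
    channels, while a second, independent 1/f process plus movement
    transients is added identically to both (common mode).  The
    differential therefore recovers exactly the local content, and common
    artifacts cancel by construction.

    Deterministic: the single seed is expanded into independent
    per-component substreams, so identical configs give byte-identical
    output.
    """
    fs = config.fs_hz
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["common", "local", "theta", "gamma", "ripples", "emg", "artifact"],
            ss.spawn(7),
        )
    }

    local_segs: list[np.ndarray] = []
    common_segs: list[np.ndarray] = []
    annotations: list[dict] = []
    spectral_params: dict[str, dict] = {}
    epoch_bounds: list[tuple[float, float, str]] = []
    t0 = 0.0
    for label, dur in config.epoch_plan:
        cond = config.conditions[label]
        offset = (
            cond.aperiodic_offset
            if cond.aperiodic_offset is not None
            else config.aperiodic_offset
        )
        local = generate_aperiodic(
            config.aperiodic_exponent, offset, dur, fs, streams["local"]
        )
        local += generate_oscillation(
            cond.theta, config.aperiodic_exponent, offset, dur, fs, streams["theta"]
        )
        local += generate_oscillation(
            cond.gamma, config.aperiodic_exponent, offset, dur, fs, streams["gamma"]
        )
        common = generate_aperiodic(
            config.aperiodic_exponent, offset, dur, fs, streams["common"]
        )
        local_segs.append(local)
        common_segs.append(common)
        annotations.append(
            {
                "label": f"sleep-{label}",
                "start_s": t0,
                "end_s": t0 + dur,
                "laser": 1 if label == "on" else 0,
            }
        )
        epoch_bounds.append((t0, t0 + dur, label))
        spectral_params.setdefault(
            label,
            {
                "aperiodic_exponent": config.aperiodic_exponent,
                "aperiodic_offset": offset,
                "theta": asdict(cond.theta),
                "gamma": asdict(cond.gamma),
                "ripple_incidence_hz": cond.ripple_incidence_hz,
            },
        )
        t0 += dur

    local = np.concatenate(local_segs)
    common = np.concatenate(common_segs)
    a = common + local / 2.0
    b = common - local / 2.0

    # Ripples at each epoch's incidence, injected in one session-level pass
    # so amplitude calibration is in the detector's (session-SD) units.
    windows = [
        (start_s, end_s, config.conditions[label].ripple_incidence_hz)
        for start_s, end_s, label in epoch_bounds
    ]
    (a, b), ripple_times = _inject_windows(
        (a, b),
        fs,
        windows,
        config.ripple_freq_hz,
        config.ripple_dur_ms_range,
        config.ripple_snr_sd,
        streams["ripples"],
        snr_jitter=config.ripple_snr_jitter,
        min_gap_s=0.25,
        max_retries=2000,
        params=RippleParams(),
    )

    duration_s = config.duration_s
    n = a.size

    # Common-mode movement transients, identical on both LFP channels.
    rng_art = streams["artifact"]
    n_common = int(rng_art.poisson(config.common_artifact_rate_hz * duration_s))
    common_times = sorted(rng_art.uniform(0.3, duration_s - 0.3, size=n_common))
    for tc in common_times:
        wave = _common_artifact_waveform(fs, rng_art)
        i0 = int(round((tc - 0.15) * fs))
        seg = slice(max(0, i0), min(n, i0 + wave.size))
        a[seg] += wave[: seg.stop - seg.start]
        b[seg] += wave[: seg.stop - seg.start]

    # EMG: smooth low-amplitude baseline plus broadband bursts at its own
    # Poisson times and at every movement-artifact time.
    rng_emg = streams["emg"]
    if config.emg_baseline_sd > 0:
        base = rng_emg.standard_normal(n)
        sos = signal.butter(4, 20.0, btype="low", fs=fs, output="sos")
        base = signal.sosfiltfilt(sos, base)
        emg = base / base.std() * config.emg_baseline_sd
    else:
        emg = np.zeros(n)
    n_emg = int(rng_emg.poisson(config.emg_artifact_rate_hz * duration_s))
    emg_times = sorted(
        list(rng_emg.uniform(0.2, duration_s - 0.2, size=n_emg)) + list(common_times)
    )
    burst_n = int(round(0.2 * fs))
    burst_env = signal.windows.tukey(burst_n, alpha=0.5)
    for tc in emg_times:
        i0 = int(round((tc - 0.1) * fs))
        seg = slice(max(0, i0), min(n, i0 + burst_n))
        emg[seg] += (
            50.0
            * config.emg_baseline_sd
            * burst_env[: seg.stop - seg.start]
            * rng_emg.standard_normal(seg.stop - seg.start)
        )

    rec = Recording(
        channels={"ca1_a": a, "ca1_b": b},
        emg=emg,
        fs_hz=fs,
        annotations=annotations,
    )
    truth = GroundTruth(
        ripple_times=ripple_times,
        emg_burst_times=list(emg_times),
        common_artifact_times=list(common_times),
        spectral_params=spectral_params,
        duration_s=duration_s,
    )
    return rec, truth
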