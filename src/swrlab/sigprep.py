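"""Differential LFP construction, resampling, and EMG-based artifact masking.

The recordings this package targets come from paired "staggered" wire
electrodes in CA1: two closely spaced tips at different depths whose
difference cancels common-mode (volume-conducted and movement) signal and
enhances locally generated, phase-reversed events such as theta, gamma and
ripples.  Muscle/movement noise is flagged from a separately recorded EMG
channel and excised from all detection statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "ArtifactMask",
    "differential_signal",
    "resample",
    "detect_emg_artifacts",
    "apply_mask",
    "mask_to_bool",
]

ANALYSIS_FS_HZ = 1250.0


@dataclass
class Recording:
    """A multi-channel extracellular recording plus annotations.

    Parameters
    ----------
    channels
        Mapping of channel name to voltage trace (µV), all equal length.
    emg
        EMG voltage trace, same length and rate as the LFP channels.
    fs_hz
        Sampling rate in samples/s.
    annotations
        Labelled intervals: list of dicts with at least
        ``{"label", "start_s", "end_s"}``; epoch annotations additionally
        carry ``"laser"`` (0/1).
    """

    channels: dict[str, np.ndarray]
    emg: np.ndarray
    fs_hz: float
    annotations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        lengths = {name: len(tr) for name, tr in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch: {lengths}")
        if self.channels and len(self.emg) != next(iter(lengths.values())):
            raise ValueError("EMG length differs from LFP channels")
        span = self.duration_s
        for ann in self.annotations:
            if not (0.0 <= ann["start_s"] <= ann["end_s"] <= span + 1e-9):
                raise ValueError(f"annotation outside recording span: {ann}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class ArtifactMask:
    """Sorted, merged list of noise intervals in session seconds."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.intervals = _merge_intervals(self.intervals)

    @property
    def total_masked_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return any(s < end_s and start_s < e for s, e in self.intervals)


def _merge_intervals(
    intervals: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for s, e in sorted((float(s), float(e)) for s, e in intervals):
        if e < s:
            raise ValueError(f"interval end before start: ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def differential_signal(chan_a: np.ndarray, chan_b: np.ndarray) -> np.ndarray:
    """Elementwise ``chan_a - chan_b``.

    Subtraction of the paired staggered electrodes cancels synchronous
    (common-mode) changes such as movement artifacts and enhances locally
    generated phase-reversed signals.
    """
    chan_a = np.asarray(chan_a, dtype=float)
    chan_b = np.asarray(chan_b, dtype=float)
    if chan_a.shape != chan_b.shape:
        raise ValueError(
            f"channel length mismatch: {chan_a.shape} vs {chan_b.shape}"
        )
    return chan_a - chan_b


def resample(
    trace: np.ndarray, fs_in: float, fs_out: float = ANALYSIS_FS_HZ
) -> np.ndarray:
    """Anti-aliased polyphase resampling to the analysis rate (down only).

    Identity when ``fs_in == fs_out``.  Raises ``ValueError`` for
    upsampling requests: the analysis rate is a floor, not a target to
    interpolate toward.
    """
    if fs_out > fs_in:
        raise ValueError(f"fs_out ({fs_out}) must not exceed fs_in ({fs_in})")
    trace = np.asarray(trace, dtype=float)
    if fs_out == fs_in:
        return trace.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    # Sharper anti-alias FIR than resample_poly's default: cut just below
    # the output Nyquist with a narrow transition so content above fs_out/2
    # cannot fold back into the analysis band.
    numtaps = 64 * max(up, down) + 1
    h = signal.firwin(numtaps, 0.92 * fs_out / 2.0, fs=fs_in * up)
    return signal.resample_poly(trace, up, down, window=h)


def detect_emg_artifacts(
    emg: np.ndarray,
    fs_hz: float,
    sd_threshold: float = 2.0,
    window_ms: float = 500.0,
    robust: bool = False,
) -> ArtifactMask:
    """Flag muscle/movement noise from sample-to-sample EMG changes.

    The first difference of the EMG is thresholded at ``sd_threshold``
    standard deviations of the first difference (computed over the whole
    session; ``robust=True`` uses 1.4826×MAD instead).  Every
    suprathreshold change masks a ``window_ms`` window centred on it;
    overlapping windows are merged.

    A constant EMG (zero SD) yields an empty mask: with no variability
    there is nothing to threshold against.
    """
    emg = np.asarray(emg, dtype=float)
    if emg.size < 2:
        raise ValueError("EMG trace must have at least 2 samples")
    diff = np.diff(emg)
    if robust:
        sd = 1.4826 * np.median(np.abs(diff - np.median(diff)))
    else:
        sd = float(np.std(diff))
    if sd == 0.0:
        return ArtifactMask([])
    # diff[i] is the change landing on sample i+1
    idx = np.nonzero(np.abs(diff) > sd_threshold * sd)[0]
    half = window_ms / 2000.0
    t = (idx + 1) / fs_hz
    span = emg.size / fs_hz
    intervals = [(max(0.0, ti - half), min(span, ti + half)) for ti in t]
    return ArtifactMask(intervals)


def mask_to_bool(mask: ArtifactMask, n_samples: int, fs_hz: float) -> np.ndarray:
    """Boolean per-sample view of a mask (True = masked)."""
    out = np.zeros(n_samples, dtype=bool)
    for s, e in mask.intervals:
        i0 = max(0, int(np.floor(s * fs_hz)))
        i1 = min(n_samples, int(np.ceil(e * fs_hz)))
        out[i0:i1] = True
    return out


def apply_mask(
    trace: np.ndarray, mask: ArtifactMask, fs_hz: float
) -> tuple[np.ndarray, float]:
    """Excise masked samples; return the clean trace and its duration.

    The returned trace concatenates the artifact-free samples (their
    session times are *not* preserved — use the boolean view for
    time-resolved work).  Raises if masking removes everything, since
    downstream rates would be undefined.
    """
    trace = np.asarray(trace, dtype=float)
    keep = ~mask_to_bool(mask, trace.size, fs_hz)
    clean_duration_s = float(keep.sum()) / fs_hz
    if keep.sum() == 0:
        raise ValueError("mask covers the entire trace; no clean baseline")
    return trace[keep], clean_duration_s
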