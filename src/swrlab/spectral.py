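"""Power spectra and their periodic/aperiodic decomposition.

A PSD of hippocampal LFP is modelled, on log-log axes, as a straight
aperiodic line (the 1/f-like "pink" background, parameterised by offset and
exponent) plus narrowband Gaussian peaks sitting above it.  Oscillatory
power is then quantified *relative* to the background: the height of a
fitted peak above the aperiodic line, rather than raw band power, so that
broadband power shifts do not masquerade as oscillation changes.

The aperiodic component is fitted separately in two frequency ranges,
3–15 Hz and 15–150 Hz, which keeps the straight-line (no-knee) model
accurate; theta (5–12 Hz) metrics come from the low-range fit and slow
gamma (25–45 Hz) from the high-range fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "PsdEstimate",
    "GaussianPeak",
    "SpectralFit",
    "BandPeak",
    "BandChange",
    "THETA_BAND_HZ",
    "SLOW_GAMMA_BAND_HZ",
    "LOW_FIT_RANGE_HZ",
    "HIGH_FIT_RANGE_HZ",
    "welch_psd",
    "fit_spectral_model",
    "band_peak",
    "aperiodic_auc",
    "psd_band_difference",
    "spectrogram_z",
]

THETA_BAND_HZ = (5.0, 12.0)
SLOW_GAMMA_BAND_HZ = (25.0, 45.0)
LOW_FIT_RANGE_HZ = (3.0, 15.0)
HIGH_FIT_RANGE_HZ = (15.0, 150.0)

# Comparison bands for off/on PSD differences: theta, its flanks, slow
# gamma, and a high-frequency reference band.
DEFAULT_DIFF_BANDS_HZ = {
    "2-5": (2.0, 5.0),
    "theta": THETA_BAND_HZ,
    "12-15": (12.0, 15.0),
    "slow_gamma": SLOW_GAMMA_BAND_HZ,
    "90-110": (90.0, 110.0),
}


@dataclass
class PsdEstimate:
    freqs_hz: np.ndarray
    power: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD values must be non-negative")


@dataclass(frozen=True)
class GaussianPeak:
    """A narrowband peak above the aperiodic line, in log10-power units."""

    center_hz: float
    height_log10: float
    bandwidth_hz: float  # 2 sigma of the Gaussian, in Hz

    @property
    def rel_power_linear(self) -> float:
        """Peak height as a linear power ratio above the background."""
        return float(10.0**self.height_log10)


@dataclass
class SpectralFit:
    fit_range_hz: tuple[float, float]
    aperiodic_offset: float
    aperiodic_exponent: float
    peaks: list[GaussianPeak]
    fit_error: float
    freqs_hz: np.ndarray = field(repr=False)

    def aperiodic_log10(self, freqs_hz: np.ndarray) -> np.ndarray:
        """The fitted straight line, evaluated in log10 power units."""
        return self.aperiodic_offset - self.aperiodic_exponent * np.log10(freqs_hz)

    def model_log10(self, freqs_hz: np.ndarray) -> np.ndarray:
        out = self.aperiodic_log10(freqs_hz)
        for pk in self.peaks:
            sigma = pk.bandwidth_hz / 2.0
            out = out + pk.height_log10 * np.exp(
                -((freqs_hz - pk.center_hz) ** 2) / (2 * sigma**2)
            )
        return out


@dataclass
class BandPeak:
    band_hz: tuple[float, float]
    present: bool
    rel_power: float | None = None  # log10 height above the aperiodic line
    peak_freq_hz: float | None = None

    @property
    def rel_power_linear(self) -> float | None:
        return None if self.rel_power is None else float(10.0**self.rel_power)


@dataclass
class BandChange:
    band_hz: tuple[float, float]
    max_abs_change: float  # |Δ log10 power| at the band's signed extremum
    sign: int


def welch_psd(
    trace: np.ndarray,
    fs_hz: float,
    window_s: float = 0.5,
    overlap_s: float = 0.25,
    fmin: float = 1.0,
    fmax: float = 200.0,
) -> PsdEstimate:
    """Welch PSD with 0.5 s windows and 0.25 s overlap, 1–200 Hz grid.

    Segments are zero-padded to the next power of two (at least 256), so
    the grid is interpolated somewhat below the 1/window_s resolution.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_s * fs_hz))
    noverlap = int(round(overlap_s * fs_hz))
    if trace.size < nperseg:
        raise ValueError(
            f"trace ({trace.size} samples) shorter than one Welch window ({nperseg})"
        )
    nfft = max(256, int(2 ** np.ceil(np.log2(nperseg))))
    freqs, power = signal.welch(
        trace, fs=fs_hz, nperseg=nperseg, noverlap=noverlap, nfft=nfft
    )
    keep = (freqs >= fmin) & (freqs <= fmax)
    n_segments = 1 + (trace.size - nperseg) // (nperseg - noverlap)
    return PsdEstimate(freqs[keep], power[keep], n_segments)


def _gaussian(f, center, height, sigma):
    return height * np.exp(-((f - center) ** 2) / (2 * sigma**2))


def _robust_line_fit(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    # Peaks only bias residuals upward, so iteratively drop points that sit
    # far above the current line and refit.
    keep = np.ones_like(log_f, dtype=bool)
    slope, intercept = np.polyfit(log_f, log_p, 1)
    for _ in range(3):
        resid = log_p - (intercept + slope * log_f)
        sd = resid[keep].std()
        if sd == 0:
            break
        keep = resid < 1.0 * sd
        if keep.sum() < 3:
            break
        slope, intercept = np.polyfit(log_f[keep], log_p[keep], 1)
    return float(intercept), float(-slope)


def fit_spectral_model(
    psd: PsdEstimate,
    fit_range_hz: tuple[float, float],
    max_n_peaks: int = 6,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.1,
    bandwidth_limits_hz: tuple[float, float] = (1.0, 12.0),
) -> SpectralFit:
    """Decompose a PSD into an aperiodic line plus Gaussian peaks.

    Procedure: (1) robust straight-line fit to log10(power) against
    log10(frequency), iteratively down-weighting points that sit far above
    the line (peaks only bias upward); (2) Gaussian peaks extracted
    greedily from the residual — each candidate must rise above
    ``peak_threshold_sd`` residual SDs and ``min_peak_height`` log10 units;
    (3) a bounded joint refit of line + all Gaussians, which re-estimates
    the aperiodic component with the peaks accounted for.

    ``fit_error`` is the RMS of (model − log10 PSD) over the fit range.
    """
    lo, hi = fit_range_hz
    sel = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    freqs = psd.freqs_hz[sel]
    power = psd.power[sel]
    if freqs.size < 4:
        raise ValueError(f"PSD does not cover fit range {fit_range_hz}")
    if np.any(~np.isfinite(power)) or np.any(power <= 0):
        raise ValueError("PSD must be finite and positive within the fit range")
    log_f = np.log10(freqs)
    log_p = np.log10(power)

    offset, exponent = _robust_line_fit(log_f, log_p)
    sig_lo, sig_hi = bandwidth_limits_hz[0] / 2.0, bandwidth_limits_hz[1] / 2.0

    # Greedy peak extraction from the flattened spectrum.  A candidate
    # landing within 2.5 sigma of an already-accepted guess is treated as a
    # residue of the same bump (subtracted but not added), so one physical
    # peak yields one Gaussian rather than a tiling of narrow ones.
    flat = log_p - (offset - exponent * log_f)
    guesses: list[tuple[float, float, float]] = []
    for _ in range(2 * max_n_peaks):
        if len(guesses) >= max_n_peaks:
            break
        i = int(np.argmax(flat))
        height = flat[i]
        if height <= max(peak_threshold_sd * flat.std(), min_peak_height):
            break
        # half-height width -> sigma guess
        half = height / 2.0
        j_hi = i
        while j_hi + 1 < flat.size and flat[j_hi + 1] > half:
            j_hi += 1
        j_lo = i
        while j_lo - 1 >= 0 and flat[j_lo - 1] > half:
            j_lo -= 1
        fwhm = max(freqs[j_hi] - freqs[j_lo], 1e-3)
        sigma = float(np.clip(fwhm / 2.355, sig_lo, sig_hi))
        center = float(freqs[i])
        flat = flat - _gaussian(freqs, center, height, sigma)
        if all(abs(center - c) > 2.5 * max(s, sigma) for c, _, s in guesses):
            guesses.append((center, float(height), sigma))

    peaks: list[GaussianPeak] = []
    if guesses:
        max_h = max(h for _, h, _ in guesses)

        def full_model(f, off, exp, *p):
            out = off - exp * np.log10(f)
            for k in range(0, len(p), 3):
                out = out + _gaussian(f, p[k], p[k + 1], p[k + 2])
            return out

        p0 = [offset, exponent]
        lb = [-np.inf, -2.0]
        ub = [np.inf, 8.0]
        for c, h, s in guesses:
            p0 += [c, h, s]
            lb += [max(lo, c - 1.5 * s), 0.0, sig_lo]
            ub += [min(hi, c + 1.5 * s), 3.0 * max_h, sig_hi]
        try:
            popt, _ = curve_fit(
                full_model, freqs, log_p, p0=p0, bounds=(lb, ub), maxfev=5000
            )
        except RuntimeError:
            popt = np.array(p0)
        offset, exponent = float(popt[0]), float(popt[1])
        for k in range(2, len(popt), 3):
            peaks.append(
                GaussianPeak(
                    center_hz=float(popt[k]),
                    height_log10=float(popt[k + 1]),
                    bandwidth_hz=float(2 * popt[k + 2]),
                )
            )
        peaks.sort(key=lambda pk: pk.center_hz)

    fit = SpectralFit(
        fit_range_hz=fit_range_hz,
        aperiodic_offset=offset,
        aperiodic_exponent=exponent,
        peaks=peaks,
        fit_error=0.0,
        freqs_hz=freqs,
    )
    fit.fit_error = float(np.sqrt(np.mean((fit.model_log10(freqs) - log_p) ** 2)))
    return fit


def band_peak(fit: SpectralFit, band_hz: tuple[float, float]) -> BandPeak:
    """The largest fitted peak whose centre falls inside ``band_hz``.

    Relative power is the Gaussian height above the aperiodic line (log10
    units; ``rel_power_linear`` gives the linear ratio), which is invariant
    to overall power scaling of the PSD.
    """
    lo, hi = band_hz
    in_band = [pk for pk in fit.peaks if lo <= pk.center_hz <= hi]
    if not in_band:
        return BandPeak(band_hz=band_hz, present=False)
    best = max(in_band, key=lambda pk: pk.height_log10)
    return BandPeak(
        band_hz=band_hz,
        present=True,
        rel_power=best.height_log10,
        peak_freq_hz=best.center_hz,
    )


def aperiodic_auc(fit: SpectralFit) -> float:
    """Area under the fitted aperiodic line on log10–log10 axes.

    Because the integrand is a straight line in log10(frequency), the
    trapezoid rule is exact for any grid.
    """
    log_f = np.log10(fit.freqs_hz)
    return float(np.trapezoid(fit.aperiodic_log10(fit.freqs_hz), log_f))


def psd_band_difference(
    psd_off: PsdEstimate,
    psd_on: PsdEstimate,
    bands_hz: dict[str, tuple[float, float]] | None = None,
) -> dict[str, BandChange]:
    """Signed extremum of the log-power difference (on − off) per band."""
    if bands_hz is None:
        bands_hz = DEFAULT_DIFF_BANDS_HZ
    if psd_off.freqs_hz.shape != psd_on.freqs_hz.shape or np.any(
        psd_off.freqs_hz != psd_on.freqs_hz
    ):
        raise ValueError("PSD frequency grids differ")
    with np.errstate(divide="ignore"):
        delta = np.log10(psd_on.power) - np.log10(psd_off.power)
    out: dict[str, BandChange] = {}
    for name, (lo, hi) in bands_hz.items():
        sel = (psd_off.freqs_hz >= lo) & (psd_off.freqs_hz <= hi)
        if not sel.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside PSD range")
        d = delta[sel]
        i = int(np.argmax(np.abs(d)))
        out[name] = BandChange(
            band_hz=(lo, hi),
            max_abs_change=float(abs(d[i])),
            sign=int(np.sign(d[i])) if d[i] != 0 else 0,
        )
    return out


def spectrogram_z(
    trace: np.ndarray,
    fs_hz: float,
    fmin: float = 1.0,
    fmax: float = 200.0,
    voices_per_octave: int = 10,
    omega0: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet CWT magnitude, z-scored per frequency row.

    Frequencies follow a logarithmic grid (``voices_per_octave`` scales per
    doubling).  Z-scoring each row over time shows relative power changes
    across frequencies with very different absolute power.  Rows with zero
    variance (e.g. an all-zero trace) come back as NaN.

    Returns ``(freqs_hz, z)`` with ``z`` shaped (n_freqs, n_samples).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    n_octaves = np.log2(fmax / fmin)
    n_freqs = int(np.ceil(n_octaves * voices_per_octave)) + 1
    freqs = fmin * 2 ** (np.linspace(0, n_octaves, n_freqs))
    # Complex Morlet with center frequency omega0/(2*pi) cycles and unit
    # Gaussian envelope (pywt's cmorB-C: exp(-t^2/B) * exp(2j*pi*C*t)).
    wavelet = f"cmor2.0-{omega0 / (2 * np.pi):.6f}"
    scales = pywt.frequency2scale(wavelet, freqs / fs_hz)
    coefs, _ = pywt.cwt(trace, scales, wavelet, sampling_period=1.0 / fs_hz)
    mag = np.abs(coefs)
    mu = mag.mean(axis=1, keepdims=True)
    sd = mag.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mag - mu) / sd, np.nan)
    return freqs, z
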