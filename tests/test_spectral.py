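import numpy as np
import pytest

from swrlab import synth
from swrlab.spectral import (
    HIGH_FIT_RANGE_HZ,
    LOW_FIT_RANGE_HZ,
    SLOW_GAMMA_BAND_HZ,
    THETA_BAND_HZ,
    BandPeak,
    GaussianPeak,
    PsdEstimate,
    SpectralFit,
    aperiodic_auc,
    band_peak,
    fit_spectral_model,
    psd_band_difference,
    spectrogram_z,
    welch_psd,
)

FS = 1250.0


def synthetic_psd(offset, exponent, peaks=(), fmin=1.0, fmax=200.0, n=400):
    """Noise-free PSD constructed directly from the model equation —
    the closed-form oracle for the decomposition."""
    freqs = np.linspace(fmin, fmax, n)
    log_p = offset - exponent * np.log10(freqs)
    for c, h, sigma in peaks:
        log_p = log_p + h * np.exp(-((freqs - c) ** 2) / (2 * sigma**2))
    return PsdEstimate(freqs, 10.0**log_p, n_segments=1)


class TestWelch:
    def test_sine_peak_location(self):
        t = np.arange(int(30 * FS)) / FS
        psd = welch_psd(np.sin(2 * np.pi * 8 * t), FS)
        assert psd.freqs_hz[np.argmax(psd.power)] == pytest.approx(8.0, abs=2.0)

    def test_white_noise_parseval(self, rng):
        x = 2.5 * rng.standard_normal(int(120 * FS))
        psd = welch_psd(x, FS, fmin=0.0, fmax=FS / 2)
        total = np.trapezoid(psd.power, psd.freqs_hz)
        assert total == pytest.approx(2.5**2, rel=0.05)

    def test_zero_trace_zero_psd(self):
        psd = welch_psd(np.zeros(int(5 * FS)), FS)
        assert np.all(psd.power == 0)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter than one Welch window"):
            welch_psd(np.zeros(100), FS)


class TestFit:
    def test_pure_line_recovered_exactly(self):
        psd = synthetic_psd(2.0, 1.0)
        fit = fit_spectral_model(psd, HIGH_FIT_RANGE_HZ)
        assert fit.aperiodic_exponent == pytest.approx(1.0, abs=1e-6)
        assert fit.aperiodic_offset == pytest.approx(2.0, abs=1e-6)
        assert fit.peaks == []
        assert fit.fit_error < 1e-9

    def test_flat_spectrum_zero_exponent(self):
        psd = synthetic_psd(1.5, 0.0)
        fit = fit_spectral_model(psd, LOW_FIT_RANGE_HZ)
        assert fit.aperiodic_exponent == pytest.approx(0.0, abs=1e-6)

    def test_single_bump_recovered(self):
        psd = synthetic_psd(2.0, 1.0, peaks=[(8.0, 1.2, 1.0)])
        fit = fit_spectral_model(psd, LOW_FIT_RANGE_HZ, max_n_peaks=3)
        assert len(fit.peaks) == 1
        assert fit.peaks[0].center_hz == pytest.approx(8.0, abs=0.25)
        assert fit.peaks[0].height_log10 == pytest.approx(1.2, abs=0.1)
        assert fit.aperiodic_exponent == pytest.approx(1.0, abs=0.05)

    def test_two_bumps_two_ranges(self):
        psd = synthetic_psd(2.0, 1.0, peaks=[(8.0, 1.2, 1.0), (35.0, 0.9, 2.0)])
        lo = fit_spectral_model(psd, LOW_FIT_RANGE_HZ, max_n_peaks=3)
        hi = fit_spectral_model(psd, HIGH_FIT_RANGE_HZ)
        assert band_peak(lo, THETA_BAND_HZ).peak_freq_hz == pytest.approx(8.0, abs=0.25)
        assert band_peak(hi, SLOW_GAMMA_BAND_HZ).peak_freq_hz == pytest.approx(
            35.0, abs=0.25
        )

    def test_generator_round_trip_exponent(self):
        """1/f traces from the generator come back with the configured
        exponent within ±0.1 and no spurious peaks dominating theta."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            trace = synth.generate_aperiodic(1.0, 2.0, 120.0, FS, r)
            fit = fit_spectral_model(welch_psd(trace, FS), HIGH_FIT_RANGE_HZ)
            assert fit.aperiodic_exponent == pytest.approx(1.0, abs=0.1)

    def test_generator_round_trip_theta_center(self):
        errs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            trace = synth.generate_aperiodic(1.0, 2.0, 120.0, FS, r)
            trace += synth.generate_oscillation(
                synth.OscillationSpec(7.7, 1.4, 0.75), 1.0, 2.0, 120.0, FS, r
            )
            fit = fit_spectral_model(welch_psd(trace, FS), LOW_FIT_RANGE_HZ, max_n_peaks=3)
            pk = band_peak(fit, THETA_BAND_HZ)
            assert pk.present
            errs.append(pk.peak_freq_hz - 7.7)
        assert abs(np.mean(errs)) < 0.25

    def test_nonfinite_psd_rejected(self):
        psd = synthetic_psd(2.0, 1.0)
        psd.power[50] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_spectral_model(psd, HIGH_FIT_RANGE_HZ)


class TestBandPeak:
    def _fit(self, peaks):
        return SpectralFit(
            fit_range_hz=(3.0, 150.0),
            aperiodic_offset=2.0,
            aperiodic_exponent=1.0,
            peaks=peaks,
            fit_error=0.0,
            freqs_hz=np.linspace(3, 150, 100),
        )

    def test_selects_largest_in_band(self):
        fit = self._fit(
            [GaussianPeak(8.0, 1.0, 2.0), GaussianPeak(10.0, 0.4, 2.0),
             GaussianPeak(38.0, 1.5, 3.0)]
        )
        pk = band_peak(fit, THETA_BAND_HZ)
        assert pk.present and pk.peak_freq_hz == 8.0 and pk.rel_power == 1.0

    def test_absent_when_no_peak_in_band(self):
        pk = band_peak(self._fit([]), THETA_BAND_HZ)
        assert not pk.present
        assert pk.rel_power is None and pk.peak_freq_hz is None

    def test_scaling_invariance(self):
        """Multiplying the PSD by a constant moves the offset, not the
        relative peak height."""
        psd1 = synthetic_psd(2.0, 1.0, peaks=[(8.0, 1.2, 1.0)])
        psd2 = PsdEstimate(psd1.freqs_hz, 10.0 * psd1.power, 1)
        f1 = fit_spectral_model(psd1, LOW_FIT_RANGE_HZ, max_n_peaks=3)
        f2 = fit_spectral_model(psd2, LOW_FIT_RANGE_HZ, max_n_peaks=3)
        p1, p2 = band_peak(f1, THETA_BAND_HZ), band_peak(f2, THETA_BAND_HZ)
        assert p2.rel_power == pytest.approx(p1.rel_power, abs=1e-6)
        assert f2.aperiodic_offset - f1.aperiodic_offset == pytest.approx(1.0, abs=1e-6)


class TestAperiodicAuc:
    def _line_fit(self, offset, exponent, lo=15.0, hi=150.0):
        return SpectralFit(
            fit_range_hz=(lo, hi),
            aperiodic_offset=offset,
            aperiodic_exponent=exponent,
            peaks=[],
            fit_error=0.0,
            freqs_hz=np.linspace(lo, hi, 68),
        )

    def test_zero_line_zero_auc(self):
        assert aperiodic_auc(self._line_fit(0.0, 0.0)) == 0.0

    def test_matches_closed_form(self):
        """AUC of y = c - e*x over x = log10(15)..log10(150) equals the
        analytic integral: c*(x1-x0) - e*(x1^2-x0^2)/2."""
        c, e = -5.5, 1.3
        x0, x1 = np.log10(15.0), np.log10(150.0)
        expected = c * (x1 - x0) - e * (x1**2 - x0**2) / 2
        assert aperiodic_auc(self._line_fit(c, e)) == pytest.approx(expected, abs=1e-9)

    def test_power_scaling_shifts_auc_by_log_bandwidth(self):
        a1 = aperiodic_auc(self._line_fit(2.0, 1.0))
        a2 = aperiodic_auc(self._line_fit(3.0, 1.0))  # 10x power
        assert a2 - a1 == pytest.approx(np.log10(150) - np.log10(15), abs=1e-12)


class TestBandDifference:
    def _psd(self, power):
        return PsdEstimate(np.arange(1.0, 201.0), power, 1)

    def test_identical_psds_zero_change(self):
        p = self._psd(100.0 / np.arange(1.0, 201.0))
        changes = psd_band_difference(p, p)
        assert all(c.max_abs_change == 0 for c in changes.values())

    def test_antisymmetry(self, rng):
        f = np.arange(1.0, 201.0)
        p1 = self._psd(100.0 / f * np.exp(rng.normal(0, 0.2, f.size)))
        p2 = self._psd(100.0 / f * np.exp(rng.normal(0, 0.2, f.size)))
        fwd = psd_band_difference(p1, p2)
        rev = psd_band_difference(p2, p1)
        for k in fwd:
            assert fwd[k].max_abs_change == pytest.approx(rev[k].max_abs_change)
            assert fwd[k].sign == -rev[k].sign

    def test_theta_sparing_smaller_than_flank_change(self):
        """Halving broadband power while sparing theta mirrors the
        stimulated-sleep signature: the theta-band change is smaller than
        the 12-15 Hz flank change."""
        f = np.arange(1.0, 201.0)
        off = 100.0 / f
        on = off / 2.0
        theta = (f >= 5) & (f <= 12)
        on[theta] = off[theta]
        changes = psd_band_difference(self._psd(off), self._psd(on))
        assert changes["theta"].max_abs_change < changes["12-15"].max_abs_change
        assert changes["12-15"].sign == -1

    def test_single_bin_spike_localized_to_gamma(self):
        f = np.arange(1.0, 201.0)
        off = 100.0 / f
        on = off.copy()
        on[f == 35] *= 5.0
        changes = psd_band_difference(self._psd(off), self._psd(on))
        assert changes["slow_gamma"].max_abs_change == pytest.approx(np.log10(5))
        assert changes["slow_gamma"].sign == 1
        for k in ("2-5", "theta", "12-15", "90-110"):
            assert changes[k].max_abs_change == 0

    def test_grid_mismatch_rejected(self):
        p1 = self._psd(np.ones(200))
        p2 = PsdEstimate(np.arange(2.0, 202.0), np.ones(200), 1)
        with pytest.raises(ValueError, match="grids differ"):
            psd_band_difference(p1, p2)


class TestSpectrogram:
    def test_stationary_sine_flat_row(self):
        t = np.arange(int(4 * FS)) / FS
        freqs, z = spectrogram_z(np.sin(2 * np.pi * 40 * t), FS)
        row = z[np.argmin(np.abs(freqs - 40.0))]
        core = row[int(0.5 * FS) : -int(0.5 * FS)]
        assert np.abs(core).max() < 1.0  # constant magnitude -> small z

    def test_burst_gives_positive_z_at_burst_time(self, rng):
        n = int(8 * FS)
        x = 0.1 * rng.standard_normal(n)
        w = synth._burst_waveform(170.0, 0.05, FS, 0.0)
        i0 = n // 2
        x[i0 : i0 + w.size] += 5.0 * w
        freqs, z = spectrogram_z(x, FS)
        row = z[np.argmin(np.abs(freqs - 170.0))]
        assert row[i0 : i0 + w.size].max() > 3.0

    def test_zero_trace_flagged_nan(self):
        freqs, z = spectrogram_z(np.zeros(1000), FS)
        assert np.all(np.isnan(z))

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            spectrogram_z(np.array([]), FS)
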