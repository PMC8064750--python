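"""Decompose laser-off vs laser-on PSDs into 1/f background plus peaks.

Shows the two-range aperiodic fit (3-15 and 15-150 Hz), relative theta
and slow-gamma peaks, the aperiodic area under the curve (AUC), and the
off/on PSD band differences.
"""

import numpy as np

from swrlab import synth
from swrlab.sigprep import differential_signal
from swrlab.spectral import (
    HIGH_FIT_RANGE_HZ,
    LOW_FIT_RANGE_HZ,
    SLOW_GAMMA_BAND_HZ,
    THETA_BAND_HZ,
    aperiodic_auc,
    band_peak,
    fit_spectral_model,
    psd_band_difference,
    welch_psd,
)

rec, truth = synth.generate_session(synth.SimConfig(seed=3))
diff = differential_signal(rec.channels["ca1_a"], rec.channels["ca1_b"])
fs = rec.fs_hz

psds = {}
for lab, laser in (("off", 0), ("on", 1)):
    segs = [
        diff[int(a["start_s"] * fs) : int(a["end_s"] * fs)]
        for a in rec.annotations
        if a["laser"] == laser
    ]
    psds[lab] = welch_psd(np.concatenate(segs), fs)

for lab, psd in psds.items():
    lo = fit_spectral_model(psd, LOW_FIT_RANGE_HZ, max_n_peaks=3)
    hi = fit_spectral_model(psd, HIGH_FIT_RANGE_HZ)
    theta = band_peak(lo, THETA_BAND_HZ)
    gamma = band_peak(hi, SLOW_GAMMA_BAND_HZ)
    print(f"laser {lab}: 1/f exponent {hi.aperiodic_exponent:.2f}, "
          f"AUC(15-150) {aperiodic_auc(hi):.2f}")
    print(f"  theta peak {theta.peak_freq_hz:.2f} Hz, "
          f"relative power {theta.rel_power_linear:.1f}x background")
    print(f"  slow gamma peak {gamma.peak_freq_hz:.2f} Hz, "
          f"relative power {gamma.rel_power_linear:.1f}x background")

# The generator slows theta 7.7 -> 7.2 Hz and raises its relative power
# ~1.5x when the laser is on; the fits above should show both.
changes = psd_band_difference(psds["off"], psds["on"])
print("off->on log10 power change (signed extremum per band):")
for name, ch in changes.items():
    print(f"  {name:11s} {ch.sign * ch.max_abs_change:+.3f}")
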