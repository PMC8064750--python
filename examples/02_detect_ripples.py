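"""Detect sharp-wave ripples in a synthetic session and score recovery.

Pipeline stages shown: differential montage -> EMG artifact mask ->
Chebyshev bandpass -> envelope detection -> multitaper peak frequency and
SWR classification -> artifact exclusion -> incidence.
"""

import numpy as np

from swrlab import synth
from swrlab.ripples import (
    annotate_events,
    bandpass_ripple,
    detect_ripples,
    exclude_artifact_events,
    swr_incidence,
)
from swrlab.sigprep import detect_emg_artifacts, differential_signal

rec, truth = synth.generate_session(synth.SimConfig(seed=5))

diff = differential_signal(rec.channels["ca1_a"], rec.channels["ca1_b"])
mask = detect_emg_artifacts(rec.emg, rec.fs_hz)
filt = bandpass_ripple(diff, rec.fs_hz)
events = annotate_events(detect_ripples(filt, rec.fs_hz, mask=mask), diff, rec.fs_hz)
kept = exclude_artifact_events(events, mask)
swrs = [e for e in kept if e.is_swr]

clean_s = rec.duration_s - mask.total_masked_s
print(f"masked {mask.total_masked_s:.1f} s of {rec.duration_s:.0f} s "
      f"({len(mask.intervals)} artifact windows)")
print(f"candidates {len(events)}, after artifact exclusion {len(kept)}, "
      f"classified SWR (peak >= 140 Hz): {len(swrs)}")
print(f"overall SWR incidence: {swr_incidence(kept, clean_s):.3f} Hz")
print(f"SWR peak frequency {np.mean([e.peak_freq_hz for e in swrs]):.1f} Hz, "
      f"duration {np.mean([e.duration_ms for e in swrs]):.1f} ms")

clean_truth = [r for r in truth.ripple_times if not mask.overlaps(r[0], r[1])]
hits = sum(
    any(e.start_s < r[1] and r[0] < e.end_s for e in kept) for r in clean_truth
)
print(f"ground truth: {hits}/{len(clean_truth)} injected ripples recovered "
      f"(sensitivity {hits / len(clean_truth):.2f})")
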