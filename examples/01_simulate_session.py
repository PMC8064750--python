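"""Generate one ground-truthed synthetic sleep session and save it.

The default configuration mimics a sleep stimulation protocol: 30 s
laser-on epochs alternating with 30 s laser-off epochs, a 1/f background
(exponent 1), theta and slow-gamma bumps, ripple bursts at 0.21 Hz
(laser off) vs 0.03 Hz (laser on), plus EMG bursts and common-mode
movement transients.
"""

import numpy as np

from swrlab import io, synth

cfg = synth.SimConfig(epoch_plan=synth.sleep_epoch_plan(5), seed=1)
rec, truth = synth.generate_session(cfg)

print(f"session: {rec.duration_s:.0f} s at {rec.fs_hz:.0f} Hz, "
      f"channels {list(rec.channels)}, {len(rec.annotations)} epochs")
print(f"injected ripples: {len(truth.ripple_times)} "
      f"(mean duration {1000 * np.mean([e - s for s, e, *_ in truth.ripple_times]):.1f} ms "
      f"at {truth.ripple_times[0][2]:.0f} Hz)")
print(f"EMG bursts: {len(truth.emg_burst_times)}, "
      f"movement artifacts: {len(truth.common_artifact_times)}")

outdir = io.write_recording(rec, "scratch/example_session")
io.write_ground_truth(truth, outdir / "ground_truth.json")
print(f"written to {outdir}/ (float32 binary + JSON sidecar + ground truth)")

# The event list gives, per ripple, (start_s, end_s, freq_hz, amplitude):
# everything the detection stage should recover.
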