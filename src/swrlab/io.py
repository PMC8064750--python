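"""Plain, open on-disk containers for recordings and derived artifacts.

A recording is stored as a raw float32 channel-major binary plus a JSON
sidecar (channel names, sampling rate, annotations); events, masks and
epoch metrics as CSV; ground truth and fits as JSON.  Nothing proprietary,
everything re-readable with one numpy/pandas call.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ripples import RippleEvent
from .sigprep import ArtifactMask, Recording
from .synth import GroundTruth

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "events_to_frame",
    "write_events",
    "read_events",
    "write_mask",
    "read_mask",
]


def write_recording(rec: Recording, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(rec.channels) + ["emg"]
    data = np.stack([rec.channels[n] for n in rec.channels] + [rec.emg])
    data.astype(np.float32).tofile(outdir / "signals.bin")
    sidecar = {
        "channel_names": names,
        "fs_hz": rec.fs_hz,
        "n_samples": int(data.shape[1]),
        "dtype": "float32",
        "order": "channel-major",
        "annotations": rec.annotations,
    }
    (outdir / "recording.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_recording(indir: str | Path) -> Recording:
    indir = Path(indir)
    meta = json.loads((indir / "recording.json").read_text())
    data = np.fromfile(indir / "signals.bin", dtype=np.float32).reshape(
        len(meta["channel_names"]), meta["n_samples"]
    )
    names = meta["channel_names"]
    channels = {n: data[i].astype(float) for i, n in enumerate(names) if n != "emg"}
    emg = data[names.index("emg")].astype(float)
    return Recording(
        channels=channels, emg=emg, fs_hz=meta["fs_hz"], annotations=meta["annotations"]
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(truth), indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    d["ripple_times"] = [tuple(r) for r in d["ripple_times"]]
    return GroundTruth(**d)


def events_to_frame(events: list[RippleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": e.start_s,
                "end_s": e.end_s,
                "duration_ms": e.duration_ms,
                "peak_time_s": e.peak_time_s,
                "peak_sd_units": e.peak_sd_units,
                "peak_freq_hz": e.peak_freq_hz,
                "is_swr": e.is_swr,
                "artifact_overlap": e.artifact_overlap,
            }
            for e in events
        ]
    )


def write_events(events: list[RippleEvent], path: str | Path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[RippleEvent]:
    df = pd.read_csv(path)
    return [
        RippleEvent(
            start_s=r.start_s,
            end_s=r.end_s,
            peak_time_s=r.peak_time_s,
            peak_sd_units=r.peak_sd_units,
            peak_freq_hz=r.peak_freq_hz,
            is_swr=bool(r.is_swr),
            artifact_overlap=bool(r.artifact_overlap),
        )
        for r in df.itertuples()
    ]


def write_mask(mask: ArtifactMask, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(mask.intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False
    )
    return path


def read_mask(path: str | Path) -> ArtifactMask:
    df = pd.read_csv(path)
    return ArtifactMask([tuple(r) for r in df.to_numpy()])
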