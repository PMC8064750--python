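"""End-to-end orchestration: recording -> per-epoch metrics -> model fits.

``run_session`` takes one annotated recording through signal preparation
(differential montage, resampling, EMG artifact masking), ripple
detection/classification, and per-epoch spectral decomposition, and
returns a tidy epoch-metrics table.  ``summarize_offon`` pools such tables
across animals and fits the laser x group mixed model with post hoc
least-square means.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .ripples import (
    RippleEvent,
    RippleParams,
    annotate_events,
    bandpass_ripple,
    detect_ripples,
    exclude_artifact_events,
)
from .sigprep import (
    ANALYSIS_FS_HZ,
    ArtifactMask,
    Recording,
    detect_emg_artifacts,
    differential_signal,
    mask_to_bool,
    resample,
)
from .spectral import (
    HIGH_FIT_RANGE_HZ,
    LOW_FIT_RANGE_HZ,
    SLOW_GAMMA_BAND_HZ,
    THETA_BAND_HZ,
    aperiodic_auc,
    band_peak,
    fit_spectral_model,
    welch_psd,
)
from .stats import ModelFit, ModelSpec, PosthocResult, fit_lmm, posthoc_lsmeans

__all__ = ["run_session", "summarize_offon"]

_MIN_SPECTRAL_S = 0.5  # one Welch window


def run_session(
    recording: Recording,
    params: RippleParams = RippleParams(),
    annotations: list[dict] | None = None,
    channel_pair: tuple[str, str] | None = None,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[RippleEvent], ArtifactMask]:
    """Per-epoch SWR and spectral metrics for one session.

    Events are assigned to epochs by peak time; SWR incidence divides by
    the epoch's artifact-free (clean) duration.  Spectral metrics come
    from Welch PSDs of the artifact-excised epoch signal — epochs shorter
    than one Welch window yield NaN spectral columns, zero-length epochs
    are skipped with a warning.  Deterministic given inputs; pass
    ``outdir`` to persist events, mask and metrics as CSV.
    """
    if annotations is None:
        annotations = recording.annotations
    if channel_pair is None:
        lfp_names = list(recording.channels)
        if len(lfp_names) != 2:
            raise ValueError("channel_pair required when recording has != 2 channels")
        channel_pair = (lfp_names[0], lfp_names[1])

    fs = recording.fs_hz
    a = recording.channels[channel_pair[0]]
    b = recording.channels[channel_pair[1]]
    emg = recording.emg
    if fs != ANALYSIS_FS_HZ:
        a = resample(a, fs, ANALYSIS_FS_HZ)
        b = resample(b, fs, ANALYSIS_FS_HZ)
        emg = resample(emg, fs, ANALYSIS_FS_HZ)
        fs = ANALYSIS_FS_HZ

    diff = differential_signal(a, b)
    mask = detect_emg_artifacts(emg, fs)
    filt = bandpass_ripple(diff, fs, params)
    events = detect_ripples(filt, fs, params, mask=mask)
    events = annotate_events(events, diff, fs, params)
    kept = exclude_artifact_events(events, mask)

    masked = mask_to_bool(mask, diff.size, fs)
    rows = []
    for i, ann in enumerate(annotations):
        t0, t1 = float(ann["start_s"]), float(ann["end_s"])
        if t1 <= t0:
            warnings.warn(f"skipping zero-length epoch {ann}", stacklevel=2)
            continue
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        keep = ~masked[i0:i1]
        clean_s = float(keep.sum()) / fs
        in_epoch = [e for e in kept if t0 <= e.peak_time_s < t1]
        swrs = [e for e in in_epoch if e.is_swr]
        row = {
            "epoch_id": i,
            "label": ann.get("label", ""),
            "laser": int(ann.get("laser", 0)),
            "start_s": t0,
            "end_s": t1,
            "clean_duration_s": clean_s,
            "n_candidates": len(in_epoch),
            "swr_count": len(swrs),
            "swr_incidence_hz": len(swrs) / clean_s if clean_s > 0 else np.nan,
            "swr_peak_freq_hz": (
                float(np.mean([e.peak_freq_hz for e in swrs])) if swrs else np.nan
            ),
            "swr_duration_ms": (
                float(np.mean([e.duration_ms for e in swrs])) if swrs else np.nan
            ),
        }
        row.update(_spectral_metrics(diff[i0:i1][keep], fs, clean_s))
        rows.append(row)
    table = pd.DataFrame(rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_events(events, outdir / "events.csv")
        _io.write_mask(mask, outdir / "mask.csv")
        table.to_csv(outdir / "epoch_metrics.csv", index=False)
    return table, events, mask


def _spectral_metrics(clean_seg: np.ndarray, fs: float, clean_s: float) -> dict:
    nan_row = {
        "theta_present": False,
        "theta_freq_hz": np.nan,
        "theta_rel_power": np.nan,
        "gamma_present": False,
        "gamma_freq_hz": np.nan,
        "gamma_rel_power": np.nan,
        "auc_low": np.nan,
        "auc_high": np.nan,
        "aperiodic_exponent": np.nan,
    }
    if clean_s < _MIN_SPECTRAL_S:
        return nan_row
    psd = welch_psd(clean_seg, fs)
    try:
        fit_lo = fit_spectral_model(psd, LOW_FIT_RANGE_HZ, max_n_peaks=3)
        fit_hi = fit_spectral_model(psd, HIGH_FIT_RANGE_HZ)
    except ValueError:
        return nan_row
    theta = band_peak(fit_lo, THETA_BAND_HZ)
    gamma = band_peak(fit_hi, SLOW_GAMMA_BAND_HZ)
    return {
        "theta_present": theta.present,
        "theta_freq_hz": theta.peak_freq_hz if theta.present else np.nan,
        "theta_rel_power": theta.rel_power if theta.present else np.nan,
        "gamma_present": gamma.present,
        "gamma_freq_hz": gamma.peak_freq_hz if gamma.present else np.nan,
        "gamma_rel_power": gamma.rel_power if gamma.present else np.nan,
        "auc_low": aperiodic_auc(fit_lo),
        "auc_high": aperiodic_auc(fit_hi),
        "aperiodic_exponent": fit_hi.aperiodic_exponent,
    }


def summarize_offon(
    table: pd.DataFrame,
    response: str,
    transform: str = "identity",
    interaction: bool = True,
) -> tuple[pd.DataFrame, ModelFit, list[PosthocResult]]:
    """Fit the laser x group mixed model to a pooled epoch-metrics table.

    ``table`` must carry ``animal`` and ``group`` columns (added by the
    caller when pooling sessions) along with ``laser`` and the response.
    Rows with missing responses are dropped.  Returns the tidy modelling
    table, the fit, and laser-within-group post hoc contrasts.
    """
    required = {"animal", "group", "laser", response}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    tidy = table.dropna(subset=[response])[
        ["animal", "group", "laser", response]
    ].reset_index(drop=True)
    if tidy["laser"].nunique() < 2:
        raise ValueError("both laser levels must be present")
    spec = ModelSpec(response, transform=transform, interaction=interaction)
    fit = fit_lmm(tidy, spec)
    posthoc = posthoc_lsmeans(fit)
    return tidy, fit, posthoc
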