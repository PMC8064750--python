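# swrlab

Analysis toolkit for hippocampal local field potentials (LFP) recorded
with paired "staggered" wire electrodes, built around the question of how
septal cholinergic activation reshapes CA1 network states: it detects and
classifies sharp-wave ripples (SWRs), decomposes power spectra into a 1/f
aperiodic background plus narrowband oscillatory peaks (theta 5–12 Hz,
slow gamma 25–45 Hz), scores appetitive Y-maze learning, and runs the
corresponding mixed-effects inference. A ground-truthed synthetic LFP
generator stands in for raw recordings, so every stage can be validated
against known injected signal.

Intended users: systems-neuroscience analysts who need a tested,
scriptable SWR/spectral pipeline, and methodologists who want a synthetic
bench with exact ground truth for detector and estimator validation.

## What it computes

**Ripple detection.** The differential signal of the electrode pair
(cancels common-mode movement artifact, doubles locally generated
phase-reversed events) is band-passed at 100–250 Hz (zero-phase Chebyshev
type II, order 4, 20 dB stopband), squared, mean-subtracted, and smoothed
with a 10 ms moving average. Candidate events are envelope excursions
above 2 SD lasting 20–300 ms whose peak exceeds 7 SD; the SD baseline
excludes EMG-flagged artifact windows (|ΔEMG| > 2 SD masks a centred
500 ms window). A candidate is an SWR iff the argmax of the multitaper
PSD (NW = 2, 3 DPSS tapers) of its segment is ≥ 140 Hz. Incidence is the
SWR count divided by artifact-free duration.

**Spectral decomposition.** Welch PSDs (0.5 s windows, 0.25 s overlap,
1–200 Hz) are modelled on log–log axes as a straight aperiodic line plus
Gaussian peaks,

    log10 P(f) = b − χ·log10 f + Σ_k h_k · exp(−(f − c_k)² / 2σ_k²),

fitted separately over 3–15 Hz and 15–150 Hz. Relative theta/gamma power
is the peak height h above the background (scale-invariant), and
broadband power is summarised by the area under the aperiodic line on
log–log axes (AUC).

**Inference.** Epoch metrics Y are modelled with a random-slope linear
mixed model, Y_i = β0 + R0a + (β1 + R1a)·L + β2·G + β3·L·G + ε_i, with
animal-specific intercept/slope corrections (R0a, R1a), laser L and group
G as fixed effects. Fitting is REML (statsmodels MixedLM); t/F tests use
a Satterthwaite degrees-of-freedom approximation implemented in this
package and cross-checked against lmerTest; post hoc least-square-mean
contrasts are Holm-Bonferroni adjusted. A Shapiro-Wilk-gated chooser
dispatches simple comparisons to t-test/ANOVA or Wilcoxon/Kruskal-Wallis
(+ Dunn) branches.

**Behaviour.** Counterbalanced pseudo-random Y-maze start sequences
(5 left / 5 right per day, no more than 3 consecutive same-side starts,
uniform over the valid set by exact enumeration), days-to-criterion
scoring (first day with ≥ 80% rewarded trials) and retention percentages.

## Worked example

`python examples/02_detect_ripples.py` runs the full detection chain on a
600 s synthetic sleep session (laser-off ripple incidence 0.21 Hz,
laser-on 0.03 Hz) and prints:

```
masked 26.9 s of 600 s (40 artifact windows)
candidates 58, after artifact exclusion 56, classified SWR (peak >= 140 Hz): 51
overall SWR incidence: 0.089 Hz
SWR peak frequency 168.3 Hz, duration 38.6 ms
ground truth: 55/56 injected ripples recovered (sensitivity 0.98)
```

The masked seconds are EMG/movement windows removed from all statistics;
the 0.089 Hz overall incidence mixes suppressed (laser-on) and intact
(laser-off) halves of the session; peak frequency and duration recover
the generator's settings (168 Hz bursts, 25–55 ms). The other examples
cover simulation (`01`), spectral decomposition (`03`), mixed-model
inference on a multi-animal cohort (`04`), and behaviour scoring (`05`).

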