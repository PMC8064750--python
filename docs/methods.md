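# Methods

This note documents the models, algorithms and numerical choices behind
`swrlab`, what the synthetic bench does and does not emulate, and the
known limitations a user should weigh before applying the pipeline to
real recordings.

## Signal model and preprocessing

The analysis assumes paired "staggered" wire electrodes: two closely
spaced tips at different depths around the CA1 pyramidal layer. Volume-
conducted and movement signal is common to both tips, while theta, gamma
and ripples generated locally between the tips appear phase-reversed.
The differential signal therefore cancels common-mode content and
doubles the local content; `sigprep.differential_signal` is a plain
element-wise subtraction and all analysis runs on it.

All analysis happens at 1250 Hz. `sigprep.resample` performs polyphase
resampling with a package-designed FIR anti-alias filter (64·max(up,down)+1
taps, cutoff at 0.92 of the output Nyquist): the library default filter
leaves content just above the output Nyquist only ~27 dB down, which
would alias into the ripple band.

Artifact rejection follows a self-normalising rule: samples where the
EMG first difference exceeds 2 SD of all first differences mask a 500 ms
window centred on the change; overlapping windows merge. The SD is
computed over the whole session (a robust 1.4826·MAD variant is
available). Two properties matter in practice:

* the rule assumes artifacts dominate the difference SD. On an EMG that
  is pure stationary noise, 2 SD is just the ~4.5% tail of its own
  fluctuations and the rule saturates, masking nearly everything. A
  truly silent EMG (SD = 0) returns an empty mask, the documented
  degenerate case.
* masked samples are excised from every statistic (threshold baselines,
  PSDs, incidence denominators) but event times stay in session time, so
  annotations remain valid.

## Ripple detection

Detection is the classic envelope method: Chebyshev type-II bandpass
100–250 Hz (order 4, 20 dB stopband, forward–backward so burst peaks are
not delayed), square, subtract the mean, smooth with a 10 ms moving
average. Envelope excursions above 2 SD form candidate crossings; an
event is retained iff its extent lies in 20–300 ms and its peak exceeds
7 SD. Thresholds are strict inequalities, making detection invariant to
positive rescaling of the trace. The SD baseline is the artifact-free
session by default (configurable per epoch).

**Fragment merging.** With a stochastic in-band background, destructive
interference can drop the envelope below the onset threshold for ~10 ms
in the middle of a genuine event, splitting one burst into fragments —
and the fragments of an over-long event would individually pass the
duration gate. Candidate events are therefore clusters of *peak-strong*
(> 7 SD) crossings separated by less than 20 ms (one minimum event
duration); weak crossings can neither join nor bridge clusters, so
coincidences of noise crossings are not promoted into events. With this
rule, white Gaussian noise yields < 0.005 false events/s.

**Peak frequency and the SWR gate.** Each event's spectral peak
frequency is the argmax of a multitaper PSD (NW = 2, 3 DPSS tapers,
zero-padded to ≥ 256 points) of the band-filtered segment from event
start to end, restricted to 100–250 Hz; events at ≥ 140 Hz (inclusive)
are classified as SWRs. Filtering before estimation is essential: on a
25–55 ms window the taper main lobe spans tens of Hz, so the far
stronger 1/f + theta background of a raw segment leaks into the search
band and drags the argmax down by tens of Hz. Two intrinsic limits
remain and are worth knowing:

* a ~50 ms event's multitaper spectrum is a plateau tens of Hz wide, so
  *single-event* estimates scatter by roughly ±15–20 Hz. Means over
  events are tight (the pipeline recovers a 168 Hz setting to ~1 Hz),
  but the 140 Hz gate misclassifies ~5% of true 168 Hz events, which
  biases measured SWR incidence slightly below truth.
* the Chebyshev transition skirt tilts the 100–120 Hz region, so events
  with true peaks near the band edge read ~10 Hz high on short windows.

**Duration semantics.** The moving average widens a short burst's
envelope by about one window (a 10 ms burst reads ~18–22 ms), and the
2 SD crossing of a long tapered burst sits inside its nominal extent.
Detected durations track injected durations linearly (r > 0.9 across
25–250 ms), but the mapping is not the identity; gate behaviour at the
20/300 ms edges is exact for events whose envelope is unambiguous
(validated on noise-free fixtures at study-typical 10–16 SD peaks) and
stochastic within a few percent for marginal events under a noisy
background.

## Spectral decomposition

PSDs come from Welch's method with 0.5 s Hann windows and 0.25 s overlap
over 1–200 Hz, zero-padding each segment to the next power of two (so
the 3–15 Hz fit range has ~10 grid points rather than 6). The
periodic/aperiodic model is fitted per range — 3–15 Hz (theta metrics,
up to 3 peaks) and 15–150 Hz (slow gamma and broadband metrics, up to 6
peaks) — keeping the straight-line, no-knee aperiodic form accurate:

1. robust line fit to log10 power vs log10 frequency, iteratively
   dropping points more than 1 residual SD *above* the line (peaks only
   bias upward);
2. greedy peak extraction from the flattened residual. A candidate must
   exceed max(2 × residual SD, 0.1 log10 units); its width is seeded
   from the half-height extent and clamped to bandwidths of 1–12 Hz
   (bandwidth = 2σ). A candidate landing within 2.5 σ of an accepted
   guess is treated as residue of the same bump — subtracted but not
   added — so one physical peak yields one Gaussian;
3. a bounded joint least-squares refit of line + all Gaussians (centres
   confined to ±1.5 σ of their guesses, heights to 3× the largest
   residual). The joint fit replaced a strictly sequential
   line/peaks/line procedure that was unstable on the few-point low
   range.

Relative band power is the fitted peak height above the line in log10
units (linear ratio 10^h), and `aperiodic_auc` integrates the fitted
line over log10 frequency with the trapezoid rule — exact for a straight
line, hence the 1e-9 agreement with the closed form. Off/on PSD
contrasts take the signed extremum of Δlog10 power per band (theta, its
2–5 and 12–15 Hz flanks, slow gamma, 90–110 Hz). Time–frequency
visualisation uses a complex Morlet CWT (ω0 = 6, logarithmic grid
1–200 Hz at 10 voices/octave), z-scored per frequency row; zero-variance
rows are returned as NaN.

Welch smearing biases recovered peak centres upward by roughly
σ_obs²·χ/f (the fitted bump is the background-relative ratio, which
weights the smeared peak by f^χ); at theta this is ~+0.15 Hz with the
default settings, well inside the ±0.25 Hz recovery bound but visible as
a consistent sign.

## Synthetic bench

`synth.generate_session` builds a session as *local* content ℓ (1/f
background + oscillations + ripples), split ±ℓ/2 between the two LFP
channels, plus a *common* 1/f process and large slow movement transients
added identically to both. The differential is exactly ℓ and common
artifacts cancel by construction. Components and defaults:

* **Aperiodic background**: white noise spectrally shaped to a one-sided
  PSD of 10^offset/f^χ — the target slope is exact, not approximated.
  Defaults χ = 1, offset = 2 (log10 µV²/Hz at 1 Hz).
* **Oscillations** are parameterised the way the decomposition measures
  them: a bump that is Gaussian in log-relative power above the
  background, with centre frequency, height h (log10 units) and spectral
  SD. This makes "peak frequency" and "relative power" well-defined
  ground truths; a linear-power Gaussian bump would peak at f0 + σ²/f in
  log space and disagree with any correct analysis by more than the
  faithfulness bound. Defaults: theta 7.7 Hz (h = 1.4, σ = 0.75 Hz)
  when the laser is off, 7.2 Hz with h = 1.4 + log10(1.51) when on
  (a 1.51× relative-power increase); slow gamma 35 Hz (h = 1.15,
  σ = 1.5 Hz) in both states.
* **Ripples**: Poisson-timed (0.21 Hz off / 0.03 Hz on by default),
  non-overlapping, flat-topped Tukey(α = 0.1) sine bursts at 168 Hz,
  25–55 ms, injected antiphase. The flat top keeps the suprathreshold
  extent close to nominal duration (a Gaussian envelope's 2 SD extent
  is only ~0.4× nominal, which would make duration ground truth
  meaningless). Amplitude is calibrated so the detection-envelope peak
  reaches `snr_sd` SDs *of the event-containing envelope* — the same
  normalisation the detector applies; calibrating against the
  pre-injection baseline would under-deliver by the ~10% SD inflation
  the events themselves cause. Default snr 10 with ±20% per-event
  scatter; the study this emulates does not report ripple amplitude
  statistics, so snr is a free parameter, not a claim about recordings.
* **EMG**: smooth (20 Hz low-passed) baseline noise with broadband
  bursts (50× baseline, 200 ms) at its own Poisson times and at every
  movement-artifact time — the artifact-dominated regime the masking
  rule assumes.
* **Epochs**: alternating 30 s laser-off/on blocks (10 cycles = 600 s by
  default), mirroring a sleep stimulation protocol of 30 s stimulation
  alternating with rest intervals.

One seed expands into per-component substreams (background, oscillations,
ripples, EMG, artifacts), so identical configurations are byte-identical
and components are independently reproducible.

What the bench does **not** emulate: sharp-wave/ripple waveform
asymmetry and intra-event frequency chirps, state transitions (REM/NREM
structure, micro-arousals), line noise, electrode drift, inter-animal
heterogeneity of spectra, or any biophysics (no spike trains, no
conductance models). Passing recovery tests therefore shows the
pipeline's estimators are correct *for signals with the assumed
statistical structure*, not that the detector is optimal for any real
recording.

## Inference

The mixed model treats repeated epochs within an animal as correlated:
random intercept and laser-slope per animal with an unstructured 2×2
covariance, REML estimation via statsmodels MixedLM (lbfgs then bfgs, up
to 200 iterations). The group × laser interaction is included by default
— it is the term that asks whether the laser does more in the
opsin-expressing group — with the additive model available.

Satterthwaite degrees of freedom are computed in-package: for a contrast
c, ν = 2(c'Cc)²/(g'Ag), with C(θ) the fixed-effects covariance as a
function of the variance parameters, g its central-difference gradient,
and A the inverse negative Hessian of the REML criterion (also by
central differences, relative step 1e-4). Estimates, SEs, df and
p-values agree with lme4/lmerTest to four decimals on interior fits (a
cross-check in the test suite runs R directly). Boundary fits —
vanishing variance components, |intercept–slope correlation| → 1, or a
non-positive-definite Hessian — invalidate the curvature; they are
flagged `singular` and fall back to between-animal df (n_animals − 2)
rather than reporting a spuriously small Satterthwaite value. Simulated
at the null with 10 animals, the interaction test's type-I error is
≈ 0.055 at nominal 0.05.

Post hoc least-square-mean contrasts (laser within each group by
default) reuse the same machinery with Holm-Bonferroni adjustment over
the supplied family. Residual diagnostics (mean, correlation with
fitted, Breusch-Pagan) support the transform rule: a multiplicative
response fails homoscedasticity on the identity scale and passes on the
log scale, and the log model refuses non-positive responses with a
pointer to use an offset or the identity model.

The simple-comparison chooser gates on Shapiro-Wilk at p > 0.05 per
group (on paired differences for paired designs): parametric branch
(t-test / one-way ANOVA) when all pass, otherwise ranks (Wilcoxon /
Mann-Whitney / Kruskal-Wallis with a Dunn post hoc, tie-corrected,
Holm-adjusted).

## Behaviour

Start sequences are drawn uniformly over the exact enumeration of
arrangements with 5 left / 5 right starts and no run longer than 3
(rejection sampling above n = 16). Days-to-criterion is the first day
with ≥ 80% rewarded trials, inclusive; mice that never reach it are
flagged rather than assigned a number, and ragged 6–10-day logs are
accepted. The synthetic behaviour generator draws per-mouse logistic
learning curves (chance 1/3 → 0.95 asymptote) with group-specific
midpoints chosen so group means land near the regime the scorer targets
(no-stimulation ≈ 2.9 days, goal-zone stimulation ≈ 4.5 days, the other
groups between).

## Pipeline conventions

Events are assigned to epochs by peak time; each epoch's incidence
divides by its artifact-free duration; epochs shorter than one Welch
window (0.5 s) carry NaN spectral metrics, and zero-length epochs are
skipped with a warning. `summarize_offon` drops rows with missing
responses, requires both laser levels, and notes dropped terms (e.g. a
constant group column) in the fit.

Problem sizes used by the test suite and the acceptance script — 600 s
sessions, cohorts of 5 + 2 animals, 25–50 seeds for spectral recovery,
100 replicates for power and 1500 for null calibration — were chosen so
Monte-Carlo error is small relative to each quantity's tolerance while a
full run stays in the minutes range on one core.

## Known limitations

* The incidence the pipeline reports is detector-filtered truth:
  sensitivity ~0.94 and the ~5% SWR-gate misclassification put measured
  off-incidence ~10% below the injected rate. This mirrors what any
  threshold detector does to real data and is why recovery criteria are
  stated in Poisson bands rather than as exact equality.
* Per-event peak frequencies are coarse (see above); treat them as
  inputs to means, not as single-event measurements.
* The EMG masking rule needs artifact-dominated EMG; applying it to a
  quiet, noisy EMG channel over-masks.
* The Satterthwaite fallback for boundary fits is a pragmatic df choice,
  not an exact small-sample theory; strongly unbalanced designs with
  few animals deserve a sensitivity check (e.g. the diagonal
  random-effects option).
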