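# Methods

This note documents the models and numerical choices behind `fiberflow`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Signal model and zdF/F correction

A dual-excitation fiber-photometry recording interleaves a
calcium-dependent channel (e.g. 470 nm with GCaMP6s) and a
calcium-independent reference (415 nm, near-isosbestic) on one camera:
with the camera at 20 Hz and two LEDs alternating, each channel is
sampled at 10 Hz on offset time grids. The raw fluorescence of either
channel is modeled as

    F(t) = drift(t) + g · artifact(t) + calcium(t) + noise,

where `drift` is slow photobleaching, `artifact` is a fiber-motion
component shared across channels with channel-specific gain `g`, and
`calcium` is present only in the signal channel. The correction chain:

1. **Smoothing.** Centered moving average of width `smooth_window_s`
   (default 1 s), implemented with reflect padding so the output has the
   input's length, zero phase shift, and exact DC preservation. A
   zero-phase Butterworth low-pass (`lowpass_cutoff_hz`) is the exclusive
   alternative for users who prefer a true frequency cutoff.
2. **Baseline removal (airPLS).** The baseline solves the weighted
   penalized least-squares problem `min Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²`.
   Weights are re-estimated each iteration: points above the running
   baseline (positive residuals, i.e. peaks) get weight 0; points below
   get `w_i = exp(iter · |d_i| / Σ|d⁻|)`. Iteration stops when the summed
   magnitude of negative residuals falls below `tol · Σ|y|` (default
   1e−3) or at `max_iter` (default 50). The inner solve uses a sparse
   banded system (scipy `spsolve`), so a 6 000-sample trace detrends in
   milliseconds.
3. **Standardization** to mean 0, sd 1 (population sd). Traces whose sd
   falls below `sd_floor` (default 1e−8) are returned as centered zeros
   and flagged degenerate rather than amplified to garbage.
4. **Reference fit.** The standardized reference, linearly interpolated
   onto the signal's timestamps (the channels live on offset grids by
   construction of interleaving), is fitted to the standardized signal by
   non-negative L1-regularized least squares (scikit-learn Lasso with
   `positive=True`; `l1_alpha` default 1e−4, near-unregularized).
   The non-negativity constraint means the reference can only be
   subtracted, never sign-flipped into a spurious signal. `l1_alpha = 0`
   falls back to constrained OLS. Robustness is realized as the L1
   penalty; an M-estimator loss is deliberately not used.
5. **Subtraction.** `zdF/F = z_signal − (a·z_reference + b)`.

One slope is fitted per whole trace (not per segment); per-segment
fitting would track slow gain changes but risks absorbing real signal.

### Choice of the baseline stiffness λ

For a second-order difference penalty the effective smoothness scale
grows like `λ^(1/4)` samples. At 10 Hz, `λ = 1e4` yields a ~1-s baseline
that tracks — and therefore removes — multi-second physiological
elevations such as sustained movement-related activity; measured on
synthetic sessions, the correlation between zdF/F and the known clean
signal dropped to ~0.63. The default is therefore `λ = 1e8` (~10-s
scale), which follows minutes-scale photobleaching while leaving
second-scale physiology intact (clean-signal correlation ~0.93, artifact
correlation reduced by 80–96 %). Users with faster or slower drift should
scale λ by the fourth power of the desired time scale in samples.

## Behavioral rules

* **Speed** from tracked coordinates: two-point Euclidean distance over
  the time step, assigned to the interval end, length n−1.
* **Mobility score**: session-wise min-max scaling of speed into [0, 1].
  Per-session (not per-animal) scaling makes scores comparable across
  tracking setups; a constant-speed session is flagged degenerate.
* **Immobility bout**: maximal run with score strictly below 0.1 lasting
  at least 2 s; a sample exactly at 0.1 counts as mobile (strict
  inequality), and a run lasting exactly 2.0 s counts as immobile. Run
  duration is measured from the first sub-threshold sample to the first
  supra-threshold sample. Mobility bouts are the complement, so the two
  classes tile the session exactly.
* **Consumption event**: lick contacts merged across gaps strictly
  shorter than 1 s (a gap of exactly 1 s ends the event); merged events
  kept if they persist at least 0.5 s (an event of exactly 0.5 s is
  kept). The detector is idempotent and insensitive to input ordering.
* **Event selection** for peri-event correlation: four kinds (mobility
  onset, immobility onset, random-in-mobility, random-in-immobility).
  Random events keep `window_s/2` clearance from bout and session edges
  so every peri-event trace is complete; the clearance rule is this
  package's choice — onsets are used as-is apart from session-edge
  clearance.

## Peri-event statistics

Trials are linearly interpolated onto a uniform relative-time grid;
trials without full coverage are dropped (never padded) and counted. SEM
uses the population sd (`sd/√n`, ddof = 0), matching the package's stated
closed-form contract (two trials at ±1 give SEM 1/√2). AUC over a named
window is the trapezoidal integral divided by the window duration, with
the window endpoints included exactly by interpolation, so a constant c
integrates to c regardless of grid alignment. No additional per-trial
baseline subtraction is applied by default (zdF/F is already
standardized); the per-test windows are fixed tables:

| test | windows (s, relative to event) |
|---|---|
| airpuff | baseline (−2,−1), airpuff (0, 1.5) |
| consumption | baseline (−2,−1), onset (−0.5, 1), drinking (2, 4) |
| mobility | immobile (−3,−1), pre-onset (−1,0), onset (0,1), mobility (1,3) |
| avoidance | baseline (−2,−1), CS (0,8), crossed (8,11) |

## Correlation analyses

Whole-session and peri-event Pearson correlations resample both series to
the slower rate by linear interpolation. Event windows are centered on
the event (−w/2, +w/2; default w = 6 s). Classification thresholds:
positive if p < 0.001 and r > 0.6; negative if p < 0.001 and r < −0.6;
otherwise uncorrelated. p-values come from the standard t-distribution
Pearson test; peri-event samples are autocorrelated, so these p-values
are anticonservative for slow signals — the thresholds are configurable
for exactly that reason, and the null calibration (below) checks the
realized false-positive rate.

Cross-correlation: for each lag ℓ in [−max_lag, +max_lag] (step = one
common-grid sample, default 0.1 s), the calcium trace evaluated at
`t + ℓ` is correlated with mobility at `t` over the event window. A
negative lag of maximum therefore means calcium *leads* the mobility
change. Exact ties are broken toward the smallest |ℓ|. Swapping the two
traces negates the lag (antisymmetry), which the tests use to verify the
sign convention.

## Optogenetics metrics

RTPP preference score follows the printed formula
`(time ON − time OFF)/total`, with OFF = everything not spent in the
laser-paired state; a three-state variant that excludes corridor time
from both chambers is available behind a flag but is not the default,
because the printed formula is the reproducible contract. Epoch metrics
detect bouts on the whole session and attribute each bout to the laser
condition of its onset (bouts straddling an epoch boundary are not
split). Consumption metrics (mean duration, mean inter-event interval,
count, total duration) are normalized per metric by the mean of the last
pre-session and the post-session; a zero baseline yields NaN rather than
an exception.

## The synthetic-session generator

`SynthConfig` defaults describe a 600-s session with a 20-Hz camera
alternating 415/470-nm LEDs (10 Hz per channel, LED-state codes are the
bitmask 1/2/4). Latents:

* **Drift**: double-exponential decay per channel
  (`bleach_amp = 10` camera units over a baseline of 100,
  `bleach_tau_s = 120` plus a faster τ/8 term) — mimics photobleaching.
* **Artifacts**: Poisson bumps (`artifact_rate_hz = 0.2`,
  `artifact_amp = 3`, random sign) with ~1-s kinetics (rise 0.1 s, decay
  0.8 s), added to all channels with channel gains 0.7 (reference) and
  1.0 (signal). The ~1-s kinetics are deliberate: artifacts that survive
  the 1-s smoothing are the regime reference-based correction exists for.
* **Behavior**: alternating immobility/mobility bouts with exponential
  durations (means 8 s and 6 s, floors 2.5 s and 1 s so planted bouts are
  detectable), linear 0.3-s ramps at transitions, and a smooth
  within-bout fluctuation in [0.55, 1] (kernel-filtered noise), so
  immobility reads exactly 0 and bout boundaries are recoverable to
  within one sample.
* **Calcium**: unit-peak difference-of-exponentials transients (rise
  0.2 s, decay 1.0 s, GCaMP6s-like), one locked to every mobility onset
  at `onset + coupling_lag_s` plus Poisson background
  (`transient_rate_hz = 0.8`) within the lag-shifted mobility windows,
  **plus** a sustained movement-locked component
  `movement_gain · mobility(t − coupling_lag_s)` (default gain 2). The
  sustained component is what makes the planted lead/lag recoverable by
  cross-correlation: the calcium trace contains an exact lag-shifted copy
  of the mobility fine structure, so the lag-of-maximum estimator is
  consistent. Coupling through onset timing alone leaves the estimator
  badly biased (a transient bump against a flat bout plateau has no sharp
  correlation maximum). Setting `transient_rate_hz = 0` disables all
  calcium activity, including the coupled components.
* **Noise**: i.i.d. Gaussian per frame, `noise_sd = 0.5` — half the unit
  transient peak.
* **Licks**: Poisson bouts of ~8 contacts (0.1-s contacts at 5 Hz);
  within-bout gaps are < 1 s and between-bout gaps > 1 s by construction,
  so the consumption detector's recovery is exact.

Everything is driven by one `numpy` Generator seeded from `config.seed`;
identical configs give bit-identical sessions, including the returned
`GroundTruth` (transient times, per-channel clean/drift traces, the
shared artifact on the camera-frame grid with per-channel gains, bout
table, true lag, lick intervals).

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: timestamp jitter and dropped
frames; hemodynamic contamination; indicator nonlinearity and
photoswitching; behavior measurement noise; non-Poisson transient
statistics; per-animal variability. Recovery results on synthetic
sessions validate the *implementation* of each rule and estimator, not
the biological adequacy of the underlying model. SNR and artifact
magnitudes of real recordings are not published for this preparation;
the defaults were chosen once for testability (every planted latent
recoverable at desk scale) and are not tuned per experiment.

## Problem sizes and numerical choices

Analyses in the test suite and the acceptance script use 300–900-s
sessions at the default rates (6 000–18 000 frames), 10⁴ events for the
classifier null calibration, and ≥ 30 mobility onsets for lag recovery —
sizes at which every stage completes in seconds while keeping
Monte-Carlo error well below the asserted tolerances. Degenerate inputs
(constant traces, zero-variance windows, empty event sets, zero
baselines) are flagged or excluded rather than raised wherever a
flagged result is scientifically meaningful; structural violations
(non-monotonic timestamps, overlapping intervals, missing columns) raise
typed errors naming the offense.

## Known limitations

* The Pearson p-values ignore autocorrelation (documented above); a
  block-permutation null would be more honest but is out of scope.
* One reference channel: no multi-reference regression, no hemodynamic
  correction, no spike deconvolution.
* Group-level inference (ANOVA families) is deliberately excluded; the
  per-session tables are the hand-off point.
* The HDF5 session store is a convenience container versioned with a
  single layout attribute, not an archival format.
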