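# Methods

This note documents the models implemented in `spindec`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions adopted where the underlying
procedures are conventionally underspecified.

## Synthetic recordings

The generator produces the kind of data the analysis chain expects: raw
multichannel extracellular voltage from a linear multi-site shank in the
ventral horn, synchronized to hindlimb joint tracking during intermittent
wheel-running.

**Behavior.** Moving and stationary bouts alternate with exponentially
distributed durations (mean moving bout 4 s; the stationary mean is set so
the long-run moving fraction equals `moving_fraction`, default 0.7). A gait
phase clock advances at `2π·step_freq` (default 3.5 Hz, within the 3–4 Hz
range typical of mouse hindlimb stepping) during moving bouts and freezes
otherwise. Each joint traces a smooth limit cycle in pixel coordinates with
joint-specific excursions (largest at the toe, smallest at the iliac crest)
and phase lags, plus 0.3 px tracking jitter. Swing is defined as the
half-cycle with positive toe-x velocity; with `toe_x ∝ cos φ` this is
`φ ∈ (π, 2π)`. This velocity-sign rule is a convention: real labeling
pipelines derive swing/stance from paw contact, which has no analogue here.

**Spiking.** Each of `n_units` (default 40) units has a random preferred
phase µ and home channel. Its rate is

    r(t) = base + (peak − base) · exp(κ·(cos(φ(t) − µ) − 1))

while moving (a von Mises bump normalized so the rate reaches `peak` at µ)
and `base` while stationary. Defaults: base 5 Hz, peak 60 Hz, κ = 2.5 —
moderately sharp tuning with a session-mean rate near 20 Hz. Spikes are
drawn by thinning a homogeneous Poisson process at the peak rate and then
enforcing a 2 ms absolute refractory period. Per-channel amplitudes decay
as `exp(−d/λ)` from the home site with λ = 60 µm on a 40 µm-pitch shank;
per-unit peak amplitudes are spread uniformly over 0.6–1.4× the nominal
150 µV, i.e. ≈ 90–210 µV, matching the amplitude range reported for
chronic ventral-horn single units. With the 5 µV white-noise floor this
yields channel SNRs (mean peak-to-peak over twice the robust σ) of roughly
6–27 — the noise floor was chosen so that amplitude range and SNR range are
mutually consistent rather than calibrated to any single figure.

**Voltage trace.** The raw trace sums: a fixed biphasic template per spike
(sharp negative peak, 35% positive rebound, 1.2 ms support, trough exactly
at the spike time) scaled by the unit's per-channel amplitude; a
movement-locked sinusoid at the step frequency, in phase with the toe-x
oscillation, gated by the moving state, with a smooth 1.5→0.5 gain gradient
along the shank (a dorso-ventral amplitude profile — deliberately not
common-mode, since a perfectly common component would be removed exactly by
the median reference and carries no referencable signal); 1/f-shaped
background (5 µV rms, spectrum flattened below 1 Hz); white noise; a 50 Hz
mains sinusoid with ±10% channel gains; and boxcar bursts of high-variance
noise (artifact events, Poisson at 0.05 Hz, 100 ms, ≈200 µV) with
channel-specific coupling so referencing cannot cancel them. The trace is
quantized at 0.195 µV/count into int16, and every latent component (spike
times, amplitudes, artifact intervals, the locked waveform) is returned as
ground truth.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: electrode drift and unit loss, bursting and
rate adaptation, correlated (shared-input) spiking beyond common phase
tuning, spatially structured LFP beyond a single locked sinusoid plus 1/f
noise, waveform shape diversity and overlap-induced waveform distortion,
chewing/grooming artifacts with structure other than broadband variance,
and any closed-loop relation between neural activity and movement (here
kinematics drive the units, never the reverse).

## Preprocessing conventions

- Impedance window [100 kΩ, 2 MΩ] is treated as a **closed** interval.
- The artifact rule tiles each channel into consecutive **non-overlapping**
  50 ms windows and invalidates windows whose sample standard deviation
  (ddof = 1) exceeds 25 µV. Non-overlapping tiles make the mask idempotent
  and give exact expected counts under a χ² null. "Removal" means
  **masking**, not excision: the timebase stays aligned with the video;
  spike detection drops events on masked samples and feature windows with
  more than half their samples masked flag their frame.
- The mask is computed after the common median reference (the rule targets
  residual motion noise); the functions are separable, so either order can
  be composed explicitly.
- The across-channel median with an even channel count is the mean of the
  two central values.
- "4th-order Butterworth, zero-phase" means a 4th-order design applied
  forward and backward (`sosfiltfilt`), i.e. an 8th-order magnitude
  response with zero net phase; edges are handled by reflection padding.
  The notch is a Q = 30 biquad, also applied zero-phase: ≥ 20 dB at 50 Hz,
  < 0.5 dB at 45/55 Hz.
- Downsampling to 1000 Hz low-passes at 0.4× the target rate (8th-order
  Butterworth, zero-phase) before decimation.

## Spike detection and unit QC

The threshold `T = mean − k·rms` is computed per channel over **valid
samples of the whole recording** (block-wise re-estimation is not used);
`rms` is the root mean square, not the standard deviation, so a DC offset
shifts both the mean and the threshold. A spike is stamped at the **trough**
of each below-threshold excursion — troughs align better across channels
than crossing times — and a 1 ms dead time suppresses double counts from
one biphasic waveform.

SNR is `mean peak-to-peak / (2σ̂)` with `σ̂ = median(|x|)/0.6745` over
valid, spike-free samples. The formula is a convention chosen for
robustness and testability.

The single-unit rule is implemented as *single iff at most 1% of ISIs are
shorter than 3 ms* (at least 50 spikes for a decision). The rule is
sometimes stated with the opposite direction, which contradicts refractory
logic; a `printed_direction` flag provides that reading for compatibility.

Detection quality against ground truth uses threshold-relative amplitude
bands: on each channel, units whose local amplitude is ≥ 1.3×|T| are
*required* (count toward recall), units between 0.7×|T| and 1.3×|T| are
*optional* (legitimate detections, not demanded) — borderline-amplitude
units would otherwise make recall/precision depend on noise sign flips. A
truth spike is recalled if any detection lies within ±0.5 ms.

Spike **sorting** is out of scope: unit identities come from the
simulator's ground truth (or an external sorter's labels); footprint
analysis uses the per-unit per-channel amplitudes directly.

## Features and decoding

Each video frame is paired with the 300 ms of neural signal before it,
summarized in 26 windows of 50 ms stepped by 10 ms
(`(300 − 50)/10 + 1 = 26`), **right-aligned** so the last window ends at
the frame time; windows are half-open `(start, end]` so a tiling conserves
counts. Causality is strict. Decoding uses per-channel threshold crossings
(multi-unit activity) by default; per-unit counts are available. Joint
coordinates are min-max normalized per session with stored constants.

Band/movement correlation decimates each channel to 1000 Hz, interpolates
to frame times, computes Pearson r over moving frames per channel, and
aggregates as the mean of |r| across channels (after referencing, a
locked component can flip sign across the shank, so signed averaging would
cancel genuine structure).

The recurrent decoder is two LSTM layers with layer normalization and
dropout between them and a linear read-out from the last hidden state,
written in NumPy with hand-derived backpropagation through time and Adam.
Sequences run oldest-bin-first. Loss is mean squared error on normalized
coordinates; features are z-scored per channel on the training block.
Sessions are split into contiguous chronological blocks (0.8:0.1:0.1);
selection uses validation data only, with early stopping on validation
loss (patience 8 by default). The lookback of early validation/test frames
necessarily overlaps raw samples of the preceding block — unavoidable with
causal features and documented rather than hidden. Training is
deterministic under the config seed. A runaway loss (non-finite, or > 10⁶×
the untrained loss) raises with the loss trace attached.

Hyperparameter search is sequential model-based optimization: a GP
surrogate (Matérn 5/2 + white noise) over the unit hypercube and an
expected-improvement acquisition maximized over 256 random candidates per
round, after 5 space-filling rounds. The full search space is hidden
16–256, dropout 0–0.5, learning rate 10⁻⁴–10⁻² (log), batch 16–128 (log);
the canonical protocol is 60 rounds × 5 repeats. Tests and the acceptance
script use a reduced protocol — 8 rounds × 2 repeats over a 16–96 hidden
range with ≤ 30 epochs — which this package treats as its desk-scale
standard for a single 1000-frame session; the search surface there is
benign enough that the small budget reliably lands within a few percent of
the larger one.

`R² = 1 − SS_res/SS_tot` about the evaluation-set mean; zero-variance
targets give NaN with a warning. A one-way ANOVA convenience wrapper is
provided for comparing R² sets across conditions.

## Trajectories

Firing rates: spike trains binned on a 100 Hz grid (fine enough to resolve
the kernel) and convolved with a unit-area Gaussian of σ = 50 ms, so each
unit's rate integrates to its spike count. PCA: columns centered (optional
z-scoring off by default — centering alone matches the usual convention),
full SVD, deterministic sign (largest-magnitude loading positive), first
three PCs kept. LFP trajectories use the same embedding on the 1000 Hz
downsampled band signal.

Step cycles are delimited at stance→swing toe transitions inside moving
bouts. The average trajectory time-normalizes each cycle to [0, 1) and
averages PC scores in 50 fixed phase bins. The **closure statistic** is the
distance between the first and last bin means over the loop diameter;
note its floor of ≈ π/n_bins (≈ 0.063 at 50 bins) from the one-bin offset
between the first and last bin centers. The phase-shuffle control applies
a random circular phase shift per cycle before averaging: a genuine loop
collapses toward a point (residual diameter ~ 1/√n_cycles of the
original), a spurious one does not. The **state-separation score** is the
distance between moving and stationary centroids in PC space over the
pooled within-state RMS spread; > 1 indicates a clear neural state change.

## Problem sizes

Tests and the acceptance script run at desk scale as a deliberate
standard: 10–60 s sessions, 32 channels, 40 units, 1000-frame decoding
sessions (≈ 17 s at 60 fps), and the reduced search protocol above. These
sizes were chosen so every statistic they exercise (detection
recall/precision, band correlations, decoder R², loop closure, separation
scores) is stable at the quoted precision.

## Known limitations

- Threshold detection merges nearby units on a channel; near-simultaneous
  spikes (< 1 ms apart) on one channel yield a single event.
- The GP search assumes a smoothish response surface; with very noisy
  objectives (tiny validation blocks) it degrades toward random search.
- The closure statistic depends on the bin count (floor ≈ π/n_bins) and is
  meaningful only with enough cycles per bin (≥ ~20 cycles at 50 bins).
- The NumPy LSTM targets small problems; it is single-threaded BLAS-bound
  and has no GPU path.
- `state_separation` requires both behavioral states in the session; very
  short sessions may contain only one bout.
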