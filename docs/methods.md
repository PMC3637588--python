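# Methods

`nirsdecode` implements an offline single-trial decoder that distinguishes
isometric-pinching periods from rest using two probe locations of functional
near-infrared spectroscopy (left primary motor cortex M1 and ventral
premotor cortex PMv) together with four autonomic biosignals (heart rate,
breathing rate, mean blood pressure, phasic skin conductance).  Because no
human recordings ship with the package, a synthetic-recording simulator is a
first-class component: it defines the study conditions under which every
end-to-end claim is tested.

## Signal model and preprocessing

**Optics.**  Each probe carries four source-detector paths
(l_p = 2, 2.5, 3.5, 4 cm) at two wavelengths (692/834 nm).  Raw intensities
I(t) at 50 Hz are decimated to 5 Hz, converted to incremental
optical-density changes ΔOD_k = −ln(I(t_{k+1})/I(t_k)), and inverted through
the modified Beer–Lambert law

    (ΔO2Hb, ΔHHb)ᵀ = (1/l_p) · E⁻¹ · diag(1/DPF_λ) · ΔOD

with extinction matrix E = [[0.9556, 4.8538], [2.3671, 1.7891]] (cm·mM)⁻¹
and DPF = (6.51, 5.86).  Cumulative summation anchors the concentration
courses at zero.  Each session is z-normalized per channel, low-pass
filtered (2nd-order Chebyshev type II, 40 dB stopband at 0.5 Hz, applied
forward–backward so the pipeline is zero-phase) and high-pass filtered at
1/54 Hz by zeroing DCT coefficients below the cutoff (54 s is the longest
rest–cue–pinch period, so slower components cannot be task-driven).

Numerical notes: decimation uses scipy's zero-phase FIR decimator with
reflect padding — the FIR anti-aliasing filter has exactly unit DC gain and
no edge transients reach retained samples, so constant inputs are preserved
exactly.  The Chebyshev low-pass is tested against its own designed
magnitude response (its zero-phase gain at 0.05 Hz is ≈0.82 by design; any
flatter expectation would contradict a 2nd-order filter with a 40 dB
stopband at 0.5 Hz).  The DCT high-pass removes DC, so its output is
mean-free; it also redistributes slow block structure, which is why
"active mean > rest mean in every trial" holds for the fitted feature
signal but only on average for single hemoglobin channels.

**Motion artifacts** are detected on the raw 5 Hz intensities after a
5-point median filter.  Sliding windows of 32 samples (6.4 s, 25% overlap)
are scored by the inverse z-score s = mean/SD over the full window and over
a half window; a window is flagged when the mean over the four light paths
of (half s)/(full s) exceeds 3.  The implementation evaluates the ratio for
the leading **and** the time-mirrored trailing half (`halves="both"`).
Design rationale: a step transient inflates the SD of any half that
contains it, so the leading-half ratio alone is blind to steps early in a
window; under 25%-overlap tiling roughly 40% of step positions would be
geometrically undetectable.  Testing both halves makes the detector
symmetric in time and covers every step offset; `halves="first"` restores
the literal one-sided rule.  The ratio is scale-free, so detectability is
set by the ratio of transient size to the fast (cardiac + noise)
within-window variability.  Rest/active trial pairs whose windows intersect
a flagged region are excluded from the analysis.

**Biosignals.**  Mean blood pressure: per-session linear detrend, 1st-order
Butterworth low-pass at 0.1 Hz.  Heart rate: ECG band-passed 0.01–40 Hz,
then a QRS slope-energy emphasis (5–15 Hz), differentiation, squaring and a
120 ms moving-window integration; events trigger where this feature exceeds
0.4 × an exponentially decaying running maximum (time constant 5 s,
refractory 250 ms).  The emphasis and integration stages are standard QRS
practice and are what keep the single-fraction threshold reliable down to
~10 dB SNR.  A parallel detector on the raw blood-pressure pulse provides a
second beat train; ECG RR intervals that are missing or implausible
(outside 0.3–2 s, or outside 0.7–1.4× the running-median RR — the
signature of a missed/spurious beat) are replaced by the BP-derived rate.
Breathing rate uses the same detector (no emphasis, refractory 1.5 s) on
the 0.1–2.1 Hz band-passed flow signal.  Rates are previous-interval step
functions sampled at 5 Hz and smoothed at 0.25 Hz.  Skin conductance is
low-passed at 30 Hz and the tonic level is removed by subtracting a
continuous piecewise-linear fit with breakpoints at trial starts.  All four
series are decimated/sampled to 5 Hz and session-wise z-normalized.

## Feature extraction and observations

For each pinching trial, an active window of N_W = 75 samples (15 s, the
shortest possible rest interval) starts N_Δ = 25 samples (5 s) after the
pinch onset; the associated rest window ends N_Δ past the end of the
preceding rest period.  Both windows carry the same forward shift — the
hemodynamic response lags the stimulus, and mirroring the shift on the rest
side keeps the two windows the same distance from their period boundaries.
Per location, the eight hemoglobin channels are collapsed to one feature
signal with weights β minimizing ‖M·β − y‖², where M stacks the training
segments (in randomized order, which provably cannot change the solution —
tested) and y is 1 on active rows, 0 on rest rows; rank deficiency falls
back to the minimum-norm solution.  Observations are 75×2 (fNIRS-only:
M1 and PMv feature signals) or 75×6 (combined: plus BP/HR/BR/SCR, used
without any further feature extraction).

## Dual hidden-Markov-model classifier

One left-to-right HMM per class (active, rest): start fixed in the leftmost
state, transitions only to self or right neighbor, the last state absorbing.
Emissions are mixtures of N_m full-covariance Gaussians per state; the
topology grid is N_s ∈ {1..5} × N_m ∈ {1, 2}.  Initialization pools all
training rows, k-means clusters them into N_s·N_m groups (5 k-means
restarts), and assigns clusters to (state, mixture) slots by their temporal
centroid so early-responding clusters seed left states; allowed transition
entries are drawn uniformly and row-normalized.  Baum–Welch (implemented
in-package, batched over the equal-length sequences) maximizes the joint
likelihood; stopping at relative improvement < 1e-6 or 100 iterations;
covariance eigenvalues are floored at 1e-6 (needed with ~22 training
sequences and full covariances).  If flooring ever breaks the EM guarantee
the previous parameters are restored and training stops, so the recorded
log-likelihood history is monotone by construction.  The start vector is
not re-randomized: the stated structure pins it to the leftmost state.

Training is restarted 10 times per class; every (active, rest) candidate
pair is scored on the training trials by

    κ = Σ_{correct} |D(i)| / Σ_all |D(i)|,   D(i) = LL_a(i) − LL_r(i),

a |D|-weighted training accuracy (trials with D = 0 are signed as rest by
the strict decision rule and carry zero weight in κ; if all D vanish κ is
defined as 0).  The κ-maximizing pair classifies test trials by the sign of
D, ties resolving to rest.

## Assessment

Rest/pinch *pairs* (never single trials) are randomly split into 4 folds,
so each train/test set holds equally many rest and active observations.
Fold metrics (Acc, Sens, Spec from pooled confusion counts) are averaged
into one complete cross-validation run; 7 independent runs (fresh
partitions) give mean ± SD; the topology with the highest mean accuracy is
selected per decoder mode, ties breaking toward fewer states then fewer
mixtures (parsimony).  Partitions are shared across modes and topologies
within a repeat so mode comparisons are paired.  Chance-level testing uses
the exact Clopper–Pearson interval evaluated at the *fractional* mean
success count (beta-quantile form; this, not integer rounding, reproduces
the published subject-7 interval [48.7, 74.8] for accuracy 62.4% over 58
trials).  Decoder modes are compared per metric with paired two-tailed
t-tests across the run-level means, and at the group level across
per-subject means; relative gain is 100·(combined − fNIRS)/fNIRS.  Group
averages include only subjects with both modes.

## Synthetic recordings

The simulator emulates the two-session protocol: 180 s lead-in and 120 s
lead-out baselines, five shuffled blocks per session of the four conditions
(cued pinches with 10 s/5 s cues, a sham cue, an uncued pinch), 20 s
pinches, rest periods uniform on [15, 24] s — 30 rest/pinch pairs in total.
Rest durations are uniform because only the range is known; condition order
is drawn without replacement per block.

Hemodynamics: a boxcar over pinch periods convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6), peak ΔO2Hb
+0.5 µM at M1 (0.7× at PMv) and ΔHHb = −⅓ of that — typical magnitudes for
overt motor tasks.  Systemic contaminants enter as equivalent-concentration
oscillations: cardiac 0.3 µM at 1.1 Hz, respiratory 0.1 µM at 0.27 Hz,
Mayer 0.05 µM at 0.1 Hz (25% leaking into HHb), chosen so that short-window
intensity variability is pulsation-dominated as in real recordings — this
is what stabilizes the motion-artifact ratio, and it yields realistic trial
exclusion rates of a few percent.  White optical-density noise (SD 5e-4 per
50 Hz sample) and a random-walk drift complete the forward model
I = I₀·exp(−ΔOD).  Autonomic channels: an integrate-and-fire cardiac phase
drives Gaussian-template QRS complexes (HR 65 → +5 bpm under task, first-
order response τ = 3 s) and the BP pulse; respiration is a
frequency-modulated sinusoid (16 → +2 breaths/min); mean BP steps +5 mmHg;
skin conductance adds Bateman-kernel phasic responses (0.5 µS, 1–3 s
latency) on a drifting tonic level.  `null_mode` zeroes every task-locked
effect while keeping all noise and contaminants.  A force-tracking stimulus
(truncated Fourier series at 0.5/1.0/1.1 Hz) is part of the protocol but
deliberately not consumed by the decoder, and is therefore not synthesized.

What the simulator does **not** emulate: realistic ECG morphology (P/T
waves), subject-to-subject anatomical and optode-coupling variability,
non-stationary contaminant amplitudes, or spatially heterogeneous
activation across light paths.  Passing end-to-end tests therefore shows
that the pipeline recovers the statistical structure it assumes, not that
it would reach the same accuracy on human data.

## Problem sizes and reproducibility

End-to-end evaluations use the full 30-pair protocol with a reduced
topology grid (N_s ∈ {1, 2}, N_m = 1) and 3 cross-validation repeats; the
oracle batteries use 100 random instances (N_s ≤ 3, T ≤ 5) and 200
sequences for parameter recovery.  These sizes keep a complete evaluation
in the minutes range on one CPU while leaving every pipeline stage
exercised at full signal length.  All randomness — protocol draws, noise,
k-means, transition initialization, restarts, partitions — derives from a
single master seed via named seed sequences, and every reported artifact is
bit-reproducible for a fixed seed.

## Known limitations

* The published per-subject accuracies stem from unreleased human
  recordings; they are reproduced here only at the level of their printed
  aggregates (group means, gains, confidence interval), which the package
  recomputes from the per-subject table.
* With ~22 training sequences, full-covariance mixtures at the larger grid
  cells (N_s = 5, N_m = 2) rely on the covariance floor; selected
  topologies on synthetic data are accordingly small.
* The SCR detrend assumes the tonic level is piecewise linear between trial
  starts; sustained phasic activity spanning several trials would be
  partially absorbed.
* The motion-artifact detector is tuned (threshold 3) for step-like
  transients; slow baseline drifts are left to the DCT high-pass instead.
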