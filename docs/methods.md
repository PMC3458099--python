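# Methods

## The generative model

The simulator represents one channel of event-related EEG as a dense sum of
sinusoids, one per frequency on a grid (defaults 0.1–250 Hz in 0.1 Hz steps;
frequencies at or above the sampling Nyquist are dropped with a warning).
Each oscillation has a fixed amplitude `a_f` and, per trial, a random phase
offset `Δφ_f` from a per-channel *target oscillation*, drawn uniformly on
(−π, π] independently per frequency (shared across channels, which differ
only in target phase).  The target oscillation for frequency `f` is
`cos(2π f (t − t_start) + φ_target)`: one target phase per channel, the same
for all frequencies and trials, anchored at `t_start`.

After a stimulus at `t = 0`, each oscillation passes through five stages —
baseline, synchronization, phase-locked, desynchronization, baseline.  `Δφ_f`
is mapped to `Δφ' = Δφ_f mod 2π ∈ [0, 2π)` so that alignment is always
achieved by *slowing* (the uniform draw is symmetric, but the model's
mechanism is slowing-only; the backward shift reconciles the two).  With
linear ramps `u1(t)`, `u2(t)` rising 0→1 over the synchronization and
desynchronization stages, the phase is

    φ_f(t) = 2π f (t − t_start) + φ_target + Δφ' (1 − u1(t) + u2(t)),

continuous everywhere, equal to the target phase (mod 2π) on
`[t_synch, t_desynch)` and back at the baseline offset from `t_end` on.  The
instantaneous frequency is `f` except for a constant dip
`Δφ'/(2π (t_synch − t_start))` while synchronizing and an equal-area rise
`Δφ'/(2π (t_end − t_desynch))` while desynchronizing.

Quadratic or spline phase transitions are not implemented (linear ramps
only); instantaneous phase resetting is representable only as the limit and
is out of scope.

### Timing laws

Synchronization latency grows with the square root of the period,

    t_synch   = t_start + k_synch   · √T
    t_desynch = t_start + k_desynch · √T + c_desynch,      T = 1/f
    t_end     = t_desynch + t_end_offset.

Defaults: `t_start = 0.08 s` (cortical arrival delay for a visual stimulus),
`t_end_offset = 1.5 s`, `k_synch = 0.5 s^½`, `k_desynch = 0.9 s^½`,
`c_desynch = 0.05 s`.  The two coefficients and the offset are *calibration
parameters of this package*: they place the synchronization times near the
phase-locking-value peak latencies seen in IMF analyses of event-related EEG
(tens of ms at gamma frequencies to ~0.6 s at 1 Hz), and they satisfy the
stage ordering `t_start < t_synch < t_desynch < t_end` over the whole default
grid, which is validated at configuration time.  Expressing the latencies as
offsets from `t_start` keeps that ordering for every frequency; with
`t_start = 0` the laws reduce to plain `k√T` fits.

### Responding fraction

`responding_fraction` (default 0.5) is the probability that an oscillator
(one frequency in one trial) follows the phase schedule at all;
non-responders stay at baseline.  Responding is all-or-none *per oscillator*
(a Bernoulli mask per trial), not an amplitude split of each oscillator into
a modulated and a stationary part.  The distinction matters: with an
amplitude split, the two parts of one oscillator drift apart in phase after
the stimulus and their cross term vanishes, so epoch-local power falls to
`r² + (1−r)²` of baseline (half, at r = 0.5) — violating the model's
constant-amplitude assumption.  With all-or-none responding every sinusoid
has constant amplitude and power is conserved exactly per oscillator.

The discrimination experiment (below) runs the *full-response* form
(`responding_fraction = 1`), the configuration under which the frequency test
was formulated; the 50% default is the variant that matches the smaller
frequency-change magnitudes of real EEG, at the cost of proportionally weaker
dips.

### Baseline spectrum

`synthetic_spectrum` builds amplitude weights `a_f ∝ f^(−exponent)` plus a
Gaussian alpha bump (peak 10 Hz, width 1.5 Hz, gain 3 by default), normalized
to unit total power.  The default exponent 0.5 makes the *power* spectrum
`∝ 1/f`, the canonical resting-EEG shape; amplitude `∝ 1/f` (exponent 1) is
available but concentrates >90% of power below 0.5 Hz — periods far longer
than a ±2 s epoch — which starves EMD of resolvable scales.  Weights may also
be taken from a Welch PSD of real baseline data restricted to the model grid.

### The evoked comparison model

Evoked trials are the same synthesis with all ramps disabled (stationary
random-phase background) plus a fixed channel × time template added unscaled
to every trial; the canonical template is the Firefly-generated ERP (raw
trial mean), so the two datasets have nearly identical ERPs.

## Analysis chain

* **EMD.** Sifting subtracts the mean of natural-cubic spline envelopes
  through the local maxima and minima (strict extrema, plateau midpoints; two
  extrema mirrored about each end).  A mode is accepted when the Cauchy
  criterion `Σ m² / Σ h² < 0.2` holds *and* its extrema and zero-crossing
  counts differ by at most one, capped at 50 sifting passes.  Six IMFs per
  trial by default; the remainder folds into the residual, so reconstruction
  is exact by construction.  On white noise the decomposition behaves as a
  dyadic filter bank (median successive-frequency ratio ≈ 2.3).
* **Hilbert analytics.** Amplitude and unwrapped phase from the analytic
  signal; instantaneous frequency by convolving the phase with a
  first-derivative-of-Gaussian kernel, σ = 20 ms, normalized to unit first
  moment (exact on linear phase; bias < 0.1% on tones 1–100 Hz).  The first
  and last 100 ms of every analytic series are flagged edge-distorted and
  excluded from statistics; for IMFs slower than ~3 Hz the true distorted
  region is larger (see Limitations).
* **Trial summaries.** Per ordinal IMF: evoked (trial-mean series), induced
  (trial-mean envelope), PLV (modulus of the trial-mean unit phasor), and
  trial-mean instantaneous frequency.  The baseline 95% CI of frequency (and
  of amplitude in the experiment) is mean ± 1.96·SE across trials of the
  per-trial mean over the −500…0 ms window.  Aggregation is strictly by
  ordinal IMF number, although IMFs are not homogeneous in frequency from
  trial to trial — an alpha component may land in IMF3 on one trial and IMF4
  on another, smearing frequency-specific effects over adjacent ordinals.
* **Classical measures.** ERP: per-trial baseline correction (−200…0 ms),
  trial mean, zero-phase 20 Hz FIR low-pass.  ERD/ERS: zero-phase FIR
  band-pass per trial, Hilbert envelope, trial mean, expressed as percentage
  change from the −500…0 ms mean (amplitude convention, positive =
  synchronization).  Filters are windowed-sinc kernels of order 3× the
  longest period in the band, capped so forward–backward padding fits the
  epoch, applied with `filtfilt`.  Welch PSD: 512-sample Hanning segments,
  50% overlap, averaged over segments and trials (0.98 Hz resolution at
  500 Hz).
* **Task PLS.** Deviation-coded condition means (averaged over subjects,
  centered across conditions) decomposed by SVD.  Permutation p per latent
  variable with condition labels re-shuffled independently within each
  subject and the add-one estimator `p = (1 + #{s* ≥ s}) / (n_perm + 1)`.
  Bootstrap resamples subjects with replacement (degenerate single-subject
  resamples are skipped and counted), sign-aligns the first right singular
  vector to the original by dot product, and reports salience / bootstrap-SE
  ratios.  On null data these ratios are anticonservative (|ratio| > 1.96 at
  ~16–19% of cells, stable across 20–100 subjects): the unit-norm constraint
  plus sign alignment keeps resampled saliences correlated with the original,
  shrinking the SE.  They are a relative reliability ranking, not calibrated
  z-scores; calibrated inference comes from the permutation test (type-I
  error 0.05 ± 0.01 measured over 200 null datasets).

## The discrimination experiment

`run_discrimination_experiment` simulates matched Firefly and evoked datasets
(same spectrum, template = Firefly ERP, sub-seeds 0/1 of the global seed),
decomposes both with EMD, and asks per ordinal IMF whether the trial-mean
instantaneous frequency and envelope leave their baseline 95% bands in the
post-stimulus window (t_start to 1.5 s, minus the 100 ms tail margin).

Before the band comparison the trial-mean series is smoothed with a Gaussian
of σ = 150 ms.  This is a null-calibration requirement, not cosmetics: the
baseline band measures the uncertainty of a 500-ms *mean*, while the raw
trial-mean series fluctuates pointwise with comparable magnitude, so an
unsmoothed null series would sit outside the band at ~30–50% of samples.
Smoothing at 150 ms brings a stationary background mostly inside the band
while leaving the Firefly dips (0.1–0.5 s wide, 5–15% of the IMF's center
frequency) clearly outside.  Two residual effects remain even for ideal null
data and are visible in the reports: (i) slow IMFs (≲3 Hz) carry a
deterministic EMD/Hilbert edge bias that extends far beyond the 100 ms
margin — it reproduces across independent datasets (r ≈ 0.7) — and (ii) the
added ERP template shifts what the EMD assigns to IMF2 post-stimulus by
~2% of its center frequency for ~0.5 s, a mode-reorganization effect of
adding any coherent transient (a fixed 40–80 Hz band-pass shows no such
shift).  Consequently the evoked dataset, whose frequency changes are 5–10×
smaller than the Firefly dips, still spends 20–50% of post-stimulus samples
outside the very tight ±1.96·SE band in some IMFs.  The discriminating
contrast is the *dip* structure: across seeds, all of IMFs 2–5 of Firefly
data dip below their band (first excursion downward, rebound later), evoked
data never show that dip pattern in more than 2 IMFs, and both show the
post-stimulus PLV peak.

### Power conservation

At the 50%-responding default, per-trial variances of the full pre- and
post-stimulus halves are statistically indistinguishable over 100 trials
(ratio 0.96–1.0, Wilcoxon p 0.03–0.99 across seeds).  Two caveats, both
properties of the model rather than bugs: a *late* 1-s window shows a real
deficit because phase alignment concentrates within-trial energy into the
early ERP wave packet while per-frequency amplitudes stay constant; and at
`responding_fraction = 1` the redistribution is large enough (~15% of the
post-window variance, part of it carried past the epoch end by the long
desynchronization ramps of slow oscillators) that the within-epoch power test
rejects equality.  Classic pre/post power tests on finite epochs therefore
probe window choice as much as the generation mechanism.

## Parameter estimation

* **Target phase.** The ERP at target phase φ is exactly
  `Re{e^{iφ} C(t)}`, with `C` the across-trial mean phasor of one fixed-seed
  simulation, because φ enters every cosine additively; the −180°…180° grid
  search therefore shares a single synthesis and a single seed, exactly as if
  each grid point were re-simulated with that seed.  With the reference
  generated from the same seed, recovery is exact to the grid step (the
  closed-loop check); with an independent reference seed, trial-sampling
  noise in the two 100-trial ERPs limits recovery to ±3°.
* **Synchronization times.** Per IMF, the PLV series is smoothed (Gaussian,
  30 ms) so sample noise cannot relocate the peak; `t_synch` is the first
  sample at the post-stimulus maximum and the phase-locked interval is the
  contiguous run within 5% of the maximum, whose end estimates `t_desynch`.
  The peak itself sits *inside* the locked interval and overestimates the
  slope of the √-period law by ~15–25%; the plateau onset (90% of peak)
  tracks the true `t_synch` to within ~10%, so the closed-loop `k_synch` fit
  uses plateau onsets.  Validated by recovering a known `k_synch = 0.5` from
  simulations (errors −1% to +17% over five seeds).  Recovery runs the
  full-response model with a featureless 1/f spectrum: with a strong alpha
  bump, the heavy alpha oscillators sweeping *through* lower bands dominate
  those bands' PLV latencies and mask the per-band law — the same confound
  the ordinal-IMF caution above describes.

## Numerical and design notes

* Seeds: one global seed expands to per-stage sub-seeds through
  `numpy.random.SeedSequence(seed).spawn`, in a fixed documented order;
  identical configuration + seed gives bit-identical output.
* Trials are synthesized per-trial with preallocated buffers (the phase array
  for the default grid is 2499 × 2000); 100 trials take ~10 s on one CPU.
* The artifact-rejection bound is inclusive (|v| ≤ limit retained), joint
  over channels.
* Text I/O writes floats with 17 significant digits; round-trips are
  bit-identical.
* Sub-Nyquist enforcement: grid frequencies ≥ rate/2 are dropped (the default
  grid's 250 Hz top sits exactly at Nyquist for 500 Hz sampling and is
  excluded).
* Ill-posed edge cases raise typed exceptions (`firefly_eeg.exceptions`):
  constant series for correlations/analytic signal, monotonic signals for
  sifting, all-trials-rejected, inconsistent sidecars.

## What the synthetic data do and do not show

The simulator emulates the phase-alignment structure of event-related EEG:
1/f-with-alpha spectra, equal pre/post power, frequency-dependent
synchronization latencies, and the classical ERP / theta-ERS / alpha-ERD
signatures as pure phase phenomena.  It does not emulate measurement noise,
volume conduction or electrode geometry (channels differ only by target
phase and spectrum), slow anticipatory potentials (CNV), condition effects
(old/new memory differences), amplitude asymmetries, or trial-to-trial
latency jitter in `t_synch` — so simulated effects are sharper than real ones
(e.g., double ERP peaks that jitter would blur).  Passing tests demonstrate
internal consistency of model and estimators under these idealized
conditions, not fidelity to any particular empirical dataset.

## Known limitations

* The 100 ms Hilbert edge margin is frequency-independent; for IMFs slower
  than ~3 Hz, edge distortion (Hilbert wrap-around plus mirrored-envelope
  ends) reaches 1–2 periods into the epoch and biases late post-stimulus
  frequency estimates.
* Bootstrap salience ratios are anticonservative under the null (see above).
* The PLV-peak estimator of `t_synch` is biased late at high frequencies;
  extrapolating the √-law there inherits that bias.
* `t_end` for the slowest default-grid oscillators (~4.5 s) exceeds a ±2 s
  epoch, so their desynchronization is truncated; this is why within-epoch
  power conservation is approximate rather than exact at full response.
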