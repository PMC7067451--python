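# Methods

## Signal model and assumptions

Ventilation is modelled as an amplitude-modulated carrier. The carrier
stands for the breath-by-breath airflow oscillation, assumed quasi-periodic
at f_c ∈ [0.25, 0.33] Hz (15–20 breaths/min, adult rest); the modulation
signal is the slow envelope swell of Cheyne-Stokes respiration at
f_m ∈ [8, 30] mHz (one CSR cycle every 30 s – 2 min). Writing the envelope
as

    env(t) = A_c [1 + h cos(2π f_m t + φ_m)],

the modulated signal is y(t) = env(t) H(env(t)) cos(2π f_c t), where H is
the Heaviside step. Only the product h = k·A_m of modulation gain and
amplitude is identifiable, so the model exposes h alone. For h ≤ 1 the
step is inactive; for h > 1 the envelope is clipped at zero — the model's
representation of central apnea — for a closed-form duration
δ = (π − arccos(−1/h)) / (π f_m) per cycle, approaching half the
modulation period as h → ∞. Clipping is applied to the envelope before
multiplication with the carrier, not to the product.

The model is deliberately minimal: constant parameters per regime, a
sinusoidal envelope, no cardio-respiratory feedback (loop gain,
chemoreflex), no SpO₂/CO₂ channels. Its purpose is to make the
demodulation problem exact so that every stage can be validated against
known ground truth.

## Stage 1 — envelope extraction

Breath cycles are segmented by penalized change-point analysis. The signal
is first detrended by subtracting a 30-s running median (mirror-padded at
the edges so the baseline does not track a half breath), since real
ventilation baselines wander and the model is silent about it. The
partition of the detrended signal minimizes the sum of per-section
residual sums of squares about a straight-line fit (capturing slope and
mean jointly in one coherent cost) plus β per change point. The search is
PELT — pruned-exact dynamic programming; pruning is lossless for an RSS
cost, so the result equals the exhaustive O(n²) program, which the test
suite verifies directly on small instances.

β defaults to `PENALTY_SCALE · σ̂² · log N` with σ̂ the
median-absolute-deviation noise estimate from second differences (robust
to the smooth breathing waveform) and a small floor for noiseless inputs.
`PENALTY_SCALE = 6.0` — roughly twice the BIC per-parameter rate for a
section spending three degrees of freedom (slope, intercept, boundary) —
was fixed once on simulated breath-shaped fixtures and is exposed in the
configuration; breath recall/precision on jittered noisy fixtures exceeds
98% at this value and is insensitive to factor-of-two changes, because
peak extraction groups sections into monotone runs rather than relying on
a one-section-per-limb segmentation.

Section filtering follows two physiological rules: sections whose fitted
|slope| is below 10⁻³ per second — measured on the signal normalized by
its 95th-percentile absolute value, since the threshold is only meaningful
on a scale-free signal — are noise; a peak (boundary between a rising and
a falling monotone run) is kept only when both flanking runs last longer
than 1 s, which admits every genuine breath limb at 15–20 cycles/min and
rejects sub-second artifacts. Requiring *both* flanks (rather than their
sum) keeps a spike superimposed on a breath limb from ever becoming a
peak. Peak time and amplitude are the sample maximum over the two runs.

Ventilation interruptions are inter-peak intervals strictly greater than
three times the median inter-peak spacing (the comparison is strict, so a
spacing of exactly 3× is not a gap). The envelope interpolates linearly
through peak amplitudes — peaks only, not troughs, and peak amplitudes
rather than peak-to-trough tidal differences, which is why the detrending
step matters — is forced to zero strictly inside gaps, clipped at zero,
and resampled at fs_env = 1 Hz: the envelope band ends at 30 mHz, so 1 Hz
leaves a ~16× Nyquist margin while giving 120 samples per estimation
window. Time is seconds from recording start; intervals are half-open
[start, end).

## Stage 2 — Matrix Pencil demodulation

On each window the envelope is a three-term complex-exponential sum: a DC
term a₁ = A_c and a conjugate pair a₂ = ā₃ = (A_c h/2) e^{jφ_m} at ±f_m.
The Matrix Pencil method builds a Hankel matrix from the window with
pencil parameter L = round(N/3) (the standard noise-robust third), keeps
the top `order = 3` right singular vectors, solves the shifted-subspace
eigenvalue problem for the poles and a least-squares system for the
amplitudes. Numerical choices:

- singular values below 10⁻⁸ of the largest indicate rank collapse; the
  order is reduced and flagged (a constant window legitimately has one
  component, an all-zero window none);
- estimated poles may sit off the unit circle; damping is discarded and
  the frequency taken from the pole angle, matching the undamped model;
- amplitudes are re-solved on the unit-modulus poles so that |a₂| is not
  inflated by spurious damping;
- under noise the conjugate pair resolves slightly asymmetrically, so
  ĥ = (|â₂| + |â₃|)/|â₁| is used when both members are present, reducing
  to 2|â₂|/|â₁| in the symmetric case;
- the DC component is the pole of smallest |frequency|; if none lies
  within 5 mHz of zero the window has no credible DC term and the
  estimate is invalid;
- ĥ is a ratio and explodes as â₁ → 0, so windows whose DC amplitude
  falls below 1% of the recording's median envelope are marked invalid
  rather than reported.

Windows are 2 min long with 80% overlap (hop 24 s): long enough for the
locally-constant-parameter assumption, short enough to track regime
changes; results on stationary envelopes agree within 5% for windows up
to 4 min. Windows are passed to the estimator as-is — no detrending, the
DC term is part of the model — and a trailing partial window is skipped.
Windows overlapping envelope gaps are estimated as-is too: the clipped
regime is exactly where ĥ > 1 is informative, and validity is governed
only by the DC floor.

On exact model envelopes the estimator recovers h to ~1e-14 and f_m to
~1e-16 Hz; with additive envelope noise of SD 0.05·A_c the median error
of ĥ over 100 windows is below 0.01. On the clipped h = 1.5 envelope the
order-3 fit cannot represent the harmonics introduced by clipping, and ĥ
converges to the ratio of the fundamental to the DC Fourier coefficient
of max(0, 1 + h cos θ) — 1.2275 at h = 1.5, computed independently by
quadrature in the tests — so over-modulation is under-read but the
decisive property ĥ > 1 is preserved.

## Stage 3 — zone detection

A window is flagged pathological when its estimate is valid, ĥ ≥ h₀ and
f̂_m ∈ [8, 30] mHz. Both comparisons are inclusive: the thresholds are
quoted values, and ties count as pathological. h₀ = 0.12 is the
operating threshold selected by ROC analysis (below). Maximal runs of
flagged windows become zones spanning [first window start, last window
end); runs shorter than 60 s are discarded (the one-minute persistence
rule that suppresses artifact-triggered false positives), and zones
separated by less than one hop — adjacent up to estimation granularity —
are merged. Whether sub-minute dropouts inside a zone should split it is
genuinely open; merging only across sub-hop separations is the
conservative reading.

## Stage 4 — classification

With T the total zone duration, E the longest single zone and h̄ the
duration-weighted mean of per-zone mean ĥ (the weighting is a choice; an
unweighted mean differs only when zones of very different lengths carry
very different ĥ): T > 600 s and E ≥ 360 s yield CSR-CSA if h̄ > 1, else
PB; otherwise non-CSR. The cycle-count parentheticals that accompany
these durations in sleep-medicine practice ("at least 5 cycles", "3
consecutive cycles") are commentary on the durations at the slowest
pathological f_m, not an independent rule; only the durations are
enforced. The 10-minute total is interpreted per recording, appropriate
for ~30-min recordings; for overnight signals a per-hour normalization of
T is the natural extension (total_min_s is configurable).

## Evaluation conventions

Minute-level scoring compares detections with three-class expert-style
annotations (CSR/PB, no abnormal pattern, erratic possibly PB); erratic
minutes are excluded from binary counts and tallied separately. A
predicted minute is an oscillation when zones cover at least 30 s of it
(majority rule). Two "specificity" variants are reported side by side:
`sp_as_printed` = TP/(TP+FP), which is the positive predictive value but
is the formula quoted alongside the method's historical performance
figures, and `specificity_conventional` = TN/(TN+FP). ROC analysis uses
the conventional one — an ROC axis requires a true-negative-based rate —
and returns the smallest grid value maximizing the Youden index.

## The simulator as validation ground

The generator emulates: the AM envelope model with per-segment regimes,
envelope-value continuity across regime boundaries (the new segment's
modulation phase is solved from the outgoing envelope value on the rising
branch, so regime changes do not inject spurious steps; an unreachable
value — e.g. a drop to flat mid-swing — still steps, as a real regime
change would), a breath-shaped carrier (raised half-sine inspiration over
40% of the cycle, a longer and shallower expiration balancing each cycle
to zero mean) with uniform ±10% cycle-period jitter, additive white
Gaussian noise, and per-minute ground-truth labels (a minute is
oscillating when ≥ 30 s of it lies in a pathological regime). The default
simulation rate is 25 Hz — clinical acquisitions run higher, but 25 Hz
keeps the 0.3-Hz carrier heavily oversampled while keeping tests fast —
and the standard simulated operating conditions are 30-min recordings,
noise SD 0.05·A_c and jitter 0.1.

Reference cohorts (`csrdemod.cohorts`) mirror the patient profiles of CSR
screening studies: severe CSR oscillating through the whole recording, PB
with one sustained mild episode, normals with slow ±15% amplitude wander
over 1–3-min stretches (healthy tidal volume is not constant; perfectly
flat normals would make any tiny threshold look adequate and rob the ROC
analysis of its object), and short-burst normals whose oscillation is too
brief to classify. On the 15-recording study cohort the pipeline returns
the designed diagonal confusion matrix (4 CSR-CSA, 1 PB, 10 non-CSR) with
minute-level Se = 100% and conventional Sp ≈ 98%; ROC selection on the
threshold cohort returns h₀ ∈ [0.10, 0.14] across seeds, bracketing the
0.12 default.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: obstructive events and mixed apneas, motion
and sensor artifacts beyond white noise, baseline drift beyond what the
running-median detrend removes, sigh breaths, sleep-stage dependence of
breathing rate, and the irregular "erratic possibly PB" patterns human
scorers flag. Minute-level agreement on real recordings will be lower;
the inherent ±1–2 min smear of 2-minute windows at regime boundaries
(a window is flagged if any part of it oscillates, and the zone inherits
the window's full extent) already bounds boundary-minute agreement, which
is why cohort profiles with few regime boundaries are used for the
designed-truth checks.

## Degenerate inputs and edge cases

Empty or sub-3-sample signals, non-positive durations/rates, overlapping
or non-contiguous schedules, non-uniform CSV timestamps and unknown
config keys are rejected with specific errors. Fewer than 3 detected
peaks yields no gaps (with a warning); fewer than 2 peaks makes envelope
reconstruction impossible and raises. An envelope shorter than one window
produces an empty estimate track with a warning, which classifies as
non-CSR with zero statistics.

## Known limitations

- ĥ under-reads over-modulation (clipping bias, quantified above); the
  CSR/PB boundary decision h̄ > 1 is preserved down to h ≈ 1.1 but severity
  grading above 1 is compressed.
- The envelope is built from peak amplitudes at ~0.3 Hz, so modulation
  components above ~50 mHz alias into the band and are not trustworthy;
  the pathological band stops at 30 mHz for this reason.
- Threshold selection needs both classes present in the annotations and
  at least two recordings; single-class references raise.
- Recordings shorter than ~12 min cannot reach the CSR/PB duration
  criteria and always classify non-CSR.
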