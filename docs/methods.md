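# Methods

`ilfs_ecg` implements an ECG-based recognition pipeline for a binary affective
state — the *impulse of love at first sight* (ILFS) versus its absence — from
10-second single-lead ECG trials and per-trial self reports.  This note
records the model, the defaults and the numerical choices, in the order the
method runs.

## Synthetic study generator

Real recordings of this design (10-s photo stimuli, ECG at 1000 Hz, per-trial
ratings) are not publicly deposited, so `synthetic_data` draws whole studies
from an explicit generative model and keeps the ground truth:

* **Tachogram.** RR intervals follow
  `RR_i = mu + A_LF sin(2*pi*0.1*t_i) + A_HF sin(2*pi*0.25*t_i) + eps_i`,
  with `t_i` the cumulative beat time and `eps_i ~ N(0, sdrr^2)`, clipped to
  [300, 2000] ms.  The two modulation frequencies sit at the centres of the
  canonical LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) bands so every spectral
  feature is exercised.
* **Class effect.** Target-state trials shorten the mean RR by `delta_rr`
  (default 80 ms on a 800 ms baseline — a higher heart rate in the target
  state, the direction reported for strong positive arousal).  With the
  default `sdrr` = 40 ms a 10-s trial averages ~12 beats, so the per-trial
  mean RR has a standard error of ~12 ms and the default effect is clearly,
  but not trivially, detectable.
* **Waveform.** A P-QRS-T template of five Gaussian bumps (R amplitude 1 mV,
  dominant) is placed at each beat time; white measurement noise (default
  0.05 mV) is added.  This gives the detector realistic morphology without
  modelling pathology, ectopy or respiration coupling.
* **Ratings.** Conditional on the class: target trials draw impulse intensity
  uniformly from {2, 3} and the four Likert dimensions (arousal, valence,
  dominance, attraction) from N(6, 0.8^2); non-target trials use intensity 0
  and N(2, 0.8^2); all values are rounded and clipped to their scales.

Everything is reproducible bit-for-bit from the integer seed.  Because the
generator has **no between-trial variation of the mean heart rate within a
class**, an injected effect is much easier to classify than a real affective
effect of the same size; passing tests therefore demonstrate that the
pipeline recovers what was injected, not that real data would separate this
well.

## Preprocessing

Recordings are polyphase-resampled from 1000 Hz to a 200 Hz working rate
(Kaiser-windowed FIR, beta 8, half-length 20 taps per output sample: passband
ripple ~1e-7, so resampled test tones match their analytic form), denoised,
and only then segmented, avoiding wavelet edge artifacts inside every 10-s
window.  Trial windows start at the stimulus onset (nearest sample) and are
exactly `round(10 * fs)` samples.

Denoising is a Daubechies-4 discrete wavelet decomposition whose depth is the
smallest level putting the approximation band below 1 Hz (level 7 at
200 Hz); the approximation is zeroed, which removes baseline wander and DC.
The noise scale is estimated once from the finest detail band
(`sigma = MAD/0.6745`), where QRS energy is sparse; estimating it per band
would read the ECG's own morphology as noise and flatten it.  The two finest
detail bands (>~ fs/8; mains and EMG territory) get the full universal soft
threshold `sigma * sqrt(2 ln N)`; coarser detail bands, which carry the
QRS/P/T energy, get a gentler one-`sigma` soft shrink.  This keeps a clean
trace essentially untouched (correlation > 0.999) while strictly reducing
RMSE at 10 dB SNR and emptying the 50 Hz periodogram bin.

## R-peak detection

The classic five-stage chain with its reference constants: zero-phase 5–15 Hz
band-pass, five-point derivative, squaring, 150 ms moving-window integration,
then dual adaptive thresholds (`THR = noise + 0.25 * (signal - noise)`, peak
estimates updated with 1/8 smoothing), a 200 ms refractory period and a
search-back pass triggered at 1.66x the running RR average (half threshold,
1/4 smoothing).  Thresholds initialise from the first two seconds of the
integrated signal (max/2 as the signal estimate, mean/2 as noise).  Accepted
peaks are refined to the band-passed local maximum (±100 ms) and then the raw
local maximum (±30 ms), so reported times align with the R wave itself.
Detection is run per 10-s segment; RR statistics for search-back use the
beats seen so far in the window.

Intervals ≤ 200 ms are treated as false detections (the second peak of the
pair is discarded); intervals ≥ 3000 ms are dropped as missed beats.  Trials
with fewer than two surviving peaks are dropped with a log entry.

## HRV features

Twenty-five features per trial, indices #1–#25 in the fixed order documented
in `hrv_features` (12 time-domain, 7 nonlinear, 6 spectral).  Conventions
that needed a decision:

* sample (n−1) standard deviations for SDRR and SDSD; mean heart rate is the
  mean of the instantaneous `60000 / RR_i`, not `60000 / mean(RR)`;
* quartile deviation is the semi-interquartile range `(Q3 − Q1)/2` with
  linear-interpolation quantiles;
* SD1 uses the population variance of the successive differences,
  `sqrt(var_pop(diff)/2)` — the Poincare-plot convention — and SD2 follows
  from the rotation identity `SD1^2 + SD2^2 = 2 SDRR^2`; the ellipse axes
  `T = 4 SD1`, `L = 4 SD2` give CSI = L/T, CVI = log10(L*T) and modified
  CSI = L^2/T.  A constant series makes these ratios NaN and the trial is
  later excluded;
* Lempel–Ziv complexity binarises RR at its median (≥ median → 1), counts
  exhaustive-history (LZ76) phrases c(n) and normalises by `c(n) log2(n)/n`,
  so the value depends only on the rank pattern;
* spectral powers come from the Lomb–Scargle periodogram of the unevenly
  sampled (beat time, RR) pairs after mean removal — a 10-s window has too
  few beats for resampled Welch estimates — integrated by trapezoid on a
  shared 0.04–0.4 Hz grid that contains the 0.15 Hz edge, so LF + HF = TP
  exactly.  Powers are on a variance scale (a pure modulation of amplitude A
  integrates to about A^2/2).

A 10-s window cannot truly resolve the 0.04 Hz lower band edge; the band
definitions are kept as stated and this limitation is accepted rather than
patched, so LF/TP values on short windows are best treated as relative.

## Labeling and outlier screening

A trial is a **target** sample when the reported impulse intensity is 2 or 3
*and* all four Likert dimensions are ≥ 5; a **non-target** sample when the
intensity is 0 and all four dimensions are ≤ 3; everything else — including
intensity 1 — is excluded.  The cut-offs sit symmetrically around the scale
midpoint 4 and are configurable.

Outliers are removed per feature *within each class* by the MAD rule: with
`MAD = median_i |x_i − median_j x_j|`, a value is an outlier iff
`x ≤ median − 5 MAD` or `x ≥ median + 5 MAD` (closed bounds: boundary points
are removed), and a trial is dropped if any of its features is flagged — the
conservative sample-removal reading.  A zero MAD (at least half the values
tied, common for count features like NN50 on short windows) disables the
rule for that feature rather than deleting the bulk of a class.  Rows with
NaN sentinels are dropped before screening.

## Feature selection and nested evaluation

The criterion `J(F)` is the mean stratified k-fold (default 10) CV accuracy
of a classifier restricted to subset F; folds shrink to the minority-class
size when needed, and the fold seed is fixed and logged.  SFFS alternates a
forward inclusion (add the `f+` maximising J, ties to the lowest feature
index) with conditional backward exclusions: remove the `f−` whose removal
maximises J whenever that strictly beats the best subset of the smaller size
already recorded, never removing the feature just added.  Each distinct
subset is evaluated once (cache), the full J(k) curve for k = 1..k_max is
recorded, and the reported best subset attains the curve maximum (smallest
size on ties).  The self-referential phrasing sometimes used to describe the
exclusion step is resolved to this standard floating form.

Nested evaluation runs the entire selection inside each outer stratified
10-fold training split and scores the refit classifier on the outer test
fold; outer test data can never influence the subset chosen for its fold,
which the tests verify by reproducing each fold's subset from its training
data alone and by checking that a zero-effect simulation stays at chance.

## Classifiers and metrics

Five classifiers behind a training-set-standardised pipeline: RBF SVM (C = 1,
gamma = 'scale'), random forest (100 trees), Gaussian naive Bayes, k-nearest
neighbours (k = 5) and a CART decision tree (gini, unlimited depth) — fixed,
overridable defaults, since no canonical settings exist for this task.  The
target state is the positive class, so sensitivity measures how well the
impulse itself is detected.  Se/Sp/ACC/F1 are computed from confusion counts
pooled over (outer) folds — fold-wise values are kept alongside — and AUC is
the rank-based (Mann–Whitney) area over the pooled continuous scores.

Per-feature group comparison uses the two-sided rank-sum (Mann–Whitney) test:
the two groups are unpaired trial sets, so the independent-samples form is
the correct one; a paired signed-rank variant is available behind a flag for
matched designs.  All-tied features report p = 1 with a warning.

## Problem sizes used by the test suite and acceptance script

The heavy checks are sized to run comfortably on a single CPU: simulated
studies use 10 subjects x 20 trials (200 trials per seed); the nested-CV
null calibration pools 10 simulation seeds and runs selection to k_max = 2
with 3-fold inner criteria and a 10-tree forest (chance-level calibration
does not depend on ensemble size or subset depth); the selection-optimality
check compares SFFS against exhaustive search over all 255 subsets of
8-feature problems on 20 instances; the acceptance script reports the
effect-recovery study, a pooled three-seed null accuracy, and nested
selection with k_max = 3, 3-fold inner criteria and a 30-tree forest.

## Known limitations

* The generator's trials are statistically independent given the class; real
  repeated-measures data have subject-level correlation.  Per-trial CV
  splitting is the default; subject-wise grouping would be the conservative
  choice for real data.
* Waveform realism is limited to a fixed Gaussian-bump template: no ectopy,
  arrhythmia, electrode artefacts or respiration coupling, so detector
  scores here are upper bounds for real recordings.
* Classification accuracy on the default synthetic effect approaches 1.0 —
  far above what heterogeneous human data yield — because the injected
  effect is homogeneous; the pipeline's discrimination claims should be read
  through the null-calibration and effect-recovery tests, not the absolute
  accuracy.
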