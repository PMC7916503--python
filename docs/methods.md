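# Methods

This note documents the models, estimators and protocol implemented in
`drowseeg`, the choices made where the design was genuinely open, and what
the synthetic data can and cannot show.

## The synthetic session generator

The generator emulates the structure of a monotonous driving-simulator
experiment: a 16-channel 10-10 montage (Fp1, Fp2, Fz, F3, F4, Cz, C3, C4,
T7, T8, FT9, FT10, Pz, P7, P8, Oz) sampled at 512 Hz for 65 min by
default, with forced lateral-move events at i.i.d. uniform intervals of
5–19 s. Each event carries a 5-level drowsiness score; levels 1–2 map to
*awake*, 4–5 to *drowsy*, and the median level 3 carries no binary label
and is excluded downstream.

**Latent state.** Real drowsiness dynamics are unknown, so the generator
uses the simplest trajectory that makes ground truth unambiguous: a
two-state piecewise-constant process. Each state segment starts with a
270-s *guard* (the longest supported epoch length) followed by a *labeled
zone*; events inside a guard would have pre-event windows straddling a
state change and are therefore scored level 3. Awake and drowsy labeled
zones alternate with lengths `2 · labeled_zone_s · (class share)`
(`labeled_zone_s` = 400 s by default), so the labeled-event balance
converges to `drowsy_fraction` (default 0.5) deterministically, without
subsampling. A configurable 5% of in-zone events also score level 3, to
exercise the label-omission rule.

**Signal.** Per channel, independently: a 1/f^β Gaussian background
(β = 1) plus, per band, unit-variance band-passed Gaussian noise scaled by
the square root of the active state's band weight. Default weights are
awake = 1 in all bands (gamma 0.5) and drowsy = theta ×2, alpha ×2,
beta ×0.5 — the drowsiness signature the analysis exploits (elevated
theta/alpha, reduced beta relative power). `effect_channels` restricts the
state dependence to a channel subset, which is how area-localization
experiments inject a posterior-only effect. Amplitudes are clipped at ±25
(never active in practice with unit-variance components; the bound exists
as an explicit invariant).

**What this does not model:** eye-blink/EMG artifacts, mains interference,
electrode pops, volume-conduction correlations between channels,
non-stationary drift of the background, or any behavioral signal. Passing
tests on this generator demonstrate that the pipeline recovers
band-power-mediated state differences under clean conditions; they do not
certify performance on human EEG.

## Preprocessing

Fixed order: read → resample to 512 Hz (polyphase, anti-aliased) →
per-channel z-scoring over the whole recording → drop the first 60 s
(synchronization cues and filter transients) → cut epochs. Normalization
precedes the exclusion; for recordings this long the alternative order
changes values negligibly. Epoch windows are half-open `[event − L,
event)` — the event-onset sample is excluded — and epochs overlapping the
excluded lead are dropped rather than truncated, because the nonlinear
estimators need fixed-length input. Sub-band filtering uses order-4
Butterworth sections applied forward–backward (zero phase, effective
order 8). The delta band starts at 0.5 Hz so every sub-band filter is a
proper band-pass; gamma ends at 50 Hz, the acquisition band edge.

I/O: EDF (16-bit, one signal per channel, µV) via a minimal writer and
mne's reader, or delimited text (comma separator, header row of channel
labels, one row per sample; sampling rate supplied by the caller).

## Feature definitions and numerical choices

**Spectral.** Single-taper Hann periodogram of the mean-removed epoch,
density-scaled so the integrated PSD matches the signal variance. Band
power integrates the PSD over `[f_lo, f_hi)` by the rectangle rule. The
"frequency" feature is the within-band *peak* frequency (the source
definition is ambiguous between peak/median/mean; peak is the common
reading), with ties broken toward the lower bin. Gravity frequency is the
in-band spectral centroid; frequency variability is the power-weighted
spectral SD (its reference formula is not reproducible from the source, so
this standard moment definition is the package's documented choice). The
six ratio features are the C(4,2) ordered pairs (lower band / higher band)
over {delta, theta, alpha, beta}; the 5-band reading would give 10 pairs
and contradict the fixed total of 26 = 4×5 + 6. A configurable floor
(default 0) can be added to both ratio terms; a zero denominator yields
NaN, never infinity.

**Higuchi FD.** Curve lengths `L_m(k)` use the Gauss-bracket count
`[(N − m)/k]` and normalization `(N − 1)/([(N − m)/k]·k)/k`; subseries are
built for k = 2..k_max (k_max = 8) as defined, and the regression grid
additionally includes k = 1 (whose L(1) is the raw curve length) for
stability — both grids are available (`include_k1`). Constant series give
NaN.

**Generalized Hurst.** First-order increment moments at τ = 1..19 samples,
least-squares slope in log-log, all τ weighted equally, no smoothing. The
raw first moment is used (not a normalized ratio; the cited variant is not
reproducible). Estimates are clipped to [0, 1] with a reportable flag.

**Spectral entropy.** Implemented exactly as defined, dividing by the
in-band bin *count* N_f (so a flat spectrum gives ln(N_f)/N_f, not 1).
The conventional ln(N_f) normalizer is available via
`normalizer="log_count"`; the count form is the default for fidelity.

**Permutation entropy.** Order n = 4, lag 1, natural log, on the sub-band
series resampled (anti-aliased) to 64 Hz, so lag 1 means 1/64 s. Relative
frequencies are taken over all T − n + 1 sliding windows. Ties rank by
position (stable sort), the standard Bandt–Pompe convention; the synthetic
signals are continuous, making ties measure-zero. A minimum of 100 windows
is required by default (overridable), as shorter series give meaningless
pattern statistics.

All 16 nonlinear features and the 6 ratio features are invariant to
positive amplitude scaling (log-log slopes and normalized distributions),
so they are insensitive to the normalization step by construction.

## Selection and models

The "generalized Fisher score" named by the source is, as used there, a
univariate ranking filter; the univariate score
`Σ_c n_c(μ_cj − μ_j)²/Σ_c n_c σ²_cj` is implemented (population variances,
classes awake/drowsy). Ranking is computed on the optimization set only —
the source does not say, but anything else leaks the test set. Features
with zero within-class variance rank first (+inf) with a warning.

Splits are stratified (the source says only "random division"; unstratified
splits degenerate at small n): 2/3 optimization, 1/3 test, then stratified
5-fold CV inside the optimization set, all driven by one integer seed
through `numpy.random.SeedSequence`. The feature count k* is the smallest
k minimizing the mean CV MSE of 0/1-coded predictions — literally the
misclassification rate, implemented as MSE so other label codings remain
correct. The k grid is configurable; sweeps over large concatenated
feature sets use a coarse grid (e.g. 1, 2, 3, 5, 8, 13, 21, 34, 42)
because CV error as a function of k is smooth at these sample sizes.

RF: scikit-learn `RandomForestClassifier`, 128 trees, bagging, seeded;
default per-split feature subsampling is accepted and recorded in
provenance. SVM: RBF kernel with C and γ from a 30-draw random search, C
log-uniform on [1e−2, 1e3], γ log-uniform on [1e−3, 1e1] scaled by
1/n_features, scored by the same 5-fold CV MSE; features are standardized
with optimization-set statistics inside the pipeline. The search runs once
per evaluation (on all ranked features) and the tuned pair is reused
across the k grid and the final fit — tuning inside every (k, fold) cell
would multiply cost by the grid size for no observed change in k*. k* is
selected per model family.

## Experiments

Area groupings: F = {Fp1, Fp2, Fz, F3, F4}, C = {Cz, C3, C4},
T = {T7, T8, FT9, FT10}, PO = {Pz, P7, P8, Oz}. Only PO is fully fixed by
the montage description; Fz's membership in F is configurable. Area
feature vectors concatenate per-channel features (4-channel area × 16
nonlinear features = 64 columns), they are not channel averages. One
held-out test split per seed; no repeated outer CV. Report tables follow
the units × (length × feature set) layout with a final arithmetic-mean row,
and across-seed summaries report mean/SD (SD marked `n/a` for single
seeds).

Learning curves fit `accuracy(n) = a − b·n^(−c)` by bounded
Levenberg–Marquardt (trust-region reflective) least squares, a ∈ [0, 100],
b ≥ 0, c > 0, initialized at (max accuracy + 1, 30, 0.5); ≥ 4 distinct
sample sizes are required for the 3 parameters.

## Problem sizes used in tests

The test suite and examples run on scaled-down sessions chosen once:
1–2 channels, 1500–2400 s (≈ 50–100 labeled events), 30-s epochs, with the
end-to-end recovery experiments using a strong effect (drowsy theta/alpha
×3, beta ÷3) over 10 session seeds and null sessions with identical state
weights over 5 seeds. Estimator calibration uses 200 Brownian series of
15,360 samples (= 30 s at 512 Hz) for the Hurst exponent and 100
realizations of 4,096 samples for the Higuchi references. These sizes give
sampling errors comfortably inside the asserted tolerances (e.g. the
Brownian Hurst mean has SE ≈ 0.002 against a 0.05 band).

## Known limitations

- The generator's two-state model cannot produce gradual drowsiness
  transitions, so transitional-state behavior is untested.
- Channels are statistically independent; spatial structure beyond
  "effect present/absent per channel" is not modeled, so area results
  reflect feature concatenation, not realistic cross-channel correlation.
- The EDF writer covers only the subset needed for round trips (1-s
  records, integer sampling rates, 16-bit linear scaling).
- `higuchi_fd` and `generalized_hurst` assume uniformly sampled input and
  are undefined on constant series (NaN, propagated and dropped with a
  logged count before model fitting).
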