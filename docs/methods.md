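# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of the `oxiscreen` pipeline. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and windowing

A recording is two synchronized channels: SpO₂ at 1 Hz (0.1% resolution)
and PPG at 62.5 Hz. Analysis uses 2-minute windows with a 1-minute hop,
aligned to the SpO₂ clock; the PPG segment of a window is the co-temporal
slice (start time × 62.5, rounded to the nearest sample). The final
partial window is discarded, so a recording of duration `D` yields
`floor((D − 120)/60) + 1` windows. Recordings shorter than 3 h are
flagged, not rejected (rejection is a CLI option): the screening
statistics assume a reasonable sample of the night.

Subjects are labelled SDB when the reference apnea–hypopnea index (AHI)
is ≥ 5 events/hour; the threshold is configurable because the clinical
cut-off is a continuum, not a constant.

## SpO₂ cleaning

Samples outside [50, 100] % and changes greater than 4 percentage points
are artifacts. The jump rule compares each sample against the last
*retained* sample, so an isolated spike masks only itself: a recovery
sample within 4 points of the pre-spike level survives. This choice
preserves the recovery limbs of genuine desaturations; comparing against
the raw predecessor would cascade masks after every spike. Masked samples
are excluded, never interpolated, from all time-domain statistics — with
one exception noted under the spectral features.

A window is invalid for SpO₂ features when more than 20% of it is masked.

## SpO₂ features (per window)

* **Basic statistics** — mean, median, sample SD, IQR of retained samples.
* **Δ index** — mean absolute difference between consecutive 12-s block
  means (the classic delta-index block length); blocks need ≥ 1 valid
  sample, and ≥ 2 blocks are required.
* **n2%** — count of maximal runs ≥ 3 s in which SpO₂ sits ≥ 2 points
  below a running baseline (median of the preceding 60 s of valid signal,
  initialized with the window median). The adaptive baseline tolerates
  slow drift; the 3-s minimum suppresses quantization flicker.
* **t92% / t94%** — seconds strictly below the saturation threshold.
  The default is 92%; 94% is exposed because both conventions exist, and
  the feature column is named after the threshold in use (`t92`/`t94`).
* **ApEn / SampEn** — embedding m = 1, tolerance r = 0.25 × window SD,
  Chebyshev distance. ApEn includes self-matches (Pincus); SampEn
  excludes them and both template lengths use the first n−m starting
  positions, returning an explicit undefined sentinel (NaN) when no
  matches exist. Entropies are computed on the retained samples at the
  oximeter's native 0.1% resolution — regularity values are strongly
  resolution-dependent, so the signal is never re-quantized.
* **CTM** — fraction of successive-difference scatter points
  (x[i+1]−x[i], x[i+2]−x[i+1]) with Euclidean norm < 0.25 (% units).

## Autoregressive spectra

The AR(p) model `x(n) + Σ aₖ x(n−k) = e(n)` has one-sided PSD
`S(f) = 2σ²T / |1 + Σ aₖ e^(−i2πfkT)|²` on (0, 1/(2T)]; the factor 2
folds negative frequencies so the PSD integral approximates the process
variance (verified within 10% on stable synthetic AR processes).

Coefficients are estimated with Burg's method — well suited to
120-sample segments and minimum-phase by construction — in a single
recursion sweep that yields every order up to the cap, making the
Rissanen MDL search `MDL(p) = N ln σ²ₚ + p ln N` over p = 1..30
essentially free. The PSD is evaluated on 256 uniform bins over
(0, 0.5] Hz, so the spectral Shannon entropy (log₂) has an 8-bit
ceiling. A model whose characteristic roots leave the unit circle by
more than a numerical tolerance (10⁻³; Burg cannot produce genuinely
unstable fits, so this only catches degenerate root-finding) falls back
to the next-best MDL order and is flagged.

Spectral analysis needs a uniform grid, so masked samples are linearly
interpolated *only* inside a window and only across gaps ≤ 5 s; windows
with longer gaps are invalid for spectral features. Long interpolations
would fabricate low-frequency power exactly where the modulation band
lives.

**Modulation band** — the peak of the PSD within 0.005–0.1 Hz is the
modulation frequency; P integrates the PSD (trapezoid, with band edges
interpolated onto the grid) over a 0.02 Hz interval centred there and
clipped to the band; R = P / total power (grid extended to f = 0 with the
model's DC ordinate); SE is the Shannon entropy of the normalized PSD
ordinates. Integration (rather than summing raw ordinates) makes P an
honest power in %²; R is invariant to amplitude scaling and P scales
quadratically, both verified by tests.

## PPG conditioning and quality gate

Baseline removal is a two-stage running-median cascade: a 127-sample
(~2 s) median removes offset and drift, and a 63-sample median on the
residual removes respiratory-band wander that a 2-s window is too wide to
track. Median detrending is shift-free and positively homogeneous, which
keeps the downstream zero-crossing detector's reference level honest; the
cascade was adopted after a single-stage median left enough ~0.25 Hz
wander to corrupt beat detection. Smoothing is Savitzky–Golay, order 3,
frame 11 samples.

The signal-quality index (SQI) is beat-template correlation: detected
beats are excised around their peaks, averaged into an ensemble template,
and the SQI is the mean per-beat Pearson correlation with that template
(negative correlations clipped to zero). A window is rejected as
`motion` when SQI < 0.7, as `insufficient_valid_samples` when plausible
pulse intervals cover < 50% of the window, and as `flatline` when there
is no amplitude or no detectable pulse. On synthetic data the SQI
decreases monotonically with the injected artifact fraction.

## Pulse-rate variability

Pulse peaks come from a simple zero-crossing detector: each upward zero
crossing paired with the next downward crossing emits the maximum sample
in between. Candidates closer than a 0.25 s refractory period (shorter
than the shortest legal pulse interval) are merged, absorbing
dicrotic-notch double crossings, and candidates smaller than 0.3 × the
75th-percentile candidate amplitude are discarded as wander-induced dwarf
crossings.

Successive-peak intervals outside [0.33, 1.5] s are censored; the series
is *not* re-linked across a deletion. RMSSD therefore uses only
differences between adjacent retained intervals, and the Berger
resampler treats censored stretches as gaps: the cumulative-interval
count function (piecewise linear, one unit per interval) bridges a gap
≤ 3 s with a single low-rate span, while longer gaps invalidate the
window. The Berger series itself evaluates, at each 4 Hz tick, the
fractional number of intervals inside a two-output-sample window divided
by its width; the stored value is the instantaneous interval (1/rate).
Time-domain features (RR, SDNN, RMSSD) use the raw retained intervals;
frequency-domain features use the resampled series — the natural split,
since resampling smooths exactly the short-scale structure RMSSD
measures.

The PRV spectrum is a fixed AR(16) on the demeaned 4 Hz series (≥ 64
samples), evaluated on 256 bins over (0, 2] Hz. Band powers (VLF
0.01–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz) are trapezoid integrals with
interpolated band edges, so LF + HF exactly equals the 0.04–0.4 Hz
total and the normalized powers sum to one by construction. VLF is
reported but excluded from normalization.

## Overnight aggregation and group statistics

Each windowed feature is summarized over the night by mean (M), median
(Me), SD (S), and IQR (I) over the windows where it is valid, giving 68
aggregates per subject (17 features × 4 statistics, named `M_P` …
`I_RMSSD`; the LF/HF ratio renders as `LF_HF`). A subject is usable when
at least `min_windows` windows are valid (default 60 ≈ 1 h at 1-minute
hop, mirroring a 3-h usable-signal requirement scaled to window count).

Group comparison per feature: Shapiro–Wilk in each group; if both pass
(p > 0.05), Welch's unequal-variance t-test with a 95% CI; otherwise the
Welch test runs on log-transformed data — or Box–Cox (λ by maximum
likelihood, fitted on the pooled data, with a half-minimum-positive
shift) when the feature contains zeros, since the log is then undefined —
plus a Mann–Whitney U test on the original data. The Bonferroni family is
the set of features entering the comparison (recorded in the output);
flags use the Welch p-value on the analysis scale against α/m. Groups
whose values are exactly identical return p = 1 rather than crashing.

## Screening model

The classifier is a two-class pooled-covariance linear discriminant with
priors (0.4, 0.6) — the SDB prior matching a ~39% referral-population
prevalence — and decision threshold posterior ≥ 0.5. Features are
z-scored with training means/SDs (LDA is affine-invariant in exact
arithmetic; scaling stabilizes the covariance inverse), and a singular
pooled covariance falls back to a flagged ridge.

Feature selection is greedy forward search over the features significant
in a training-fold group comparison (raw p < 0.05 — the uncorrected gate
keeps the pool permissive; the selection itself provides the real
control). Each candidate subset is scored by leave-one-subject-out AUC
of the discriminant, computed exactly via rank-one downdates of the
class means and pooled scatter (a batched k×k solve per left-out
subject), with mid-rank tie handling in the AUC. Ties in AUC gain break
by larger Mann–Whitney effect size, then lexicographically. Selection
stops at 15 features; the subset size with the best internal AUC is the
fold's model.

The external loop is stratified 4-fold CV (stratification guarantees
both classes in every fold at a 38% prevalence); test subjects never
enter the gate, the selection, or the fit of their fold. Features
selected in ≥ 3 of 4 folds form the consensus set, refit on all data for
the final model (refitting is the default; a flag keeps the per-fold
models instead). When no feature passes the gate — routine under
permuted-label null runs — the few smallest-p features enter instead, so
null performance is still estimable; the fallback is logged in the
report.

Metrics are confusion-table based (Acc, Sn, Sp, PPV, NPV, referred
fraction) with zero-denominator ratios reported as undefined, plus
trapezoidal ROC AUC.

## Synthetic data: what it emulates, and what it does not

The generator produces exactly the structure the feature chain measures:

* **SpO₂** — baseline 97% with slow AR(1) noise (SD 0.25%), quantized to
  0.1%, plus trapezoidal desaturations (10 s fall, plateau, 15 s
  recovery, ~28 s total; depth ~4 ± 1% in SDB-like subjects) arranged in
  pseudo-periodic trains (default 8 events per train, period 33 s ⇒
  modulation frequency 0.03 Hz, jittered 10%). Trains occupy
  non-overlapping slots of the night; the planted event rate doubles as
  the reference AHI (SDB group 20/h, NonSDB 1.4/h — the reported group
  AHI means of screening cohorts of this kind).
* **PPG** — beats rendered as a fixed asymmetric two-Gaussian pulse
  (systolic peak + dicrotic hump), with interval modulation from
  respiratory sinus arrhythmia (0.25 Hz; depth 5.0–5.5%), a
  low-frequency oscillation (0.1 Hz; depth 3.7% SDB vs 3.0% NonSDB),
  beat-to-beat jitter (1.5%), and — in SDB subjects — a biphasic
  tachycardia/bradycardia swing (6%) time-locked to each planted
  desaturation. Baseline wander (0.23 Hz), drift, measurement noise,
  and optional motion bursts (band-limited high-amplitude noise
  replacing ~2% of the night) complete the channel.
* **Cohorts** — per-subject log-normal jitter (σ 0.05–0.3 by parameter)
  around the group configurations, with the planted AHI clipped to the
  subject's side of the labelling threshold so labels and group
  membership agree. Default sizes 56 SDB / 90 NonSDB (38% prevalence).
  One seed determines everything.

Not emulated: real cardiorespiratory coupling, sleep architecture
(REM/NREM), PPG morphology beyond what peak detection needs, sensor
physics, or inter-night variability. Passing tests therefore show that
the chain recovers planted structure of realistic magnitude through
realistic nuisance (quantization, artifacts, wander, jitter) — not that
the classifier's synthetic-cohort AUC transfers to clinical data. The
synthetic groups are more cleanly separated than a real referral
population, so cohort AUCs near 100% are expected on synthetic cohorts
and say nothing about clinical AUC.

## Problem sizes

Cohort-level experiments (test suite and acceptance script) simulate
146-subject cohorts with 1.25 h recordings per subject and a usable-window
minimum of 28 (the 3-h-of-8 rule scaled to the shorter night), keeping a
full cohort extraction near one minute; single-recording analyses use
10–30 min signals. Generator defaults keep the full 8-h night for
realistic standalone use. These sizes are the package's choice of test
economy; effect sizes, rates, and noise levels are never scaled.

## Numerical notes

* Quantization is decimal-correct (`round(x·10)/10`), and the EDF writer
  maps one digital unit to one 0.1% step with integer-anchored scaling,
  so CSV and EDF round-trips of saturation values are bit-exact; EDF
  quantizes the PPG to 16 bits of its own range.
* CSV reads use round-trip float parsing; feature tables reload
  bit-for-bit.
* Percentiles/IQR use linear interpolation; SD/SDNN use ddof = 1.
* The LOO downdate adds a 10⁻⁹-scaled ridge before each batched solve to
  tolerate duplicated candidate features during forward selection.
* All simulations and cross-validation partitions are driven by explicit
  seeds; identical seeds reproduce results bit-for-bit.
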