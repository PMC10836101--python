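# Methods

## Scope and data model

The pipeline operates on epoched multichannel EEG in microvolts
(`EpochedRecording`: channels × epochs × samples, with sampling rate, channel
labels and montage identity) and on participant-level feature tables
(pandas DataFrames with `participant_id`, `group`, `sex`, `mosaic` metadata
followed by named EEG variables). Artifact removal is assumed to have
happened upstream; epochs containing non-finite samples are dropped with a
logged count. Analysis stays in sensor space.

## Resting spectral features

Spectra are one-sided magnitude FFTs of periodic-Hann-windowed,
non-overlapping 2 s epochs, normalized so a grid-aligned unit sinusoid reads
1 µV in its bin. 2 s epochs fix the grid at 0.5 Hz. Magnitudes are averaged
over epochs, then over a region's channels.

Band edges are configurable; the defaults are the conventional
delta 1–4, theta 4–8, low alpha 8–10, high alpha 10–13, beta 13–30,
low gamma 30–55 and high gamma 65–90 Hz (low edge inclusive, high edge
exclusive), with 55–65 Hz excluded from the analyzed set as a line-noise
notch. The relative-power denominator is the total over analyzed bins only,
so the seven bands partition it and relative values sum to exactly 1 per
region. Absolute values are band sums of bin amplitudes reported ×10⁶
(picovolt scale).

Peak alpha frequency is the raw log-power argmax on the 0.5 Hz grid within
6–14 Hz, ties broken toward the lower frequency. No 1/f detrending is
applied by default (an optional flag fits and removes a log-log line first);
when the argmax lands on a window edge — i.e. there is no interior alpha
peak — an `EdgePeakWarning` is raised rather than silently returning the
edge bin.

Frontal/posterior quadrant membership for the dense 128-channel geodesic
montage and the 20-channel 10–20 montage ship as editable conventions in
`fxseeg.montages`; they are configuration, not measured geometry.

## Chirp time-frequency features

Trials are averaged across a fronto-central sensor cluster (default: a named
23-channel set on the dense montage; any label set is accepted) before the
wavelet transform — cluster averaging before transforming matches the
steady-state-response convention and raises SNR for the phase measures.

The Morlet transform uses a 1 Hz grid from 2 to 100 Hz (the lower bound is
set by trial length) with cycle counts increasing linearly from 1 at the
lowest frequency to 30 at the highest; wavelets are truncated at ±4σ and
normalized so an amplitude-A sinusoid yields |coefficient| ≈ A.
Time-frequency points whose wavelet support overruns the trial are marked
invalid and excluded from all aggregations. The transform output may be
decimated in time (default keep-every-10th in the high-level extractor);
decimation subsamples the full-rate convolution, it does not low-pass.

ITPC is the plain resultant length of unit phase vectors across trials —
"scaled to critical R" is read as this [0, 1] resultant; an optional
Rayleigh-critical normalization is deliberately not the default, since the
plain resultant is the quantity with closed-form expectations
(wrapped-normal jitter σ ⇒ ITPC → exp(−σ²/2); uniform phases ⇒
E|R| ≈ √π/(2√N)). Zero-magnitude coefficients carry no phase and are
excluded with a logged count.

Single-trial power is 10·log₁₀ of the trial-mean squared magnitude (µV²);
the base-10 decibel convention was chosen over the natural log (the printed
theta magnitudes of ~22–24 do not disambiguate the two) and is isolated in
one place. Evoked (baseline-corrected) power subtracts the per-frequency mean
log power over a pre-onset window, so post-onset desynchronization is
negative.

The seven regions of interest default to: onset ITPC 4–13 Hz × [0, 0.5] s;
offset ITPC 4–13 Hz × [2.0, 2.5] s; low-gamma chirp ITPC as a diagonal mask
±10 Hz about the instantaneous sweep frequency f(t) = 50·t within 30–50 Hz;
high-gamma likewise within 70–90 Hz; theta and gamma STP over the full trial
at 4–8 and 30–90 Hz; evoked alpha 8–13 Hz × [0, 2] s against a [−0.5, 0] s
baseline. The published ROI geometry exists only graphically, so all ROIs
are configurable.

## Classifier

Gaussian naive Bayes, written from scratch. Class-conditional means are
sample means; variances use the unbiased n−1 denominator (the plug-in n
denominator is available via `ddof=0`) and are floored at
max(10⁻¹², 10⁻⁹ × pooled feature variance) so near-constant features (e.g.
clipped relative power) cannot blow up the likelihood. Posteriors are
computed in log space with log-sum-exp normalization; priors are fixed at
0.5/0.5 regardless of subgroup imbalance (override available). An exact
posterior tie at 0.5 is classified as control. Missing feature values are
rejected, not imputed. Models serialize to human-readable YAML for audit.

scikit-learn's `GaussianNB` serves only as an independent cross-check in the
test suite (posterior agreement within 10⁻⁶ on random instances), never as
the implementation.

## Evaluation protocol

- 70/30 split, stratified by class, with the per-class training count
  rounded to the nearest integer (70 + 71 participants → 49 + 50 train,
  21 + 21 test). Nearest rounding rather than flooring is what reproduces
  those published counts.
- AUC is the rank statistic (probability a random case outscores a random
  control, ties ½), which equals trapezoidal integration of the empirical
  ROC; the test suite asserts that identity to 10⁻¹². Holdout AUC comes from
  the withheld 30%; "entire dataset" AUC applies the same model back to all
  rows and is therefore in-sample — the report marks it as such.
- Cross-validation is stratified 10-fold (plain k-fold would risk empty
  classes in the small subgroups); folds shrink to the smaller class size
  with a warning when needed.
- Confusion matrices count full-dataset predictions at the 0.5 posterior
  threshold (forced by equal priors); a flag switches them to holdout-only.
- Every report row records the seed that produced it.

A subtlety worth noting: with unequal class variances the naive-Bayes
posterior is a quadratic function of a univariate feature, so its AUC can
legitimately exceed the raw-score closed form Φ(Δμ/√(σ₁²+σ₂²)). The tests
therefore check the raw rank-AUC against Φ and the posterior-score AUC
against a Monte-Carlo likelihood-ratio reference computed independently.

## Study orchestration

Stage 1 evaluates all 65 a-priori variable sets (25 absolute, 25 relative,
4 alpha-peak, 11 chirp) on the full cohort. Stage 2 selects the top two per
family by full-dataset AUC — the column the narrative results quote — with
cross-validation error and then name as tiebreaks. Stage 3 re-runs the
selected sets on males, females, and non-mosaic FXS males vs male controls;
subgroup comparisons never mix sexes, and absolute power is not pursued at
the subgroup level by default (flag to force). Stage 4 re-evaluates the best
resting (set, subgroup) per family on a 20-channel clinical montage.

Montage reduction selects the nearest mapped sensor for each 10–20 target
channel rather than interpolating: down-sampling should only use signals the
clinical montage would actually record. When the study runs on feature-level
simulated cohorts (the default), the montage stage re-draws the selected
subgroup from the same group statistics under a derived seed — for a
spatially uniform field, quadrant means are montage-invariant, so the
re-draw models an independent re-measurement; with signal-level input the
recording is reduced and features re-extracted.

## Synthetic data

The feature-level generator draws each participant's features independently
from class-conditional distributions parameterized by published group means
and SDs — independence across features is exactly the downstream
classifier's assumption, and the printed tables contain no correlation
structure to calibrate against. Bounded variables are drawn from
moment-matched bounded families: a gamma law anchored at the near bound when
only one bound is within 4 SD (several absolute-power cells have a
coefficient of variation above 1, which no truncated Gaussian can match),
a moment-matched truncated normal when both bounds bind, and a plain
Gaussian otherwise. Simple clipping was rejected because its truncation bias
(up to ~3 standard errors at n = 5000 for ITPC-like cells near zero) would
break mean recovery. Default cohort composition mirrors the study samples:
resting 70 FXS (26 non-mosaic males, 12 mosaic males, 32 females) vs 71 CON
(41 M / 30 F); chirp 57 FXS (28 + 9 + 20) vs 57 CON (34 M / 23 F). The
source counts are internally inconsistent by one participant between text
and tables, so all stratum sizes are parameters. Mosaic males are drawn from
the all-male FXS statistics (no mosaic-specific columns are published),
which makes simulated male strata slightly more homogeneous than reality.

The resting signal generator sums 1/f-shaped Gaussian noise (power slope
χ = 1.5, 5 µV RMS), sinusoidal band oscillators (theta 6 Hz / 1 µV,
beta 20 Hz / 0.5 µV, gamma 40 Hz / 0.3 µV), an alpha oscillator at the
configurable peak frequency (default 8.5 Hz, 3 µV — a visible interior
alpha peak), and white sensor noise (1 µV), at 1000 Hz for 5 minutes by
default. The chirp generator builds each trial from phase-locked damped
onset/offset transients (6 Hz, 150 ms decay), a chirp-following oscillation
at instantaneous frequency 50·t Hz with per-trial wrapped-normal phase
jitter (uniform jitter available as the degenerate case), a
non-phase-locked 10 Hz background attenuated by a desynchronization factor
after onset, and white noise, over a −0.5…2.5 s window at 1000 Hz,
200 trials.

What the generators do **not** emulate: between-feature correlation,
blink/muscle artifacts, volume conduction and realistic scalp topography,
age effects, narrowband (non-sinusoidal) oscillatory dynamics, or
habituation across trials. Passing tests therefore demonstrate correctness
of the measurement and classification machinery and internal consistency
with the published summary statistics — not that real dense-array EEG would
reproduce the published multivariate classification accuracies, which
depend on correlation structure the printed tables do not carry.

## Numerical choices and degenerate inputs

- Periodic (DFT-even) Hann window: a grid-aligned sinusoid leaks into
  exactly two adjacent bins and the amplitude normalization 2/Σw is exact.
- Wavelet edge handling is conservative: a point is invalid if the ±4σ
  support leaves the trial at full rate.
- Relative power with zero total analyzed power, empty regions/clusters,
  ROIs without valid points, single-class tables, classes with fewer than
  two members, non-finite classifier inputs, and baselines overlapping the
  stimulus all raise errors naming the offender rather than propagating
  NaNs.
- All randomness flows from explicit integer seeds through deterministic
  child-seed derivation (crc32-keyed `SeedSequence`), so every reported
  number is bit-reproducible from config + seed; derived seeds stay below
  2³¹.

## Problem sizes in the test suite

Unit and acceptance tests run the signal generators at 250–500 Hz with a few
channels, tens of epochs/trials, and the feature-level recovery checks at
5000 participants per group; the full-study determinism check uses the
complete 141 + 114-participant simulated cohort. These sizes keep the whole
suite under a minute of CPU while leaving every statistical tolerance at
3–4 standard errors of its check.

## Known limitations

- EDF export covers continuous (resting) recordings at integer sampling
  rates; epoched chirp trials are exchanged as npz/CSV arrays rather than
  discontinuous EDF+.
- The quadrant/cluster channel lists and the dense→10–20 montage map are
  editable conventions; results on real recordings depend on using the
  original study's sensor lists.
- In-sample "entire dataset" AUC is optimistic by construction; it is
  reported because it mirrors the published protocol, and it is flagged in
  the report notes.
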