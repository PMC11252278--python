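# Methods

## The synchrony statistic

For two feature series on a shared uniform grid, synchrony is computed
segment-wise. Series are cut into consecutive, non-overlapping segments of
`segment_length_s` (default 30 s); a trailing partial segment is dropped.
Within an aligned segment pair, the Pearson correlation is computed at every
integer lag τ in ±`max_lag_s` (default ±5 s, so eleven lags at the default
1-Hz feature rate). The lag convention is that positive τ pairs x[t] with
y[t+τ], i.e. y lags x; the aggregation window is symmetric, so results do
not depend on argument order. Correlations at the segment boundary are
computed on the truncated overlap (segment length − |τ| samples); a lag is
excluded when that overlap falls below `min_overlap_fraction` (default 0.8)
of the segment or when either window has zero variance.

Each correlation is Fisher-Z transformed, arctanh(r), after clipping r to
±0.999 so identical (degenerate) segments stay finite: the maximal
attainable per-lag Z is arctanh(0.999) ≈ 3.80. The observed synchrony Z is
the mean over admissible lags within a segment, then over segments, with
sign preserved (in-phase Z > 0, anti-phase Z < 0).

The null re-pairs segments: a surrogate pairs the segment sequence of one
series with a seeded random derangement (permutation without fixed points)
of the other's segments and re-aggregates. By default `n_surrogates = 100`
derangements are drawn; when the total number of distinct derangements is
smaller (2 segments have one, 3 have two), they are enumerated exhaustively
instead. The alternative reading in which the null is the set of all
n(n−1) single segment mispairings is available as
`surrogate_mode="segment_pairs"`. The effect size of a dyad is
ES = (Z − mean Z_surr)/SD Z_surr; ES is undefined (missing) when the
surrogate SD is zero.

Implementation note: all segment-by-segment mean-Z values of a dyad are
precomputed as a matrix, so the observed statistic is the diagonal mean and
every surrogate is an indexed mean over a permutation — surrogates cost
essentially nothing beyond the first pass. Missing samples are tolerated via
pairwise-complete correlations; segments with more than
1 − `min_overlap_fraction` missing are unusable, and undefined lags or
segments are excluded from means rather than zero-filled.

Reproducibility: one master seed; each dyad derives an independent RNG
stream keyed by (channel, scope, unordered participant pair), so results are
identical regardless of evaluation order or parallelism, and symmetric in
the two participants.

## Audience aggregation

An audience of N listeners defines N(N−1)/2 dyads per channel and scope.
Audience synchrony is the mean dyadic Z. A listener's synchrony
contribution is the mean of the N−1 dyadic Z values they belong to; the
mean of all contributions equals audience synchrony exactly (each dyad is
counted twice and renormalized), which the tests assert to 1e−12. The
participant-level surrogate distribution is built draw-wise — the s-th
surrogate contribution is the mean over partners of the s-th surrogate draw
of each dyad — preserving between-surrogate variance for the
participant-level ES. Presence of synchrony is a paired t-test of observed
vs surrogate contributions across listeners, per channel and scope.

The composite "all channels" measure averages a listener's ES values over
HR, HRV, SCR and RR (the breathing waveform is excluded as a null channel)
after z-standardizing ES within concert and channel; listeners missing a
channel contribute the mean of the rest (pairwise deletion).

Piece-level analyses slice each recording by the piece boundaries in the
concert metadata and re-segment the sub-series independently; pieces shorter
than two segments are skipped with a warning.

## Regression models

Synchrony contributions (as ES) are outcomes in linear mixed models with a
random intercept per concert, fitted by REML through `statsmodels.MixedLM`.
Predictors are centered within concert (isolating within-concert variance)
for affect-change, experience-factor and piece-item blocks; personality
traits enter uncentered since traits have no plausible between-concert
variance. Affect change is expressed per participant as
(pre − post)/SD_pre, so a positive value is a decline.

Reported per predictor: estimate, t and the large-sample normal p-value
(the exact small-sample degrees-of-freedom correction of commercial mixed
model software is not reproduced; with hundreds of observations the
difference is negligible). The random-intercept share is
100·σ²_intercept/(σ²_intercept + σ²_residual); model r² is the squared
correlation between fitted (fixed + predicted random effects) and observed
values. Rank-deficient designs raise an error naming the offending columns
— in particular, a group-constant predictor combined with centering.
Singular fits fall back to ordinary least squares with a zero-variance
random intercept and a warning; with a single group level the model reduces
to OLS exactly. Within a model, predictor p-values are reported raw; the
piece-contrast analysis (piece as a categorical fixed effect) corrects its
pairwise contrasts with Holm's method and emits a rank string such as
`Dean > Brahms > Beethoven` joining adjacent pieces by `>` (significant) or
`=`. An optional two-pass mode refits keeping only first-pass-significant
predictors, limiting multicollinearity in correlated item blocks.

## Feature extraction

The five feature series are derived with deliberately transparent
operators; the synchrony statistic consumes only their temporal shape.

* **HR** — instantaneous 60/IBI (beats/min) at each beat, linearly
  interpolated to the feature grid.
* **HRV** — RMSSD (ms) of inter-beat intervals in a sliding window centered
  on each grid point; window 30 s by default, matching the segment length.
  One successive difference (three beats) suffices; smaller windows are
  missing. RMSSD is invariant to adding a constant to all IBIs.
* **RR** — 60/(inter-peak interval) from breath peaks (local maxima with
  prominence ≥ 0.25·SD and spacing ≥ 1.5 s), interpolated to the grid.
* **RESP** — the belt waveform itself, z-scored and resampled, preserving
  inhale/exhale phase.
* **SCR** — the phasic electrodermal component: trace minus a centered
  20-s moving-median tonic estimate, negative residuals clipped at zero.
  The moving median is a dependency-free stand-in for model-based
  tonic/phasic decomposition; a rectangular burst shorter than half the
  window survives essentially intact while ramps over minutes are absorbed
  into the tonic level.

Samples without support are NaN and excluded pairwise downstream. The
feature rate defaults to 1 Hz — 30-s segments then contain 30 samples and
the ±5-s lag window spans ±5 samples — and is configurable, as is the HRV
window.

## The synthetic-data generator

The generator emulates *induction synchrony*: listeners who do not interact
but share a stimulus. Per concert, a latent driver stands in for the
music's arousal contour: an AR(1) series (coefficient 0.9) smoothed by a
5-s moving average and standardized. `driver_smooth_s = 0` exposes the raw
AR(1), whose lag-1 autocorrelation equals the coefficient — the form the
calibration tests use. Participant i's series on a coupled channel is
κ_{i,c}·driver(t − ℓ_i) + AR(1) noise (coefficient 0.7, unit innovation
variance), standardized. Lags ℓ_i are drawn once per participant, uniform
in ±2 s, constant over the concert. Couplings are
κ_{i,c} = κ_mean + Σ_k β_k·(x_k(i) − x̄_k) + N(0, σ_κ), truncated at zero
(an `allow_negative_coupling` switch permits planted anti-phase);
covariates enter centered so κ_mean stays the mean coupling. Defaults:
κ_mean = 0.6, σ_κ = 0.15, planted trait effects β_Openness = +0.30,
β_Extraversion = −0.25, β_Neuroticism = −0.25 per unit of the centered
trait.

The breathing waveform RESP is generated as an independent per-participant
oscillator (≈15 breaths/min with slow frequency drift) with coupling
exactly zero — the built-in null channel. Per-piece coupling multipliers
(default 1) allow piece-graded synchrony.

Surveys are generated at the summary level: Big-Five traits as clipped
normals on [1, 5] (mean 3, SD 0.7); seven experience factors as
QR-orthogonalized standard-normal scores; affect scales with pre means
typical of a concert audience and post = pre − change, where the change
(in pre-SD units) is planted with a mean negative-activation decrease of
0.5·SD and a small valence rise; nine items per piece on [1, 5] around
piece-specific means. The covariates used to build κ appear verbatim in the
survey table. Raw-level signals (inter-beat intervals tracking the HR
target, a respiration waveform with instantaneous frequency RR/60, an
electrodermal trace of tonic drift plus driver-modulated Poisson bursts
convolved with a bi-exponential kernel) exercise the feature-extraction
stage end to end.

What the generator does **not** emulate: movement artifacts and sensor
dropout, nonstationary or piece-specific coupling dynamics beyond a scalar
multiplier, item-level questionnaire structure, respiratory sinus
arrhythmia or any physiological cross-talk between channels, and real music
audio. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — linear lagged coupling to a shared smooth driver —
not that real concert recordings satisfy that structure.

## Numerical choices and problem sizes

* r clipped to ±0.999 before arctanh; undefined lags/segments excluded, not
  zero-filled.
* Derangements sampled by rejection; enumerated exhaustively when ≤
  `n_surrogates` exist and the segment count is ≤ 7.
* CSV interchange uses `NA` for missing and round-trip float parsing, so
  write → read → write is byte-identical.
* Validation and calibration runs use desk-scale conditions chosen to keep
  a full pass in minutes on one core: concerts of 10–15 min at 1 Hz (20–30
  segments), audiences of 2–60, 30–100 surrogates; the default simulated
  series is 11 concerts × 60 listeners. The statistic itself is O(segments²
  × lags) per dyad and scales to hour-long recordings unchanged.

## Known limitations

* Surrogate nulls from segment shuffles are only approximately standard
  normal; the empirical two-sided rejection rate at |ES| > 1.96 for
  independent AR(1) dyads lies near, but not exactly at, 5% (the tests
  bound it in [0.02, 0.09]).
* Lag means weight all admissible lags equally, not by overlap length.
* Mixed-model p-values use the normal approximation (see above).
* The moving-median SCR detrending is not a deconvolution; overlapping
  sudomotor responses are not separated.
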