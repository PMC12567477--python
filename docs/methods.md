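# Methods

This note documents the models, conventions and design choices behind
`breathstage`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The pipeline estimates, from a single night of respiratory audio, the
fraction of recording time spent in four macro sleep stages: Wake, Light
(N1+N2 merged — the two light non-REM stages are hard to separate from
non-EEG modalities), Deep (N3) and REM. Targets are *proportions of total
recording time* derived from a 30 s-epoch hypnogram by epoch counting; the
output is a point on the 4-simplex, not an epoch-by-epoch staging. The
physiological signal being exploited is that respiratory rate and
regularity vary with sleep depth: slow and regular in N3, faster and more
variable in REM and wakefulness.

## Segmentation

Audio is split into overlapping windows of W = 20 s with hop H = 10 s.
W is the windowing the method is defined on; H is a package choice — 50%
overlap gives every interior frame at least two votes without tripling
compute, and is configurable. Each window is converted to a log-Mel
spectrogram (16 kHz nominal rate, 80 mel bins, 25 ms analysis window, 10 ms
hop → 100 frames/s, HTK mel scale, `log(mel + 1e-10)` floor). These
front-end defaults mirror the common speech-model front-end and are
configurable; nothing downstream depends on them beyond the frame rate.

A backend maps each spectrogram to per-frame posteriors over
{inhale, exhale, silence} (rows on the 3-simplex within 1e-9). Three
backends ship:

* **oracle** — emits one-hot posteriors from a reference label sequence;
  used to isolate downstream stages from classifier error and to run
  full-night experiments without audio synthesis
  (`segment_with_oracle` windows the label timeline directly, exercising
  the same fusion code path).
* **energy heuristic** — frames are silence unless their log-energy exceeds
  median + 3·MAD of the window; active frames split inhale/exhale by
  spectral centroid (threshold 900 Hz). Deterministic, untrained.
* **trainable** — multinomial logistic regression on standardized per-frame
  mel features (mel vector, mean energy, mean delta), seeded, with a
  50k-frame training subsample cap. A desk-scale occupant of the contract
  that a large fine-tuned acoustic model would fill; training such a model
  is explicitly out of scope.

Training uses the mean categorical cross-entropy
L = −(1/N) Σᵢ Σ_c y_ic log ŷ_ic with probabilities clipped at 1e-12, so L
is finite and ≥ 0, zero only on one-hot-correct predictions (up to
clipping).

**Fusion.** Each window casts one hard vote (its argmax class) per covered
frame; zero-padded tail frames of the final window are excluded. The modal
class wins. Ties are broken by the larger mean posterior over the covering
windows among the tied classes, then by the fixed priority
silence > exhale > inhale (deterministic, and errs toward not fabricating
breaths). Voting is over hard labels rather than posterior sums — "majority
vote" is read literally, confidence enters only through the tie-break.

## Event parsing

Fused labels are merged into maximal runs and parsed into inhale onsets in
four ordered steps: (1) hysteresis — non-inhale runs strictly shorter than
`min_gap_s` flanked by inhale runs on both sides are absorbed, iterated to
a fixpoint (the absorbed set is order-independent because absorption only
ever turns runs into inhale); (2) inhale runs strictly shorter than
`min_inhale_s` are dropped (relabelled to the preceding run's label, else
the following run's, else silence); (3) candidate onsets at every
{silence, exhale} → inhale transition — an inhale run opening the sequence
also counts, since the recording starts mid-stream; (4) candidates within
`refractory_s` of the last accepted onset are discarded, left to right.
The onset time is the first frame of the validated run divided by the frame
rate.

Rule defaults — `min_inhale_s` 0.3, `min_gap_s` 0.2, `refractory_s` 1.0 —
are physiological-plausibility choices of this package (no published
values exist): breaths shorter than 0.3 s and rates above 60/min are not
plausible in sleep, and the simulator enforces the matching 1 s minimum
inter-onset spacing.

Per analysis window, Respiratory Count is the number of onsets in the
half-open window interval scaled to breaths/min, and Respiratory Period is
the median of consecutive onset differences among onsets within
`margin_s` = 2 s of the window edges — the margin captures the interval
straddling a boundary without reaching into distant cycles. A window with
fewer than two qualifying onsets has an *undefined* period, carried as an
explicit mask (never a zero, which would corrupt downstream medians).
All windows/frames are half-open `[start, end)` on a 0-based episode clock.

## Ground-truth annotation from respiratory effort

Breath timing for supervision comes from an abdominal effort belt: the
trace is smoothed with a centred 25-sample moving average (shrinking edge
windows, so constants are preserved and the operator is linear), then
alternating local maxima and minima are found with prominence ≥ 0.1 × SD
and spacing ≥ 1 s (the same physiological ceiling); where two same-kind
extrema are adjacent the less prominent is pruned. Maxima are taken as
inhale onsets by default (`max_is_inhale`); because belt polarity varies by
sensor and the physiological reading is disputable, the opposite convention
is a flag. Frames from a maximum to the next minimum are inhale; from a
minimum over the first α = 0.7 of the gap to the next maximum, exhale; the
remainder silence. α is a construction of this package — the silent gap
between breaths is not observable from the effort trace alone — chosen so
all three classes occur with a tunable silent fraction.

## The 76-feature episode vector

The published description of the feature stage fixes the count (76) and the
five families but not the individual definitions; the enumeration in
`features.py` (34 statistics per series × {RC, RP} + 8 cross-features) is
this package's canonical contract and is frozen by name and order. Numeric
conventions, all chosen so every vector entry is finite:

* population moments (ddof = 0); skewness m₃/m₂^1.5 and excess kurtosis
  m₄/m₂² − 3, both defined as 0 on constant input;
* autocorrelation at lag k is the Pearson correlation of the series with
  its k-shifted copy (bounded in [−1, 1]; 0 on zero variance or series
  shorter than k+2);
* the periodogram is P_k = |X_k|²/n of the mean-centred series, one-sided,
  frequencies k/n in cycles/window; the dominant frequency is the non-DC
  argmax; spectral entropy is Shannon entropy of the normalised non-DC
  spectrum in bits divided by log₂(#bins) (0 for a delta or empty
  spectrum); the centroid is the power-weighted mean frequency;
* slopes are OLS slopes of the centred moving average (windows 5 and 15,
  shrinking edges) against window index, units per window;
* CV = std/mean with 0 on zero mean; all ratio cross-features are 0 on a
  zero denominator;
* zero-crossing rate counts sign changes of the mean-centred series
  (zeros count as positive) over n − 1;
* percentiles use linear interpolation; the trimmed mean cuts
  ⌊0.1·n⌋ per side;
* windows with undefined RP are dropped before any RP statistic (never
  interpolated — interpolation would fabricate respiratory cycles); the
  cross-features pair RC with RP on the RP-defined windows only; dropped
  counts are recorded in the vector's provenance.

Fewer than two usable windows in either series is a degenerate-input error
naming the offending series.

## Stage regression and simplex projection

One scalar regressor per stage is fitted on the shared feature vector; the
four raw outputs are projected by p̂_s = max(ε, p̃_s)/Σ max(ε, p̃_s') with
ε = 1e-6 — small enough that the injected mass is negligible, large enough
to guard the all-nonpositive corner. No clipping to [0, 1] is applied
before the projection; the projection alone carries the constraint. Note
the projection is exactly idempotent only when every output component is
≥ ε: a component can legitimately normalise to below ε (e.g. a raw −0.1
against mass 1.1 yields ≈ 9.1e-7), and reprojection then re-clips it; the
discrepancy is bounded by the ε scale and is treated as such in tests.

The regressor inventory is the standard tabular suite with fixed
hyperparameters: LinearRegression; DecisionTree (squared error, unlimited
depth); RandomForest (100 trees, bootstrap); SVR (RBF, C = 1, ε = 0.1,
gamma scale); kNN (k = 5, uniform, Minkowski); MLP (one hidden layer of
100, ReLU, Adam, α = 1e-4, adaptive LR, 1000 iterations). SVR/kNN/MLP
inputs are standardized with fit-set statistics (a package addition, flag
`standardize`, default on — distance- and gradient-based learners are
unusable on raw mixed-unit features). Stochastic learners are seeded. A
TabPFN adapter sits behind the same interface but is optional; the default
for tests and benchmarks is the random forest, which is deterministic
under seed and dependency-light.

## Evaluation protocol

Errors are analysed per stage in percentage points, subjects pooled within
a stage. `fixed_tolerance_accuracy` reports the share of subjects with
|e| ≤ b for b ∈ {5, 10, 20} pp; `coverage_bound` answers the inverse
question with the order statistic b_c = the ⌈c·n/100⌉-th smallest |e| —
the smallest half-width achieving at least c% coverage, no interpolation,
which makes b₁₀₀ the maximum |e| and b_c non-decreasing in c.
Cross-validation is subject-wise: subjects are randomly permuted under a
seed (default 7, recorded in outputs) and split into k folds whose sizes
differ by at most one; per-fold metrics are averaged rather than pooling
errors across folds.

## The synthetic generator

No generative description of real overnight tracheal audio is available,
so every simulator choice is an explicit stand-in; what the generator
fixes is the *ground truth* (hypnogram, onset times, proportions), which
is what the pipeline is scored against.

* **Hypnogram**: first-order Markov chain over 30 s epochs. Stage s has
  self-transition 1 − 30/mean_bout_s; leaving mass follows configurable
  weights. Defaults (mean bouts: W 150 s, N1 90 s, N2 540 s, N3 420 s,
  REM 480 s) produce realistic run lengths and a light-sleep-dominated
  stationary distribution; the initial epoch is drawn from the stationary
  distribution so expected proportions are length-independent and
  analytically known (eigen-analysis, cross-checked by matrix power in
  tests).
* **Onsets**: inter-onset intervals are Gaussian with mean 60/rate and SD
  cv × mean for the stage of the epoch containing the previous onset,
  floored at 1 s. Default profiles (rate breaths/min, CV): W 15/0.22,
  N1 14/0.14, N2 13/0.10, N3 11.5/0.05, REM 15.5/0.25 — slow/regular in
  deep sleep, fast/irregular in REM and wake, rates within the adult
  sleeping range.
* **Audio**: a 0.01-RMS white-noise floor plus Hann-enveloped band-noise
  bursts, burst RMS set `snr_db` above the floor: inhale bursts
  (500–2000 Hz, duration min(1.2 s, 0.35Δ)) at each onset, exhale bursts
  (200–700 Hz, 0.7× amplitude, over [0.45Δ, 0.85Δ)) mid-cycle. Distinct
  bands make the classes acoustically separable for the shipped backends;
  band edges are compressed below Nyquist at low sample rates. The
  reference frame labels use the same cycle layout.
* **Effort**: cos of a piecewise-linear phase through 2πk at onset k, so
  local maxima sit at inhale onsets (matching the default annotation
  polarity) within ±0.1 s, plus 0.02-SD sensor noise.
* **Cohorts**: each subject's 76 features are a fixed unit-norm linear
  image of 8 standard-normal latent factors — every marginal is standard
  normal while the table carries the strong collinearity of real episode
  descriptors, which are deterministic functionals of just two underlying
  series. This matters statistically: with a full-rank 76-dimensional
  design and cohorts of ~100, ordinary least squares would inflate
  held-out variance by ~p/(n−p−1); on the low-rank design the minimum-norm
  OLS solution effectively regresses on the latent space and small-cohort
  recovery is well-posed. The default feature→proportion mapping is linear
  with per-feature coefficients summing to zero across stages and
  intercepts (0.15, 0.50, 0.20, 0.15) summing to one, so raw scores sum to
  1 identically and the simplex projection is the identity on noiseless
  data — linear-regression recovery is then exact by construction.
  Coefficients of magnitude 0.02 on unit-variance features encode a
  modest-signal regime. Target noise is stage-wise Gaussian, re-projected.

What the simulator does **not** emulate: apnea/hypopnea events, snoring,
body-movement artifacts, room acoustics and microphone variation,
night-to-night variability, and any real correspondence between the
cohort's latent factors and physiology. Passing tests therefore
demonstrate that the pipeline's machinery is correct and self-consistent —
not that its accuracy transfers to clinical recordings.

## Classical baselines

Both baselines are deterministic and count *acoustic events*:

* **FFT**: band-pass 300–2000 Hz → rectify → low-pass to a 50 Hz envelope →
  log1p dynamic compression → Gaussian smoothing (σ 0.2 s) → detrend →
  zero-padded periodogram argmax within 4–40 breaths/min. Confidence is
  the share of band power within ±10% of the winning frequency.
* **Peak envelope**: log-Mel intensity envelope (per-frame mel mean) →
  Gaussian smoothing (σ 0.3 s) → peak detection (spacing ≥ 1 s, prominence
  ≥ 0.1 × SD) → each peak refined by L-BFGS-B maximisation of a cubic
  spline through the envelope, bounded to ±1 frame.

Every cutoff, σ and the refinement objective are documented package
defaults; only the pipeline sketch is inherited. Because both estimators
count envelope events, audio in which inhale *and* exhale are separately
audible yields an event rate near twice the breath rate; their rated
fixtures therefore use one acoustic event per cycle, and on full
two-burst-per-cycle synthetic nights their window-level RC error is
correspondingly large relative to the label-based pipeline.

## Problem sizes

Full-night runs (oracle round trip: one 8 h episode; end-to-end benchmark:
60 subjects × 4 h, 5-fold subject-wise CV with the random forest) use the
oracle segmentation path on the 100 frames/s label timeline, which makes a
night a few-second computation. Audio-consuming components (energy and
trainable backends, both baselines) are exercised on episodes of minutes
at 4–8 kHz sample rates, with the trainable backend trained on 200 windows
and evaluated on 50 held-out windows. Cohort-recovery experiments use 100
subjects with target noise SD 0.02. These sizes are the package's chosen
experiment scale; all are parameters.

## Known limitations

* The 76 feature definitions are this package's enumeration of the stated
  families; numeric equality with any other implementation's vectors is
  not claimable — only the count, the families and these definitions.
* The silent-gap fraction α, the parsing thresholds, the RP margin and all
  baseline constants are documented defaults, not measured quantities.
* The simplex projection is idempotent only up to ε-mass injection (above).
* Sequential error propagation: segmentation mistakes flow into features
  and regression with no uncertainty quantification.
* The trainable backend is a shallow linear classifier on mel features; it
  occupies the backend contract but is not a substitute for a large
  fine-tuned acoustic model on real audio.
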