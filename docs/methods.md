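# Methods

This note documents the models, defaults and numerical choices behind
`cardioahi`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Epoch labelling

Epochs are half-open 30-s intervals `[30k, 30k+30)`, timestamps in
seconds from recording start. An epoch is an RE-epoch when

* a **single** event overlaps it by at least 10 s (overlaps of distinct
  events are not summed — the per-event reading of the rule), or
* it starts strictly less than 5 s after an event's end; an event ending
  exactly on the boundary triggers the rule (distance 0 < 5 s).

Characterisation assigns the kind of the longest-overlapping event,
overridden by `after_event` when the 5-s rule fired; the
`after_combination` tag separates epochs with both an after-trigger and a
≥10-s overlap (`after`), overlap only (`no_after`), and trigger only
(`pure_after`). Events extending past the recording end are clipped with
a warning. Correctness is checked against a 1-ms rasterisation oracle on
randomised event sets.

## Preprocessing

R-peak detection is a Hamilton–Tompkins-style chain: 8–20 Hz zero-phase
band-pass, derivative, rectification, 80-ms moving-window integration,
adaptive dual (signal/noise) threshold with a 250-ms refractory period,
then refinement to the extremum of the absolute filtered signal within
±50 ms (the refinement window is a declared choice — narrower than half
the shortest admissible interval; the original refinement algorithm is
not specified in a reproducible form). Using the absolute filtered signal
makes detection polarity-invariant.

Interval cleaning is two-stage and order-matters: values outside
[0.5, 2] s are tagged `out_of_range` first; then consecutive pairs that
share a beat and are both still valid are tagged `ectopic` when
`value[i]/value[i−1] > 1.5` strictly (a 60→40 bpm drop is exactly 1.5 and
is kept). The test is one-directional — a premature beat produces the
short-then-long pattern the ratio catches; ratios across gaps left by
rejected intervals are not evaluated because they are physiologically
meaningless. Tags are never reverted, so cleaning is idempotent.

Recording-level exclusion is advisory: ectopic fraction > 3% of
intervals, or > 30% of epochs missing ≥ 70% of features, or a reported
technical fault. The CLI refuses excluded recordings unless `--force`.

## Feature extraction

Windows are centred on the epoch (the assignment of a window to its
central epoch motivates centring; trailing windows would lag the event
response). A feature is computed only when valid intervals cover at least
half the *nominal* window and at least 5 s of the central 30 s; edge
windows keep their nominal length in this test, so low-coverage edges
come out missing rather than silently shortened. All values are finite or
missing (NaN); there are no fill values.

Defaults per family:

* **hrv_time** (300 s): mean/median/SDNN/rMSSD/SDSD/pNN50/pNN20/IQR/
  range/CV/skewness/kurtosis of the intervals, mean and SD heart rate.
* **hrv_freq** (300 s): linear interpolation of the tachogram to 4 Hz,
  Welch periodogram (150-s segments, linear detrend), band powers VLF
  0.003–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz, total power, LF/HF and
  normalised powers. Band edges follow the HRV task-force conventions.
* **dfa** (360 s): scaling exponents over box sizes 4–16 (α1), 16–64
  (α2) and 4–64 beats; linear detrending in non-overlapping boxes.
* **dfa_progressive** (60 s) and **dfa_windowed** (360 s, mean of 60-s
  sub-window exponents).
* **sample_entropy** (300 s): SampEn(m=2, r=0.2·SD); undefined (missing)
  for constant series or when no template matches exist.
* **multiscale_entropy** (540 s): coarse-grained SampEn at scales 1–20,
  r fixed from the scale-1 SD.
* **activity_counts** (30 s): 10-Hz high-passed, rectified ECG amplitude
  integrated per epoch — a movement surrogate; the cut-off is
  configurable.

Families defined only in external methodological papers (arousal
probability, adapted spectral analysis, high-frequency pole, local phase
coordination, visibility graphs, Hilbert analysis) are not reimplemented;
the registry accepts them as plugins with their own window size, and they
then participate in optimisation and classification transparently. With
all built-in families enabled the matrix has 48 columns.

## Feature optimisation

The AMSD (|class-mean difference| / pooled SD) uses the **population**
(n-denominator) SD — the convention is a declared choice, as is pooling
all epochs including wake (consistent with classifier training; a
sleep-only switch exists). Transformations are applied strictly per
recording: every statistic (percentiles, medians, Box-Cox λ, quantile
maps) comes from that recording alone, so a trained chain transfers to
unseen recordings without leakage.

Catalogue conventions where the naming is loose:

* Box-Cox λ is the grid maximum-likelihood estimate over 41 points in
  [−2, 2] (deterministic and fast for the many small per-recording
  fits), followed by a population z-score.
* Tukey-Ladder picks the exponent in {−2, −1, −½, 0 (log), ½, 1, 2}
  minimising absolute skewness per recording; negative exponents are
  negated to preserve ordering.
* Histogram equalisation maps through a 10-bin empirical CDF to [0, 1];
  quantile normalisation maps ranks to target quantiles at rank/(n+1)
  (normal, exponential or uniform).
* Amplitude divides by the maximum absolute value; Percentile maps to
  the empirical CDF position in [0, 1].
* Butterworth filters (2nd order, cut-offs 0.25/0.5/0.75 in
  Nyquist-normalised units) run forward–backward so transformed series
  stay aligned with epoch labels; deliberate lags are the explicit
  Time-shift transformation. NaNs are bridged by interpolation for
  filtering and restored afterwards.
* Windowed operators (7/15/23/31 epochs; backward/forward/centred)
  ignore missing values inside the window; Log and Box-Cox shift
  non-positive recordings by min + ε before transforming; the square
  root is applied signed so it stays defined on ℝ.

The greedy search scores every legal successor (group graph, depth ≤ 5),
keeps the single best, breaks ties toward the earliest catalogue entry
(determinism) and stops on the first non-improvement. Depth-1 results are
verified against exhaustive enumeration; legality against an independent
restatement of the group table.

## Classifier, calibration, AHI

Balancing: SMOTE (k=5 minority neighbours, uniform interpolation) to
parity, then ENN cleaning (k=3 majority vote over all samples). Candidate
models — elastic-net logistic regression (SGD), a Huber-type linear
classifier (modified Huber loss), LDA and QDA — are graded by mean inner
4-fold precision–recall AUC when selection is requested; the default
trains the logistic model directly (it is also what selection returns on
linearly separable data by the tie rule). SGD hyper-parameters default to
α=1e-4, l1_ratio=0.15, max_iter=1000, tol=1e-3 and are config-exposed.

Missing features are imputed with per-recording medians (training-pooled
medians as fallback), then standardised with training statistics.
Training uses all epochs including wake; β and the probability threshold
use sleep epochs only.

β is the Theil–Sen slope (median of pairwise slopes, equal-x pairs
skipped) of reference AHI against the true RE-epoch fraction; any
intercept is discarded because the AHI equations are purely
multiplicative. The probability threshold sweeps 0.01–0.99 in 0.01 steps
maximising severity kappa, ties resolved to the highest threshold
(favouring specificity). Severity bounds are inclusive at the lower edge
(AHI ≥ 5 mild, ≥ 15 moderate, ≥ 30 severe).

**Out-of-fold threshold selection.** The kappa sweep runs on
probabilities predicted by inner 4-fold participant-level models rather
than on the final model's in-sample probabilities: in-sample
probabilities are optimistically sharp, which drags the threshold low and
overestimates dense recordings at validation time. Both variants use
training data only; the out-of-fold one matches how the estimator is
applied to unseen recordings.

## Evaluation

Bland–Altman limits use the sample (n−1) SD — the conventional choice for
limits of agreement. Screening positivity is AHI ≥ threshold. The ROC
sweeps every distinct predicted value plus ±∞; the optimal cut minimises
the Euclidean distance to (sensitivity, specificity) = (1, 1). The
Breusch–Pagan test regresses the residuals of an OLS fit of the estimate
on the reference against the reference (the regressor choice is not
fixed by convention; this one is recorded here). Kappa with both raters
constant and equal is defined as 1. Plot export is not implemented; the
report objects expose everything a plotting layer needs.

## Synthetic data

The generator is the package's test bed, not a physiological model. Per
recording: a two-state Markov hypnogram (wake fraction 0.15, mean wake
bout 4 epochs); events only inside sleep segments, exponential-weight
gaps with a 10-s refractory after each event, count matched to the
target AHI (so the generated AHI is exact ground truth); durations
N(22, 8) clipped to [10, 60] s; kind mix 30% obstructive apnea, 55%
hypopnea, 10% central, 5% mixed (hypopnea-dominant, as in clinical
cohorts). Hypopneas are drawn to survive the 4%-desaturation/arousal
harmonisation rule so ground truth is unaffected by it. The IBI signature
is a ramped lengthening during the event (bradycardia, 12% deep) and a
decaying shortening after it (tachycardia surge 15%, 8 s), lagged 2 s;
baseline 1 s with respiratory (0.25 Hz) and baroreflex-band (0.095 Hz)
modulation and white noise (SD 25 ms). Ectopic injection pulls a beat
38% forward, creating the short-then-long pair the rejection rule
targets, and logs the site. ECG rendering convolves the beat train with
a QRS-like wavelet and adds baseline wander, sensor noise, and movement
bursts after arousal-flagged events and in wake.

Populations draw per-class target AHIs uniformly inside the severity
bounds (counts by largest remainder) and jitter each subject's
physiology multiplicatively (baseline IBI ±20%, noise ×0.7–1.5,
oscillation and response magnitudes ×0.6–1.4, arousal probability and
wake fraction similarly). Identical-physiology populations let absolute
feature levels carry the class signal across recordings — something no
real cohort allows — so heterogeneity is on by default
(`heterogeneous=False` exists for controlled experiments).

**What a green test establishes.** The simulator emulates event-locked
mean responses, between-subject scale variation and simple artifacts. It
does **not** emulate sleep-stage-dependent HRV, respiration–cardiac
amplitude coupling, arrhythmias beyond isolated ectopy, movement
disorders, or annotation noise. End-to-end recovery on this world shows
the pipeline is wired correctly and the calibration logic behaves; it
does not predict clinical performance.

## Known limitations

* **Severity-dependent calibration error.** The detected epoch fraction
  responds convexly to true event density (long feature windows blur
  dense recordings), while β is a single multiplicative constant.
  Consequently the severity classes are not calibrated simultaneously:
  at the kappa-selected threshold, severe recordings can be over- or
  under-estimated by tens of events/h depending on the population, and
  end-to-end bias/severity accuracy fluctuate several events/h across
  simulation seeds. This mirrors the per-severity error pattern reported
  for the method on clinical data; it is a property of the calibration
  model, not of the implementation.
* Epoch-level detection on heterogeneous populations reaches per-subject
  kappa ≈ 0.3 with the reduced feature set — the realistic operating
  point for this method class.
* EDF reading is deliberately minimal (16-bit, uniform record duration,
  one channel extracted); WFDB input is not supported in this build.
* QDA is regularised (reg_param 1e-3) for stability on collinear
  features; SampEn at large coarse-graining scales is frequently
  undefined on short windows and reported missing by design.
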