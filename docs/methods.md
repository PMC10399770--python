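# Methods

This note documents the measurement definitions, model assumptions,
parameter defaults and numerical choices behind `cavesong`, and what the
synthetic-soundscape validation does and does not establish about field
recordings.

## Signal model and the synthetic generator

Cave click sounds are modelled as short carrier pulses in stationary
background noise:

- **Single click** — a sinusoidal carrier at the dominant frequency under an
  amplitude envelope. The default envelope is an exponential decay with
  decay constant τ = duration / ln 10, so the envelope reaches 10% of its
  peak (−20 dB, the segmentation boundary) exactly at the nominal duration;
  with this convention the nominal duration *is* the measurable duration.
  Hann and flat envelopes are available for tests and sensitivity checks.
  Defaults: 2 kHz dominant frequency, 5 ms duration — the scale reported
  for wild Single Clicks.
- **Serial click** — a train of identical pulses with onset-to-onset
  interval `interpulse` (default 15 ms) and `pulse_count` (default 8)
  pulses; interval jitter is Gaussian with relative SD `jitter_fraction`,
  with bounded redraws forbidding pulse overlap.
- **Noise** — seeded white noise, or pink noise generated by 1/√f amplitude
  shaping of seeded white noise (cave ambience is low-frequency dominated);
  rescaled to the requested RMS exactly. The benchmark condition is
  click-amplitude/noise-RMS = 5, i.e. amplitude 0.5 on a 0.1-RMS bed.

The generator does **not** model propagation, reverberation, multipath,
fish movement, amplitude variation within a train, or non-stationary
ambience. Recovery results on synthetic soundscapes therefore demonstrate
the estimator chain's correctness and its noise robustness under the stated
model, not performance on arbitrary field tape.

### Ground-truth sidecars record *effective* values

The truth table written next to each soundscape holds, per event, the
feature values obtained by applying the package's own measurement chain
(band-pass, envelope, −20 dB boundary; see below) to the *clean, noise-free*
event waveform, plus the SNR the noisy measurement is expected to return
(signal RMS and in-band noise power add). Deterministic measurement offsets
— envelope smoothing widens a pulse by a fraction of a millisecond on each
side, the band-pass filter sheds spectral sidelobes below 500 Hz — are thus
identical in truth and measurement and cancel from recovery comparisons,
which then isolate what they should: the noise-induced error.

## Detection

- **Matched filter.** Sliding zero-mean, energy-normalized cross-correlation
  (Pearson coefficient per lag). Implemented with overlap-add convolution
  for the numerator and running sums for per-window energy; the contract —
  equality with the direct per-lag computation to 1e-9 — is enforced by
  test. Zero-energy windows get coefficient 0; the trace is invariant to
  positive rescaling of the recording.
- **Peak picking.** Local maxima are first thinned so no two survive within
  `min_separation` (default 20 ms, one maximum Single-Click duration; the
  higher peak wins), *then* thresholded. Doing suppression before
  thresholding makes detection counts monotone in the threshold, which the
  tuning sweep relies on.
- **Supervised tuning.** Candidate thresholds are the sorted unique
  suppressed-peak scores on the annotated segment (every achievable
  operating point). For the default precision criterion the sweep returns
  the *lowest* threshold with precision ≥ target — accepting as many
  signals as possible while at least 95% of reported signals are true; for
  the recall criterion, the *highest* threshold with recall ≥ target. With
  more than 256 candidates a strided coarse sweep brackets the criterion
  boundary before the exact sweep refines inside it. Tuning never draws
  unseeded randomness; the segment is caller-supplied.
- **Scoring.** Greedy one-to-one matching by ascending time distance at
  ±10 ms default tolerance. A truth event spans `[time, time + duration]`;
  extra detections inside an already-matched span (the later pulses of a
  serial train also match a single-pulse template) count neither as hits
  nor as false alarms. Degenerate precision/recall (no detections, no
  truths) is reported as 0 with an explicit flag.

## Segmentation

Regions around detections (±50 ms, merged when overlapping) are band-passed
to 500–10,000 Hz (the stated bandwidth of these sounds; 4th-order
Butterworth, zero-phase), the amplitude envelope taken as the
analytic-signal magnitude and smoothed by a 1 ms centered moving average.

Noise-floor correction happens in the *power* domain: the expected envelope
power of signal-plus-noise is the sum of the two powers, so subtracting the
estimated mean noise envelope power (the mean of envelope² over values
below 4× its median, which excludes the pulses) leaves a nearly unbiased
signal-envelope estimate. Subtracting a mean *amplitude* instead would bias
pulse boundaries inward at low SNR (Rice-distribution convexity); using the
median power rather than the mean biases them outward — both were measured
and rejected.

Pulse delimitation uses two thresholds on the corrected envelope:

- **boundary** (default 0.1 of the local peak, −20 dB) delimits a pulse's
  extent — onset, offset, duration;
- **core** (default 0.3 of the local peak) decides whether a run is a pulse
  at all. At SNR 5 the −20 dB boundary sits near the residual noise
  fluctuation level and brief noise excursions above it are common; the
  core requirement rejects them while leaving the −20 dB edges in charge of
  the measured extent.

Runs closer than `merge_gap` (default 0.25 ms) are merged; runs shorter
than 1 ms are dropped. A region whose peak does not exceed 4× the noise
envelope floor yields no pulses. The merge gap is deliberately tight:
sustained dips below the boundary essentially never occur inside a real
pulse above the noise floor, while a generous gap splices adjacent noise
excursions onto pulse tails and inflates durations (measured effect at
SNR 5: a 1 ms gap costs ≈ +8% median duration error).

Event assembly follows the field rule: consecutive pulses with
onset-to-onset gaps ≤ `serial_gap` (default 200 ms — an order above the
15 ms interpulse, an order below the isolation rule) form one Serial Click;
a lone pulse is a Single Click iff it is shorter than 20 ms *and* more than
1 s from its nearest neighbour; lone pulses failing either clause are
emitted flagged `unclassified` rather than silently dropped. The serial
grouping gap is a gap-filling default — only the Single rule is externally
given — and is configurable.

## Acoustic features

- **Duration**: pulse offset − onset, from the segmentation boundaries (ms).
- **Dominant frequency**: peak of the Hann-windowed magnitude spectrum of
  the band-passed event window, zero-padded to ≥ 4096 points (Δf ≈ 10.8 Hz
  at 44.1 kHz), restricted to 500–10,000 Hz. Windows are filtered with
  10 ms of surrounding context so filter edge transients stay outside the
  measurement.
- **SNR**: linear ratio of band-limited event-window RMS to the RMS of a
  40 ms noise window immediately preceding the event (shifted past any
  overlapping event; right filter context zero so the event cannot leak
  backward through the zero-phase filter). 40 ms rather than event-length:
  a 5 ms noise window yields an RMS estimate with ≈10% relative error,
  which would dominate the SNR error budget. A silent noise window returns
  a capped sentinel (1e6) with a flag; dB output is available.
- **Serial parameters**: pulse number; mean pulse duration; mean interpulse
  duration (mean *silent gap*, previous offset → next onset — the generator
  truth also records the onset-to-onset variant); total duration (first
  onset → last offset); pulse rate = pulse number / total duration (the
  printed group means of the source data cannot disambiguate this from the
  reciprocal-interval definition; the alternative is available via
  `pulse_rate_mode`).

Measured recovery at amplitude/noise 5 across the reported parameter scales
(the acceptance suite recomputes this): median relative errors ≈6% for
duration, ≈4% for SNR, ≈0.2% for dominant frequency, and ≤3% for all five
serial parameters, with pulse counts exact.

`reduce_variables` ranks features by first-principal-axis loading and
greedily drops any feature whose absolute Spearman correlation with a
retained one exceeds the threshold (default 0.9); the adequacy report flags
any group with fewer than ten events per retained variable.

## Population-signature statistics

- **Assumption checks**: per-group normality via the Lilliefors-corrected
  Kolmogorov–Smirnov test (group means and SDs are estimated from the data;
  the uncorrected KS test would be far too conservative), homoscedasticity
  via Bartlett; flags at α = 0.05.
- **Kruskal–Wallis**: tie-corrected H; chi-square p-value, except that a
  pooled sample of ≤ 10 observations switches to the exact p from full
  enumeration of the permutation distribution of H. Dunn's post hoc
  z-tests use the tie-corrected rank variance; the default multiplicity
  adjustment is Bonferroni (Holm, Benjamini–Hochberg and none are
  options). All of it is rank-based, hence invariant under monotone
  transformations.
- **PCA acoustic space**: correlation-mode by default (features are
  z-scored — their units differ by orders of magnitude; covariance mode is
  an option). Constant columns are dropped with a warning. Per-group 95%
  ellipses are chi-square(2) quantile contours of the group's score
  covariance; simulated coverage is checked to sit in [0.93, 0.97].
- **pDFA**: the observed discrimination quality is the leave-one-out
  cross-validated linear-discriminant reclassification rate; the null
  repeats it on seeded label permutations and
  p = (#{null ≥ observed} + 1)/(B + 1). The LOO refits use a rank-one
  (Sherman–Morrison) downdate of the pooled within-class scatter, making
  the permutation loop cheap; predictions are verified identical to
  scikit-learn's LDA under explicit leave-one-out. A singular scatter
  triggers flagged ridge regularization. This is the simple
  label-shuffling pDFA; a nested/crossed variant for repeated measures on
  identified individuals is out of scope (the data model has no individual
  identity), a known limitation.
- **Geo-projected clustering**: groups are summarized by the median of
  their z-scored feature vectors, merged by average linkage on Euclidean
  distances; the tree serializes to Newick (merge heights as branch
  lengths, round-trippable with standard tree tooling) and plots with
  leaves at cave (longitude, latitude).

## Numerical and interface conventions

All times are seconds from recording start with half-open windows
[onset, offset); features report ms and Hz as conventional units. The
canonical sample rate is 44.1 kHz (hydrophone band is flat to ~4.5 kHz and
the sounds span 0.5–10 kHz); templates and recordings at different rates
are polyphase-resampled to match. Multichannel WAV input is averaged unless
a channel is selected — which channel of a stereo field recorder was
analyzed is not externally specified. Waveform sample counts use half-up
rounding (a 5 ms click at 44.1 kHz is 221 samples). WAV I/O is PCM16/24/32
and float; annotation CSVs round-trip float64 exactly (`%.17g`).

## Problem sizes used in validation

The test and acceptance suites scale the study conditions to: one
20-minute / 200-click soundscape for threshold tuning and detection
recovery; 9-configuration sweeps (≈180 single clicks, ≈135 serial trains)
for feature recovery; 2000 null replicates for Kruskal–Wallis calibration,
200 seeded null datasets (99 permutations each) for pDFA calibration,
2000-point groups for ellipse coverage; and 20 seeded replicates of the
four-population end-to-end discrimination test (25 clicks per population,
dominant-frequency means 2 within-group SDs apart, 199 permutations).
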