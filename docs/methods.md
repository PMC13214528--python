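# Methods

## The modeling chain

`audsurp` models how deviant sound tokens embedded in complex scenes are
detected, both in button-press behavior and in the pupil dilation response
(PDR). The chain is: acoustic features → per-feature Bayesian surprisal →
cross-feature integration by constrained regression → binary deviance
targets from behavior or pupillometry → discrimination/correlation
evaluation.

### Acoustic features

Waveforms are resampled to 16 kHz. Six channels are extracted and mean-pooled
into 100 ms frames (10 Hz):

- **envelope** — |analytic signal|, low-passed by a 6th-order Butterworth at
  40 Hz. Filtering is zero-phase (forward–backward) so the envelope stays
  time-aligned with the spectrogram-derived channels.
- **auditory spectrogram** — 128 constant-Q bandpass filters (4-pole
  Butterworth, quarter-octave bandwidth), half-wave rectification, 10 ms
  energy frames. Center frequencies are log-spaced over exactly 5.3 octaves
  from 180 Hz. This is a light-weight stand-in for a cochlear filterbank
  with the same channel geometry.
- **pitch** — harmonic-template matching on the spectrogram (f0 grid
  80–1200 Hz at 1/24-octave steps; templates are the first 8 harmonics with
  1/k weights, linearly interpolated onto the channel grid), log2-transformed,
  median-filtered (window 5); frames whose first derivative deviates from its
  mean by more than two SDs, and low-energy frames (below 1 % of the trial
  maximum), hold the preceding value.
- **spec_low / spec_high** — mean spectrogram energy below / above 1120 Hz.
- **scale / rate** — magnitudes of spectral-modulation filters
  (2⁻⁴…2⁴ cycles/octave, 9 log-spaced Gaussian bands applied along the
  log-frequency axis) and temporal-modulation filters (2–32 Hz along time),
  averaged over filters and channels. The rate-filter grid and the use of
  unsigned magnitudes are package defaults; they are declared here because
  no standard fixes them.

### Surprisal (run-length filtering)

Each channel is treated as piecewise-stationary Gaussian with unknown mean
and variance. A run-length filter tracks contexts (frames since the last
change) under hazard `H = 0.5`; each context carries conjugate
normal–inverse-gamma statistics (`κ0 = a0 = 1`; `μ0` and `b0 = a0·var` from
the trial's first time quadrant, variance floored at 1e-6), giving Student-t
posterior predictives. The surprisal of frame *t* is the negative log2 of
the belief-weighted predictive density, computed *before* absorbing the
frame. Beliefs then branch: each context grows with probability `1−H` and a
fresh prior context spawns with probability `H`. All mixture arithmetic is
in log space; contexts with belief below 1e-6 are pruned and at most 50 are
kept. With pruning disabled the recursion is exact: it matches brute-force
marginalisation over all change-point configurations to ~1e-15 (the test
suite asserts 1e-8 over 20 random length-8 sequences). A vectorised batch
path (`run_drex_batch`) runs many equal-length series simultaneously and is
bit-compatible with the sequential filter.

Only first-order temporal dependence is implemented; the quadrant-based
prior is applied to every context's prior, not just the first.

### Integration model

Per feature, surprisals are min–max normalised to [0, 1] using the minimum
and maximum over *all* trials jointly, then values below the feature's
pooled 70th percentile (linear-interpolation convention) are zeroed.
Normalisation and sparsification are applied to the raw surprisals before
boosting: training needs the boosted form, and the boost needs trained
weights, so the preprocessing must precede both.

The boost couples features within ±100 ms (±1 frame at 10 Hz):
`s'_i = s_i (w_ii + Σ_{j≠i} w_ij · windowed-max of s_j)`, with the window
clipped at trial edges. Probabilities are `α_i = tanh(s'_i/2)` (identically
`2/(1+e^{−s'}) − 1`) and `α` is their mean. Training maximises the Bernoulli
log-likelihood `Σ_t y log α_i + (1−y) log(1−α_i)` row by row (six
independent bound-constrained L-BFGS-B problems, `w ≥ 0`, start at the
uniform model `w_ii = 1`, analytic gradients, ftol 1e-6, 500 iterations);
`α` is clamped to [1e-9, 1−1e-9] inside the likelihood only. Standard
errors come from the observed information (central differences of the
gradient; one-sided at the nonnegativity boundary, where they are nominal).
The 6×6 matrix reduces to 3×3 perceptual attributes (loudness = envelope;
pitch = pitch + spec_low; timbre = spec_high + scale + rate) by block means,
within-group off-diagonals included.

### Targets

`y(t) = 1` for `t0 ≤ t < t0 + Δt` with Δt = 1.2 s (Music) or 1.4 s
(Nature); frames are stamped at bin centers and the window is half-open.
Hits anchor `t0` at the true onset; false alarms at the earliest peak of the
summed sparsified surprisal; misses and correct rejections are all-zero
targets. For pupil models, epochs are condition-averaged within the 32
cells (2 loudness × 2 pitch × 2 timbre × 4 quadrants; the Music
background/foreground instrument pair is collapsed to same-vs-different)
and controls are randomly grouped into clusters of four; `t0` is the peak
of the averaged PDR within one second after the deviant onset (earliest
maximum on ties). Each condition cell pairs its PDR-derived target with the
mean of its member trials' sparsified surprisal; an alternative pairing
(per-trial surprisal with the cell's shared target) was evaluated and
produced less stable weights.

### Pupil preprocessing

Right-eye traces at 1000 Hz, never low-pass filtered. Blink samples and
samples with gaze farther than 2 visual degrees from fixation are replaced
by shape-preserving piecewise-cubic (PCHIP) interpolation; edge gaps take
the nearest valid value; recordings without a blink column fall back to
dilating zero-diameter runs by ±50 ms. Traces are z-scored against all
samples of the session, epoched to [−1 s, duration + 2 s] and
baseline-corrected by the 1 s pre-stimulus mean. Binarisation marks samples
at or above 90 % of the epoch peak.

### Evaluation

A trial's score is its maximum α; at each threshold θ in 0…1 (step 0.01) a
deviant trial with score ≥ θ is a hit and a control trial a false alarm,
and AUROC is the trapezoid area with (0,0)/(1,1) padding. Trial-global
scoring is the default: it treats the model like the subject (a keypress is
a hit wherever the evidence crossed threshold), and it makes the
shuffled-onset null exactly symmetric. A window-restricted variant
(`window_only=True`) and a score-augmented threshold grid
(`augment_scores=True`) are available; note the augmented grid makes AUROC
purely rank-based, which pins every positive-monotone model (including
shuffled-trained ones) to nearly the same value.

The behavioral model is evaluated leave-one-subject-out: one weight matrix
per training subject, averaged, applied to the held-out subject. The
uniform baseline uses the identity matrix. The random baseline shuffles
deviant-onset labels across each subject's trials — for training *and* for
scoring that model — making it a permutation null whose AUROC expectation
is 0.5; a model trained on shuffled onsets but scored against true labels
cannot reach chance, because any nonnegative weight matrix ranks trials by
their surprisal peaks. Ten shuffled refits per subject are averaged
(five for PDR models).

PDR models are scored per condition cell by the maximum normalised
cross-correlation `C(τ) = Σ a b / √(Σa²Σb²)` within |τ| ≤ 3 s, model α
interpolated to 100 Hz against the binarised condition-averaged PDR pooled
to 100 Hz. Quadrant models train on one quadrant's deviants plus a random
quarter of controls (each control used exactly once per pass), ten
bootstrap passes averaged. d′ is `Φ⁻¹(hit) − Φ⁻¹(FA)` per factorial cell
with rates clamped to [0.01, 0.99] (bounding |d′| at 4.6527); the four-way
repeated-measures ANOVA (loudness × pitch × timbre-background ×
timbre-foreground, 15 effects) uses the within-subject sums-of-squares
decomposition.

## Synthetic studies

The generator fixes the study conditions once:

- **Design** — Music: 5 s trials, 1.2 s tokens, levels {2, 6} dB and
  {2, 6} semitones; Nature: 6 s trials, 1.3–1.5 s tokens, {2, 8} dB,
  {0, 3} semitones; 128 trials per session, half controls; deviant onsets
  uniform within one of four equal quadrants, with factorial cells tiled in
  shuffled blocks and quadrants rotated per cell so the design stays
  balanced at any trial count.
- **Features** — per-channel Gaussian backgrounds (trial means drawn from a
  subject-level prior, SD 0.3 around it; frame noise SD 1). Channels share a
  common per-frame component (correlation 0.5): a scene of overlapping
  tokens drives every acoustic dimension at once, and without this shared
  fluctuation the windowed cross-channel maxima become artificially clean
  deviant indicators. Deviants add a mean shift over the token:
  1.5 σ/dB on the envelope, 2 σ/semitone on pitch, 1 σ/semitone on
  spec_low, and 4 σ on each timbre channel when the instrument/species
  differs. The transfer gains are calibrated so the forward model's hit
  rates are monotone in level with realistic false-alarm rates; they are a
  declared mapping, since only the stimulus-level differences are known.
- **Behavior** — detection probability is the trial's maximum α under the
  true weight matrix (default 4·I, giving clear detectability of strong
  deviants) mixed with a 5 % lapse of fair guessing. Because α averages six
  channels and sparsified backgrounds keep 30 % of frames, this forward
  model has a false-alarm floor of roughly 0.2 — a generator limitation,
  not a property of the estimation code.
- **Pupil** — sessions concatenate 1 s pre-stimulus + trial + 2 s post +
  2 s gap (a 5 s inter-trial interval). Deviants add a gamma kernel (shape
  3, scale 0.5 s; peak 1.0 s after the deviant) scaled by per-feature gains
  times the injected shifts; noise SD 0.5 z (single-trial PDR signal-to-noise
  near 1, as in practice); 2–10 blink gaps of 50–400 ms per trial zero the
  diameter; gaze jitters with occasional >2° excursions.
- **Audio** — scenes of overlapping harmonic tokens on a pentatonic grid;
  the deviant token is raised by the condition's dB/semitones and given an
  odd-harmonic (brighter) envelope when the timbre differs. Audio is a
  schematic rendering for exercising the front end, not perceptually
  realistic music or birdsong.

Two canned study designs differ from the defaults for identifiability: the
*recovery* and *quadrant* experiments use a one-to-one condition→channel
mapping with levels that include zero (loudness {0, 8} dB → envelope only;
pitch {0, 6} st → pitch only), so channels deviate independently and
planted cross-weights are identifiable.

## What the experiments show — and what they cannot

- **Recovery** (planted cross weight 0.5, identity self-weights): per-row
  binary targets drawn from each row's true deviance probability are
  refitted by the constrained estimator; the recovered pattern correlates
  with the truth at ≥ 0.97 and the planted entry tops every true-zero cross
  entry. This is an estimator-consistency check. Recovery through the
  *trial-level* detection bottleneck (responses from max α) cannot identify
  cross-weight direction: the shared deviance windows are symmetric in
  (i, j), so `w_ij` and `w_ji` are exchangeable there — a genuine
  identifiability limit of window-based training, verified empirically.
- **Ordering**: trained > uniform > random AUROC holds in essentially every
  seeded study, with the permutation-null random baseline at 0.5.
- **Quadrant dynamics**: with interactions active only after quadrant 1,
  the mean recovered cross weight over quadrants 2–4 exceeds quadrant 1.
  Quadrant 4 alone is attenuated because late windows are truncated at the
  trial end.
- **Pupil dissociation** — known limitation. The fitted PDR model robustly
  out-correlates its shuffled-onset baseline. But the companion claim — no
  significant cross-feature weights when the pupil truth has none — does
  not emerge from this generator: deviants co-elevate a small set of
  channels at known times, so the windowed max of another deviating channel
  is itself informative about deviance windows and the constrained fit
  assigns it consistent positive weight, significant both against zero and
  against the bias-matched shuffled baseline. (A one-sample t-test against
  zero is additionally ill-posed for boundary-constrained estimates, whose
  means are positive under pure noise.) Richer background statistics —
  real scenes in which cross-channel coincidences are ubiquitous rather
  than deviant-locked — would be needed for the cross terms to carry no
  information; the low-dimensional synthetic background cannot provide
  that, and the corresponding acceptance check is expected to fail.

Passing tests therefore demonstrate the correctness of the filter, the
integration algebra and the estimation machinery, and the qualitative
behavior of the evaluation pipeline on data matching the model's
assumptions. They do not certify performance on real recordings, where the
feature statistics, pupil dynamics and behavioral strategies are richer
than the generator's.

## Numerical choices

- Probability arithmetic in log space throughout the filter; surprisal may
  be negative (densities above 1) and is never clamped — downstream min–max
  normalisation absorbs the offset.
- Ties in any argmax (false-alarm anchor, PDR peak) break to the earliest
  time.
- Median/derivative cleaning of the pitch track uses reflect padding, so
  the trial onset carries no filter artifact; trailing/leading pupil gaps
  take the nearest valid sample.
- The RM-ANOVA reports F = 0 when an effect's sum of squares is exactly
  zero (statsmodels yields 0/0 there).
- Constant feature channels abort normalisation with the channel named;
  constant channels are legal inside the filter (variance floor).
- Trial records validate their own invariants (controls carry no onset;
  onsets lie inside their quadrant).
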