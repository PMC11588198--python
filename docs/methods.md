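# Methods

`pcgseg` implements a hybrid algorithm for analysing 4 kHz phonocardiograms:
a discriminative recurrent frame classifier supplies per-frame state
posteriors, and a bank of four generative duration-explicit hidden
semi-Markov models (HSMMs) turns those posteriors into competing
whole-recording interpretations.  Comparing the interpretations yields a
heart-sound segmentation, a systolic-murmur decision with timing, a
signal-quality estimate, and inputs for a patient-level clinical-outcome
classifier.  This note documents the model, the defaults, the numerical
conventions, and what the synthetic data does and does not establish.

## Signal model and feature extraction

A recording `r_{1:N}` is demeaned and scaled to unit peak amplitude
(stethoscope pressure makes absolute amplitude uninformative; constant
recordings are rejected).  Features are a log power spectrogram with a 50 ms
Hann window stepped by 20 ms: the window is long enough to resolve 20 Hz
frequency structure yet shorter than the ~100 ms S1/S2 transients, so the
major sounds stay localised in time.  At fs = 4000 Hz this is a 200-sample
window (no zero padding, one-sided FFT, magnitude-squared power, floored at
1e-10 before the log), hopped by 80 samples, giving
`T = floor((N-200)/80)+1` frames.  Rows above 800 Hz carry no heart-sound
information and are discarded, leaving 41 bins at 0, 20, …, 800 Hz.
Finally every frequency row is z-scored across time (population standard
deviation; constant rows map to zero).  Murmurs carry an order of magnitude
less energy than valve sounds; the per-row normalisation brings their
broadband signature onto the same scale.  A config switch
(`zscore_rows(..., use_variance=True)`) divides by the variance instead,
for users who prefer that reading; the default is the conventional z-score.
The whole chain is deterministic and invariant to positive amplitude
scaling of the input.

## Frame classifier

Ground truth is a per-frame sequence over five states
(S1, systole, S2, diastole, murmur).  Interval annotations are rasterised
by frame-centre containment (centre of frame t is `t*0.02 + 0.025` s); a
clinician's murmur-timing label is expanded into murmur frames inside each
systolic period: the first `ceil(L/2)` frames for early-systolic, the middle
`ceil(L/2)` (offset `floor(L/4)`) for mid-systolic, all `L` for
holosystolic.  The 50% fraction rounds up on odd-length periods, and a
systolic period is identified as a maximal run of systole-or-murmur frames,
which makes the expansion idempotent.  Diastolic murmurs are not
representable by design.

The classifier is a three-layer bidirectional GRU with hidden size 60; the
concatenated forward/backward outputs (120 values per frame) pass through
fully connected layers of 60 and 40 units with Tanh activations and a
softmax over the five states.  Dropout 0.1 is applied between the recurrent
stack and the head only.  Training minimises cross-entropy with
inverse-frequency class weights (normalised to mean 1; a state absent from
the training labels is an error) using Adam.  The network and its gradients
are implemented directly on numpy arrays; backpropagation is verified
against central finite differences in the test suite.

Defaults the architecture does not pin down: learning rate 1e-3, batch size
16 recordings, up to 50 epochs with early stopping (patience 10) on a 15%
recording-level validation split, returning the best-validation weights.
Sequences are batched by equal frame count so no padding is needed (padding
frames would distort the class weights).  One seed drives initialisation,
batch order, dropout and the validation split; training is exactly
reproducible.

## Heart-rate estimation

The per-frame probability of *not* being in diastole
(`1 - P(diastole)`) pulses once per cardiac cycle and is far cleaner than
an amplitude envelope, because the classifier has already suppressed noise
and murmur energy enters the numerator consistently.  Its autocorrelation
(mean-removed, biased, normalised to 1 at lag zero) is searched for peaks
with lags in the 30–180 bpm window, the upper bound covering paediatric
rates.  Peaks are strict local maxima; ties go to the smaller lag.  A
candidate whose doubled lag has an autocorrelation more than 5% higher is
rejected as a half-period alias (the S1–S2 spacing).  The winning integer
lag is refined by parabolic interpolation of the autocorrelation around the
peak — the true period rarely sits on the 20 ms frame grid, and without
interpolation rates near the 180 bpm edge quantise outside the window — and
clamped into the bpm range.  On synthetic recordings across 60–180 bpm the
median absolute error is well under the 5 bpm tolerance the duration
scaling needs (the acceptance script reports it, typically below 1 bpm).

## Parallel duration-explicit HSMMs

Four models reinterpret the posterior matrix, sharing state durations but
differing in topology and observation mapping:

| model  | cycle                                      | observation mapping |
|--------|--------------------------------------------|---------------------|
| omega1 | S1 → systole → S2 → diastole               | murmur column dropped, rows renormalised |
| omega2 | S1 → systole → S2 → diastole               | systole state reads the murmur column |
| omega3 | S1 → murmur → systole → S2 → diastole      | direct columns |
| omega4 | S1 → sysA → murmur → sysB → S2 → diastole  | sysA/sysB read the systole column |

omega1 is the no-murmur hypothesis; omega2 holosystolic (the systolic
period *is* murmur); omega3 early-systolic (murmur immediately after S1);
omega4 mid-systolic.  A mid-systolic murmur cannot be placed inside a
single systolic state of a cyclic chain, so omega4 splits systole into
halves around the murmur.  For omega1 the murmur posterior is discarded and
each row renormalised over the remaining four states, keeping its
confidence on the same [0, 1] scale as the five-state models.

State dwell times are Gaussian.  S1 and S2 means are fixed at 0.122 s and
0.092 s; the rest of the beat period (60/bpm, from the heart-rate estimate)
is split systole : diastole = 1 : 1.7, so each model's cycle of means sums
exactly to the period.  In omega3 the murmur and systole states split the
systolic share 50/50; in omega4 the split is 25/50/25, mirroring the
labelling rule.  Standard deviations are 25% of each mean.  All of these
are config-exposed constants.

Decoding maximises `sum_t log obs(q_t) + sum_interior log N(d; mean, sd)`
over segment boundaries, durations and entry phase, with duration support
truncated to mean ± 3 sd (clipped to ≥ 1 frame).  Recordings start and end
at arbitrary cycle phase, so the first and last segments are treated as
partial: they carry observation cost and the duration-support cap but no
duration penalty (a single segment covering the whole recording carries
none).  Arithmetic is in the log domain with observations floored at 1e-12.
The dynamic program is O(T · states · max-duration); a brute-force
enumeration over all duration-valid segmentations reproduces its score and
path exactly on small instances.

The confidence of a model is the mean posterior mass along its decoded
path, each decode state reading its own observation column.  The most
confident model wins (ties to the lower index).  A murmur is detected when
a murmur model wins; the murmur likelihood is
`C(M-N) = max(C(omega2..4)) - C(omega1)` and the chosen model's confidence
doubles as signal quality.  The per-frame argmax ("greedy") segmentation is
retained as a baseline: it maximises per-frame posterior mass but allows
physically impossible transitions such as S2 → systole.

## Patient-level rules

A patient is murmur-present if any recording's winning model is a murmur
model.  Otherwise the mean of the chosen-model confidences across the
patient's recordings is compared with 0.65: below it the patient is
"unknown" (uninterpretable signal), at or above it "absent".  The paper-level
rule does not say how multiple recordings aggregate for the unknown
decision; the mean is the default and `aggregate="min"` is available.

Clinical outcome (normal/abnormal) is predicted by a gradient-boosted
decision tree over an 11-value feature vector: per-site averages of C(M-N)
and of signal quality for the four auscultation sites (sites not recorded
are genuine missing values, handled natively by the tree learner —
recordings from non-standard sites are pooled into the mitral position with
a warning), plus ordinal age band, pregnancy flag and recording count.
Hyperparameters: depth 9, abnormal class weight 1.8 (normal 1.0), decision
threshold 0.4738, 200 boosting iterations at learning rate 0.1 (run in
full; no early stopping, for determinism on small cohorts).  The
implementation is LightGBM.

## Synthetic data

The generator produces what the pipeline assumes and nothing more: cycles
of Gaussian-windowed tone bursts for S1 (100 ms, 60–120 Hz) and S2 (80 ms,
100–200 Hz, 0.7 amplitude), a systolic interval of 30% of the cycle,
cycle-length jitter of ±5%, optional murmurs as 100–400 Hz band-passed
noise occupying the first half / middle half / whole of systole, additive
white noise (default 20 dB SNR), and exact ground-truth intervals.  Murmur
loudness tiers are −12/−6/0 dB relative to the S1 burst RMS (quiet /
moderate / loud).  Heart rates are drawn uniformly from 60–180 bpm.
Cohorts add 1–4 distinct auscultation sites per patient, a shared murmur
timing, an "unknown" fraction (default 5%) realised as heavily
noise-corrupted recordings, and an abnormal outcome drawn with probability
`sigmoid(-1.2 + 2.0·murmur + 0.5·grade)`, so a fraction of abnormal
patients have no audible murmur.

A separate feature-level cohort generator draws per-recording murmur
likelihoods and qualities directly (murmur recordings
C(M-N) ~ N(0.15, 0.08), normal N(-0.10, 0.06), quality ~ Beta(8, 2)) and
plants `P(abnormal) = sigmoid(-1.0 + 20·max C(M-N))`.  The coefficients are
set so the relationship is strong but noisy: the probability-optimal
classifier scores about 0.92 AUROC, leaving room for a fitted model to
demonstrate recovery (≈ 0.9) without the task being deterministic.

What the synthetic data does **not** contain: real murmur spectra and
grades, S3/S4 sounds, diastolic murmurs, respiratory and motion artefacts,
device coloration, inter-patient anatomical variability.  Passing the
end-to-end tests therefore shows that the implementation is internally
correct and that the comparative-confidence mechanism works when its
assumptions hold; it does not certify clinical performance, which the
published cross-validation numbers address on real data.

## Problem sizes and numerical conventions

The packaged end-to-end experiment trains on 200 simulated 10 s recordings
for 12 epochs and evaluates on 100 held-out recordings — sizes chosen so the
full suite runs comfortably on a single CPU while still reaching frame
accuracies around 0.96 and murmur AUROC near 1.0 on this clean data.
Tolerances and floors: observation floor 1e-12, spectrogram power floor
1e-10, z-score tolerance 1e-6, duration support mean ± 3 sd.  Ties break
deterministically everywhere (greedy argmax to the earlier state, model
argmax to the lower index, autocorrelation peaks to the smaller lag).

## Known limitations

* The murmur likelihood saturates for loud murmurs: above roughly 0 dB SNR
  the classifier's murmur posterior is already ~1 inside the murmur, so
  C(M-N) stops increasing with loudness (monotonicity holds in rank, with a
  plateau at the top).
* The decoder's partial first/last segment convention slightly favours long
  entry/exit dwells, since they escape the duration penalty.
* Only systolic murmurs are modelled; diastolic murmurs are invisible to
  both the labels and the model bank.
* The outcome classifier inherits whatever murmur-detection errors the
  upstream pipeline makes; its features are averages, so a single bad
  recording at a site dilutes rather than dominates.
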