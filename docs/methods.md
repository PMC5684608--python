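# Methods

## Signal model and scope

The predictor operates on multichannel scalp EEG, segmented into
overlapping epochs, and uses only the *second-order spatial structure* of
the signal: every quantity downstream of segmentation is a function of
per-epoch channel covariances. Times are in seconds, intervals half-open
`[start, end)`, sample indices 0-based. Each patient's records are placed
on one global clock (record order plus declared start times); recording
gaps ("missing hours") are derived as the complement of coverage, which the
postictal-merging, gap-margin and horizon rules all need.

## Seizure policy

Two preprocessing rules are applied to raw annotations before anything is
trained or scored:

* a seizure whose onset falls within the postictal interval (default
  600 s) after the previous seizure's offset is merged into it;
* a seizure with less recorded signal before onset than one preictal
  training interval is marked excluded. The exclusion threshold is
  deliberately tied to the configured preictal length (180/300/600 s): a
  seizure that cannot supply a full preictal window cannot be trained on or
  fairly counted. The operation is idempotent.

## CSP derivation

For an epoch `D` (channels × samples) the normalized covariance is
`C = DDᵀ/trace(DDᵀ)` — no mean removal, per the classical form; EEG is
high-pass-filtered at acquisition and epochs are short. Class covariances
are the arithmetic means of per-epoch normalized covariances (each epoch
normalized *before* averaging, so every epoch contributes equal weight
regardless of amplitude).

Two numerical choices deserve note, both forced by internal consistency:

* **Square-root whitening.** `P = ψ^(−1/2) F_cᵀ` is used, which is the
  unique member of the whitening family satisfying `P C_c Pᵀ = I`; only
  then do the whitened class matrices share eigenvectors with eigenvalue
  pairs summing to exactly one (`Λ₁ + Λ₂ = I`), the property the tests and
  the acceptance script verify to 1e−8.
* **Whitened class matrices.** `S₁ = P C₁ Pᵀ` and `S₂ = P C₂ Pᵀ` (the two
  *class* covariances, not the composite) are what is simultaneously
  diagonalized; any other choice degenerates.

Eigen-decompositions use symmetric routines; eigenvalues are sorted
descending with eigenvector signs fixed so the first nonzero component is
positive (reproducibility under permutation/sign ambiguity). If the
composite covariance's condition number exceeds 1e12, a ridge of
1e−10·trace is added and logged. Class 1 is preictal, so leading rows of
`W = UᵀP` maximize preictal variance; since *all N* filters are kept as
features (a 23-channel montage yields a 23 × 1 vector), the sort direction
only fixes component order.

Features are natural logarithms of per-row sample variances (ddof = 1);
the log base is a monotone choice invisible to a linear classifier and is
fixed for reproducibility.

## Classifier and smoothing

LDA is solved in closed form with equal priors — justified because training
sets are balanced first by random undersampling of the majority class
(uniform, without replacement, seeded per cross-validation round). The
pooled within-class covariance is shrunk toward its diagonal with
coefficient 1e−3 by default: 23-dimensional log-variance features estimated
from a few hundred preictal epochs are otherwise close to singular. Ties
(`w·x + b = 0`) classify as interictal — the conservative direction for an
alarm system. The 1 Hz decision series is smoothed by a seventh-order
sliding median with reflected edges (truncation would bias the first and
last three seconds toward zero).

## Alarm logic

An alarm fires at the first instant a run of consecutive preictal decisions
reaches the threshold α, and at most once per maximal run — the run must
break before the detector can re-arm. This is the only reading of a
"consecutive-ones count with a 1 s moving window" that produces a countable
alarm series. α is selected from the grid {3, 5, 10, 20, 40, 60, 90, 120}
seconds by maximizing training sensitivity, tie-broken by lowest false-alarm
rate, then by the largest (most conservative) α; the selection criterion is
this package's stated choice, as is per-round (rather than per-patient)
selection.

Alarm classification: positive inside `[onset − horizon, onset)` of a
non-excluded seizure; discarded inside ictal/postictal time, within the
10-min margin of a recording gap, or inside the horizon of an *excluded*
seizure (that seizure is outside the sensitivity denominator, so penalizing
its horizon as false time would be inconsistent); false otherwise.
Same-type alarms inside an earlier alarm's horizon merge into it.

## Evaluation metrics

Specificity follows the false-waiting-time formulation `spec = 1 − fwt/np`.
Normal intervals run from the end of one seizure's posthorizon (taken equal
to the 10-min postictal interval — the posthorizon length is otherwise
unspecified, and this is logged) to the start of the next seizure's
horizon, with coverage start opening the first interval. After the last
seizure no normal interval is emitted, because no following seizure defines
its end; a record set with no seizures is entirely normal time. These
boundary conventions reproduce the reference arithmetic exactly: 6 h of
coverage with one seizure at hour 5 and a 60-min horizon gives a single
normal interval [0 h, 4 h), and false alarms at hours 1 and 2.5 each open a
one-hour waiting window, so fwt = 2 h and spec = 50 %.

`fwt` is the *union* of per-alarm waiting windows clipped to their normal
interval — a summed version could exceed `np` and push specificity below
zero. The FPR denominator is evaluated time: coverage minus ictal,
postictal, and gap-margin seconds (the rate's base is not otherwise pinned
down; per-hour rates require one). Prediction time is measured from the
*earliest* positive alarm in a seizure's horizon to onset. Baselines raise
alarms periodically with period T, or at exponentially distributed
intervals with mean M (seeded); both default to the patient's average
interictal interval.

## Cross-validation protocol

Leave-one-recording-out with inner model selection: per round, the N − 1
training records are split into up to 5 folds; CSP + LDA fitted on the
complement scores each fold, and only α is selected from the pooled inner
alarm performance. CSP and LDA are then refit on all N − 1 records and all
parameters are frozen before the held-out record is scored. This keeps the
held-out record untouched by covariance averaging, LDA fitting,
undersampling and α selection (asserted by instrumentation in the tests).
Interictal *training* epochs come only from seizure-free records;
interictal *testing* epochs are all non-excluded, non-preictal time. Rounds
whose held-out record has no seizure contribute specificity/FPR but not
sensitivity or prediction time; averages skip not-applicable entries.

## Synthetic data generator

The generator emulates exactly the features the method consumes and no
others: zero-mean stationary multichannel Gaussian signal whose spatial
covariance switches between an interictal and a preictal matrix, a seizure
timeline with configurable preictal windows, optional gaps excised from
coverage, and ictal bursts (preictal covariance × 5 — ictal content is
excluded from training and evaluation, so it only needs to exist). The two
covariances share a random orthogonal eigenbasis with log-spaced base
eigenvalues spanning one decade; a single `separation` knob scales the
preictal eigenvalues by `exp(separation · s_i)`, `s_i ∈ [1, −1]`, making
the generalized eigenvalue spectrum known in closed form
(`1/(1 + e^(−separation·s_i))`) — separation 0 gives identical matrices and
a flat spectrum at 0.5. All randomness flows from explicit per-call seeds.

What the generator does **not** model: 1/f spectra, rhythms, artifacts,
electrode drift, nonstationarity. Passing tests therefore demonstrate that
the pipeline recovers *spatial covariance structure* when present and finds
nothing when absent; they say nothing about how strongly real preictal EEG
expresses such structure.

## Problem sizes and defaults

The generator's default sampling rate is 256 Hz with 3 s / 768-sample
epochs, matching the recordings it emulates. The test suite and the
end-to-end demos run at 64 Hz with 8 channels and 6 × 10-minute records —
sizes chosen so a full leave-one-out run with inner α selection completes
in seconds while every covariance estimate still averages hundreds of
epochs. With 10-minute records and 60-minute horizons, normal intervals are
structurally empty, so the synthetic end-to-end runs exercise sensitivity,
FPR and prediction time; specificity is exercised by the worked-example and
metric-level tests, where its arithmetic is exact.

At zero separation the predictor's cross-validated sensitivity is compared
against a rate-matched Poisson baseline with an additive margin rather than
a significance test: on these short timelines both alarm generators
saturate near sensitivity 1 (the horizon exceeds the mean inter-seizure
interval), and the check guards against the predictor *appearing* to beat
chance, not against saturation.

## Known limitations

* Records of one patient must share a channel set; harmonization drops
  extra channels with a warning and treats missing ones as an error.
* EDF is read (via mne) but never written; the portable container is a
  versioned `.npz`.
* The preictal-window membership rule is "entirely within" — epochs
  straddling the window boundary count as interictal, and preictal windows
  clipped by record boundaries lose their uncovered epochs (logged), rather
  than being shortened.
* Only the three preictal lengths 3/5/10 min and offsets 0/60/120 min are
  exposed; multi-class CSP, filter banks, shrinkage-CSP variants and
  probabilistic alarms are out of scope.
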