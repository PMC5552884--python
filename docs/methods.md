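# Methods

This note documents the models, numerical choices and limitations of the
`hbci` package: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where genuinely open design
choices were resolved.

## The decision model

A participant *p* observes a briefly presented scene and decides whether a
target is present, `d_{p,i} ∈ {+1, −1}` on trial *i*, with response time
`RT_{p,i}`. Decision confidence is defined as the probability that the
decision is correct. The hBCI estimates it from trial-resolved features and
uses it to weigh votes in the group decision

G_i = sign(Σ_p w_{p,i} · d_{p,i}),

ties (an exactly zero sum) being resolved by a fair coin flip. Weighting
variants: plain majority (w ≡ 1), RT-only (RTCI), neural-only (nf-BCI),
neural + RT (hBCI), reported confidence used raw on its 0–100 scale
(Confidence Majority), and plain majority over post-communication second
responses.

## Preprocessing

Continuous EEG (64-channel 10–20 montage, 2048 Hz) is:

1. re-referenced to the average of the two earlobe electrodes (the
   reference channels are zeroed and dropped from analysis);
2. band-pass filtered 0.15–40 Hz with a linear-phase FIR filter
   (14,677 taps at 2048 Hz; the tap count scales pro rata with the
   sampling rate so the transition widths in hertz are preserved). The
   kernel is built as the difference of two unit-DC-gain windowed-sinc
   low-passes, which nulls DC exactly. Filters are applied forward with
   odd-length symmetric kernels and `same` convolution, so the net group
   delay is zero and ERP latencies are preserved (whether the original
   recordings were filtered zero-phase is not documented anywhere; this is
   our choice);
3. corrected for ocular activity by regressing out the proxy
   o(t) = ½[(Fp1−F1) + (Fp2−F2)]: each channel has its least-squares
   projection onto the mean-centred proxy subtracted, leaving it
   uncorrelated with o. A zero-variance proxy leaves the recording
   unchanged with a logged warning.

Per trial, two raw 1900 ms epochs are cut: stimulus-locked
[−200, +1700) ms and response-locked [−1200, +700) ms. Windows crossing a
recording edge exclude the trial (logged). Each epoch is linearly
detrended per channel, low-pass filtered with an equiripple (Remez) design
(pass edge 14 Hz, stop edge 16 Hz, ≥40 dB stop band), trimmed to the
central 1500 ms and decimated to 32 Hz, yielding exactly 48 samples per
channel (3,072 values for 64 channels).

Sample bookkeeping: 1900 ms at 2048 Hz is 3891.2 samples; we extract
⌈1.9·fs⌉ = 3892 samples and trim 410 per side, leaving exactly
3072 = 48·64 samples before decimation by 64. At other rates the same rule
applies with the (integer) decimation factor fs/32; odd trim remainders
drop the extra sample from the right edge. All windows are half-open in
sample indices, and the event sample belongs to its epoch. The 14/16 Hz
low-pass already satisfies the anti-aliasing requirement of the 32 Hz
output rate, so no extra anti-alias stage is added.

## Features

CSP solves the generalized eigenproblem Σ_a w = λ(Σ_a + Σ_b) w on the two
class covariances (correct = "confident" = label −1; incorrect =
"non-confident" = +1). Covariances are per-trial channel covariances
normalised by their trace and averaged within class; if the composite
covariance is ill-conditioned (condition number > 1e10) a small ridge
(1e-6 toward the scaled identity) is applied and logged. Filters are
sorted by decreasing variance ratio λ ∈ [0, 1] for the confident class;
only the first filter per lock type is used — deliberately not the common
first+last pair, since the logistic layer absorbs the orientation either
way. The neural feature is the natural log of the projected epoch variance
(floor 1e-12 before the log). One transformation is fitted per lock type
(stimulus, response), and CSP is refit inside every outer cross-validation
fold from that fold's training trials only.

Feature vectors: (rt) for RT-only, (nf_stim, nf_resp) for neural-only,
(nf_stim, nf_resp, rt) for the hybrid system.

## Confidence model

An L2-penalised logistic regression is trained on correctness labels. The
regularisation strength C is selected from {1e-4, …, 1e4} by stratified
3-fold inner cross-validation minimising held-out logistic loss: 288
training trials split 192 fit / 96 validate per inner fold. Ties in mean
validation loss resolve to the smallest C (strongest regularisation),
making selection deterministic. Features are z-scored on training
statistics; inside the inner CV the standardisation is recomputed from each
fold's fitting trials so selection never sees validation statistics.
Whether the original analysis standardised features is not documented; we
standardise so the shared C grid is meaningful across features with very
different scales (log-variances vs seconds). The confidence weight is
w = P(correct class) = logistic(−score), the linear score being oriented
toward the non-confident (+1) class.

Degenerate cases: single-class training labels raise an error and the
evaluation harness falls back to constant weight 1 for that fold (logged);
a minority class of two reduces the inner CV to leave-one-minority-out; a
minority of one skips selection and fixes C = 1.

## Group evaluation

Groups are formed off-line, never pooling data across participants: all
C(n, m) subsets of the n participants, or — for communicating cohorts —
all C(#pairs, k) unions of whole pairs (sizes 2k only; odd sizes are not
formed, and no group ever splits a communicating pair). Tie-breaks draw
from one seeded generator per evaluation run in (group, trial) order, so
runs are bit-reproducible; the tie test uses a scale-relative tolerance
(|Σ w·d| ≤ 1e-9·max w) so equal weights cancel to a tie despite
floating-point summation. A reported confidence of 0 makes that member
abstain; an all-zero group falls to the coin flip.

The outer evaluation is 10-fold cross-validation over the 320 trials
(288 train / 32 test per fold), with folds shared across participants so
groups are always scored on common test trials, and stratified by stimulus
class so each test fold keeps ≈25% targets (stratification is our choice;
sharing folds is forced by the group evaluation itself). Test predictions
concatenated over folds cover every trial exactly once.

Statistics: method comparisons use the one-sided Wilcoxon signed-rank test
over paired per-group error rates (exact null for ≤25 nonzero differences,
normal approximation above); correct/incorrect contrasts of RT, reported
confidence, estimated w and per-sample ERP voltages use the Kruskal–Wallis
test with tie correction (retained for two groups, where it is equivalent
to a rank-sum test). ERP contrasts report grand averages and per-channel,
per-sample p-values on the 48-sample grid, with helpers mapping named
latencies (e.g. 600/900 ms post-stimulus, ±200 ms around the response) to
sample indices; no multiple-testing correction is applied — consumers flag
the 5% line. Temporal dynamics use a simple moving average over 40
consecutive trials advancing one trial at a time, with an OLS trend line,
correlation coefficient and two-sided p-value fitted to the smoothed
series.

## Synthetic cohorts

The simulator generates the statistical structure the pipeline assumes,
not realistic EEG:

* **Design** — 8 blocks × 40 trials, exactly 25% targets per block, one
  seeded stimulus sequence shared by all participants; 4 s of recording
  per trial with stimulus onset 1.3 s into the slot, so response-locked
  epochs never cross trial slots.
* **Behaviour** — per-participant error rates default to 0.2 with an 0.08
  between-participant spread (clipped to [0, 0.95]), matching the ≈20%
  error and ≈9-point spread typical of isolated observers in this
  paradigm. RTs are log-normal (positive support, right skew): median
  0.6 s (σ_log 0.25) on correct trials, 1.0 s (σ_log 0.30) on incorrect
  ones; draws beyond the 2.0 s response window are resampled and counted.
* **EEG** — white Gaussian background noise (10 µV SD; optional 1/f) on
  all channels plus a biphasic ERP template (Gaussian lobes, peak 8 µV —
  a typical late-positivity amplitude) injected at stimulus onset and
  around the response on central-parietal midline channels. On incorrect
  trials the template amplitude is multiplied by 0.5.
* **Confidence reports** — quantised to {0, 10, …, 100}. Isolated:
  80 (correct) / 40 (incorrect) plus Gaussian noise (SD 15). With
  communication: 60 plus noise regardless of correctness, i.e. fully
  decoupled.
* **Communication** — participants are paired; the correct/incorrect ERP
  difference shrinks to 40% of its isolated size and overall amplitude
  scales by 0.7 (communication attenuates the neural correlates); on
  disagreement the less confident member (ties: slower RT) conforms to
  the partner with probability 0.5, producing the second responses.
  Individual error rates are not coupled to the communication flag — the
  elevated error rates communication produces in practice are expressed by
  setting `error_rate` explicitly.

Not emulated: volume conduction and realistic spatial covariance, alpha
rhythms and other oscillatory structure, blinks/saccades beyond what the
regression stage is tested with directly, electrode drift, inter-trial ERP
latency jitter, and learning effects. Passing tests therefore demonstrate
that the pipeline recovers injected structure under its own assumptions,
not that it would perform identically on human recordings — the original
recordings are not publicly deposited, so their exact error rates and
p-values are out of reach by construction.

## Problem sizes for routine runs

The simulator defaults to the full montage (64 channels, 2048 Hz). Routine
study-scale computations — the test suite's parameter-recovery checks and
`scripts/acceptance.py` — use 16 scalp channels at 128 Hz: 128 Hz is the
smallest power-of-two rate that both exceeds twice the 40 Hz band edge and
is an integer multiple of the 32 Hz epoch rate, and 16 channels retain the
four ocular-proxy electrodes plus a representative midline/parasagittal
spread including all ERP injection sites. Design-contract quantities
(epoch sample counts, fold sizes, enumeration counts) are always computed
at the full-scale values.

## Known limitations

* The ocular "standard subtraction algorithm" is implemented as
  least-squares regression on the Fp1−F1 / Fp2−F2 proxy; other
  implementations of that family differ in detail.
* CSP uses a single component per lock type by design; no frequency-band
  or Riemannian variants.
* Confidence weights are raw logistic probabilities; no post-hoc
  recalibration is applied.
* The Kruskal–Wallis p-values are asymptotic (chi-square); only the
  statistic is exact under ties.
* Reported-confidence weighting uses the raw 0–100 scale; normalisation
  variants are out of scope.
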