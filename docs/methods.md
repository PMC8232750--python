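# Methods

## Problem and scope

`teflow` implements a directed functional-connectivity analysis for
multichannel EEG: pairwise transfer entropy (TE) between channels,
lag-optimized to estimate the information-transfer delay, contrasted against
neutral control conditions, thresholded by bootstrap confidence bounds,
reduced to high-out-degree "channels of interest", compared across
experimental settings with rank-based statistics, and probed for
setting-specificity with a resampled multinomial logistic-regression
protocol.  The experimental context is a six-condition design — neutral,
androstadienol-odour and estratetraenol-odour settings crossed with female
and male storyteller voice ({NF, NM, AF, AM, EF, EM}) — recorded from a
64-electrode 10-10 cap and analysed on 62 scalp channels.  Since no public
recordings exist for this paradigm, a synthetic generator with a known
ground-truth coupling graph drives all validation.

## Transfer entropy and its estimator

For a source X and target Y, TE quantifies the deviation of Y from its
generalized Markov property:

    TE(X->Y) = I( Y_t ; X_{t-mu} | Y_{t-1}, ..., Y_{t-l} )   [nats]

a conditional mutual information between the target's next value and the
lagged source, given the target's own past.  It is zero for independent
processes and — because a perfectly synchronized source adds nothing beyond
the target's own past — zero again under complete synchronization, which is
why it is a measure of information transfer rather than of coupling
strength.

Estimation uses the Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbour
construction in its conditional-MI form (Frenzel–Pompe counting): with
max-norm balls of the k-th-neighbour radius in the joint space, the
estimate is

    psi(k) + < psi(n_z + 1) - psi(n_uz + 1) - psi(n_sz + 1) >

with neighbour counts strictly inside the radius.  The kernel width adapts
to the local density, so apart from k the estimator is effectively
parameter-free; embedding lengths are **not** estimated adaptively here and
default to history 1/1 with k = 4 — explicit, reproducible defaults that
can be overridden in `TEConfig`.

Numerical choices:

- **Lag convention.** `delay=mu` pairs `y[t]` with `x[t-mu]`, so the lag
  that maximizes TE estimates the true coupling delay directly (a coupling
  `y[t] <- x[t-5]` peaks at mu = 5).  `mu = 0` uses the simultaneous source
  sample ("no time lag"); for an exactly synchronized pair this degenerates
  to self-information, so zero-law checks of synchronized pairs use
  mu >= 1.
- **Tie-breaking jitter** (`noise_jitter_sd`, default 1e-8 of the series
  SD) is seeded from each series' own content.  Per-series (rather than
  per-pair) seeding keeps exactly synchronized inputs exactly tied after
  jittering; the strict-inequality counting rule then handles the
  degenerate geometry without bias.  Jittering the two copies independently
  instead produces a systematic negative bias (~-0.06 nats at n = 4096).
- **Dual implementation.** Below 2500 usable vectors the neighbour counts
  come from dense max-norm distance matrices (fast at analysis scale and
  reused across a lag scan); above, from k-d trees.  Both apply the same
  strict counting rule.
- **Lag scans** evaluate all delays on the common sample range implied by
  the largest lag, so the scanned values are comparable; ties break toward
  the smaller delay.

A closed-form linear-Gaussian oracle (`gaussian_te_oracle`) computes TE
exactly for stationary VAR processes from the Lyapunov-equation stationary
covariance: TE = 0.5 ln(Var(y|y-past)/Var(y|y-past, x-past)).  For the
reference process x_t = 0.5x_{t-1}+e, y_t = 0.5y_{t-1}+0.5x_{t-1}+n the
symbolic value is ln(sqrt(2310)/42) = 0.134832, reproduced independently by
a long-simulation regression plug-in.  At the weakest tested coupling
(0.1, true TE 0.0066 nats) a single KSG realization has sampling SD ~0.003
nats, so oracle agreement within +-15% is asserted on the mean over ten
seeded realizations; single realizations carry the correlation and
monotonicity checks.

## Preprocessing

Fixed order: band-pass, artifact rejection, decimation, detrending.

- Band-pass 0.5–50 Hz, Butterworth order 4 (24 dB/octave equivalent),
  applied forward-backward (`sosfiltfilt`).  Zero-phase filtering is a
  deliberate choice: causal filtering would shift channels in time and bias
  the estimated transfer delays.
- Artifact rejection: contiguous 1-s segments containing any sample with
  |amplitude| > 125 uV are excised from all channels jointly (time-locking
  preserved).  The segment length is a package choice; only the amplitude
  rule is prescribed by the protocol.  Flagging more than half the data
  logs a warning but still returns.
- Decimation to a tenth of the length (120000 samples at 1000 Hz -> 12000
  points at 100 Hz) with an anti-alias FIR low-pass before sample picking;
  naive subsampling is available behind a flag for sensitivity checks.
- Per-channel linear detrending (least-squares line removed).

## Channel-of-interest pipeline

Per subject and condition, every ordered channel pair gets a lag-optimized
TE (delays 0–50 at the downsampled rate, i.e. up to 500 ms).  Each odour
setting's matrix is contrasted against the same subject's voice-matched
neutral matrix (AM and EM against NM; AF and EF against NF) — negative
residuals are retained, since only the later threshold removes them — and
contrasts are grand-averaged over subjects into one matrix per setting.

Thresholding pools the off-diagonal entries and bootstraps their mean
(default B = 10000); the 97.5th percentile of the bootstrap mean
distribution is the setting's threshold, and entries below it are zeroed —
a one-tailed "greater than the average" test at p < 0.025.  Entries equal
to the threshold survive ("discard strictly below"), which makes the
degenerate all-equal matrix keep all entries and, degrees then being
balanced, select no channel.  Channel selection bootstraps the mean of the
out-degree vector (count of surviving outgoing entries per channel) and
keeps channels whose degree strictly exceeds the upper 95% bound.  The
per-setting selections are intersected; settings with empty selections are
dropped from the intersection and reported.

**Calibration caveat (measured, documented, not hidden).**  Both bootstrap
stages test against confidence bounds of a *mean*, which individual entries
and degrees exceed easily: under a coupling-free null roughly 40% of
contrast entries survive the pooled threshold and the top-degree channels
exceed the degree bound, so the procedure selects ~2 of 8 channels on pure
noise and an empty selection is rare.  An empty selection can only arise
from balanced degrees, not from "nothing survives" (the threshold can never
exceed the largest entry).  Consequently the pipeline's specificity comes
from the neutral contrast and the relative magnitude of real couplings —
which pull the threshold far above the noise quantiles — not from the null
behaviour of the selection stages.  Two acceptance tests assert the
idealized null behaviour (empty selection on coupling-free data; automatic
dropping of a coupling-free setting) and are expected to fail; they are
retained deliberately as an honest record of this property.

## Group statistics

TE distributions are heavily skewed, so comparisons are rank-based, with
normality screened by a Monte-Carlo Lilliefors test (KS distance against a
normal with estimated moments; null distribution from seeded standard-
normal simulations).  Effect sizes follow Rosenthal: r = sqrt(H/N) for
Kruskal–Wallis and r = W/sqrt(N) for Wilcoxon tests, where W is the
*standardized* (z-like) statistic — computed with tie and continuity
corrections — since raw rank sums would not be dimensionally consistent
with published values such as W = -7.99 at N = 720.  Magnitudes: small
|r| <= 0.3, medium 0.3 < |r| < 0.5, large |r| >= 0.5.  Reported p-values
below 0.001 render as "p < 0.001".

## Specificity protocol

Each retained setting contributes one row per common channel: the channel's
thresholded outgoing-TE vector over all montage channels (3 settings x 6
channels x 62 targets = an 18 x 62 design, labels 1/2/3 for AF/AM/EM).
Per run, one random channel per setting is held out (15 x 62 train,
3 x 62 test), a multinomial logistic regression (L2, C = 1.0, features
standardized on the training fold only) is fit, and the 3-row test set is
scored; 1000 runs are aggregated.  With three balanced classes chance is
33.33%; per-run test accuracy is necessarily coarse (0/33/67/100%), so the
run-level mean and SD are the meaningful surface.  Precision/recall/F1 are
macro-averaged per run before averaging over runs.  Above-chance evidence
uses the signed-rank test of per-run accuracies against 33.33 with
N = number of runs; label-shuffled runs (labels permuted afresh each run)
calibrate the chance level.  Per-setting weight maps are the mean
coefficient vectors over runs — an explicit choice, since a single final
fit would be equally defensible — and are compared by Kruskal–Wallis plus
pairwise rank-sum tests.  The regularization strength and standardization
are package choices recorded in the report metadata.

## Sensitivity analysis

The repeated-measures sensitivity analysis follows the G*Power "within
factors" noncentrality convention: lambda = f^2 * n * m / (1 - rho), with
numerator df (m-1) and error df (n-g)(m-1), nonsphericity fixed at 1.  For
alpha = 0.05, power = 0.8, n = 20, g = 2, m = 6, rho = 0.4 the smallest
detectable effect root-finds to f = 0.261 — bracketing the published
f = 0.258, whose exact dialog settings are not recoverable.  The conversion
chain is closed-form: eta^2 = f^2/(1+f^2), d = 2f, r = d/sqrt(d^2+4);
full precision is carried (0.258 -> r = 0.2498, commonly printed truncated
as 0.249).

## Synthetic data: what it does and does not emulate

Each channel is an order-1 autoregression (default coefficient 0.5,
innovation SD 10 uV nominal) plus condition-gated lagged linear couplings
and Gaussian innovations; an optional tanh saturation makes the process
non-Gaussian to exercise the estimator's model-free claim, and an
artifact-injection flag adds >125 uV transients for the rejection rule.
Defaults mirror the acquisition geometry: 62-channel 10-10 roster (the
64-cap minus the two mastoid-adjacent reference electrodes — the exact
excluded pair in the original montage is not documented, so the roster is
configuration-driven), 1000 Hz, 120000 samples (the pre-decimation length
that yields 12000 analysis points; the narration length is not exactly
recoverable, so the duration is configurable).  Seeding is counter-based
per (design seed, subject, condition), so subjects are exchangeable and
every recording is bit-reproducible; a burn-in of at least 10x the maximum
coupling delay (>= 200 samples) is discarded.

The generator does not model volume conduction, biophysical sources,
oscillatory spectra, or stimulus-locked dynamics.  A green recovery test
therefore establishes that the pipeline recovers planted directed lagged
couplings against autoregressive background noise — not that it would
isolate physiological effects in real EEG.

Scaled-down stated worlds used by the recovery tests (chosen by power
considerations before the tests were first run, then frozen): the delay-
recovery suite uses 2000-sample series with a delay-5, strength-0.5
coupling; the end-to-end suite uses 8 channels, 6 subjects, 640 samples at
the analysis rate, two source channels with three strength-0.6, delay-5
couplings each, active only in EM, and B = 1000 bootstrap draws, with lag
scans over 0–6.

## Known limitations

- Single-source, single-target TE with short histories; no conditional or
  multivariate TE, so indirect paths can masquerade as direct edges.
- The bootstrap selection stages are liberal under the null (see above).
- The Gaussian oracle covers linear dynamics only; nonlinear-coupling
  accuracy is validated only qualitatively (asymmetry, monotonicity).
- BrainVision support covers the BINARY/MULTIPLEXED IEEE-float32 (and
  INT16) core layout this package writes, not the full format family.
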