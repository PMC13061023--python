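# Methods

This note documents the models and procedures implemented in `gapcross`,
the assumptions behind them, the defaults that matter, and what the
synthetic validation does and does not establish.

## The synthetic jump generator

The generator is the package's ground-truth instrument: every analysis is
validated by recovering quantities the generator planted. It emulates the
structure of mouse gap-crossing jumps without claiming to reproduce any
particular animal's data.

**Kinematic chain.** Ten canonical landmarks (nose, ear, shoulder, elbow,
forepaw, hip, knee, ankle, hindpaw, tail-base) are generated from a 2-D
chain rooted at the **hindpaw** — the stance contact point. Chain
parameters are the hip/knee/ankle interior angles, the absolute foot
orientation, the trunk length, and two forelimb segment orientations,
each following per-phase templates connected by half-cosine ramps that
start at phase boundaries. The rooted-at-the-paw construction has two
consequences that the tests exploit:

* body-posture changes (including the counter-movement dip, the
  peri-takeoff extension peak and the in-flight flexion) move the body
  *relative to* the paw and therefore never contaminate the hindpaw
  acceleration trace used for segmentation;
* the paw's flight trajectory is exactly ballistic, so its vertical
  position is an exact parabola over every flight frame.

The paw trajectory itself is: planted through preparation; a ramp-and-hold
push through propulsion whose amplitude is solved so that the takeoff
velocity carries the paw across the configured gap in the configured
flight time; ballistic flight under gravity (9810 mm/s²); and a constant
deceleration to rest over 30 ms after touch-down. Flight duration
lengthens with gap distance (2.5 ms/cm around 15 cm), which drives the
flight-duration ANOVA; propulsion duration does not change with distance.

**Posture variability** has three planted components, all scaled by a
per-phase schedule (preparation 1.0, propulsion 0.5, flight 0.8, landing
1.1 — propulsion is the most stereotyped phase, landing the most
variable, matching the dispersion ordering the analysis must recover):

* per-trial template jitter (1° SD on angles) — trial identity;
* within-trial postural wander, an Ornstein–Uhlenbeck process on each
  chain parameter (3° stationary SD, 12 ms correlation time) — continuous
  sway that makes frames from different trials interleave in posture
  space rather than forming per-trial islands;
* additive landmark noise (0.15 mm per coordinate), the scale of
  sub-pixel tracking error. This value matters: double differentiation
  at 500 fps amplifies tracking noise by the frame rate squared, and a
  generator with several-fold larger noise would produce an acceleration
  trace whose noise floor buries the propulsive push — unlike the clean
  phase-structured traces the segmentation method presumes.

**EMG model.** Each muscle signal is `s(t) = env(t) · n(t)` with
`n ~ N(0,1)` i.i.d. at 2 kHz, so the windowed RMS is an asymptotically
unbiased envelope estimator with relative error `≈ (2W)^{-1/2}` for a
W-sample window — an analytic test surface. Envelopes are sums of
Gaussian bursts over a small floor: low tonic extensor activity through
preparation (the eccentric crouch), a pre-takeoff extensor burst (center
−25 ms, σ 18 ms) whose amplitude is `1 + β(d − 10 cm) + u_i` with planted
β = 0.269 per cm and animal intercepts `u_i ~ N(0, 0.3²)`, a flexor
(IP/TA) co-activation burst preceding flight (center −8 ms), and an
extensor landing burst. Bi-articular muscles (BF, RF, GS) activate with
the extensor burst. The additive-in-distance peak keeps envelopes
positive at every configured distance and makes the planted slope the
exact estimand of the mixed-model analysis in raw envelope units.

**Stimulation effects.** `suppress` multiplies the signal by a factor
(default 0) inside the epoch. `flex_drive` blends the hindlimb angle
series toward flexion targets with a configurable latency, cosine rise,
hold, and decay, then rebuilds the landmarks with the trial's original
noise realization — so a zero-blend drive is bit-identical to the input
and the injected latency is recoverable to within a frame.

## Phase segmentation

Acceleration is the Savitzky–Golay second derivative (window 11, order 3,
edges by polynomial fit on truncated windows) of the landmark trajectory,
by default the magnitude over x/y. Boundary detection is anchored to the
canonical trace shape and is scale-free (all thresholds are multiples of
a robust baseline spread, so positive rescaling changes nothing):

1. baseline level and spread: median and MAD of a 5-frame moving average
   of the initial 100 ms, the spread floored at 2% of the dynamic range
   so noiseless traces are well-posed;
2. propulsion onset: first sustained run (half the minimum phase length)
   above `μ + 3σ`;
3. takeoff: the steepest sustained drop within 100 ms of onset, scored as
   the difference of 4-frame means before/after each candidate frame —
   robust to frame-to-frame noise where a single-frame difference is not;
4. landing onset: first sustained run above the flight plateau level
   plus `3σ`. The flight level is the median over a short window placed
   past the takeoff transient (the smoother smears the takeoff drop over
   half a window), and the search likewise starts beyond that transient.
   The landing threshold is referenced to the flight level rather than
   the baseline because ballistic flight has acceleration magnitude g,
   which a quiet-baseline threshold can sit below.

Phases shorter than 20 ms trigger one retry with a halved rise threshold,
then failure with a diagnostic. On noiseless synthetic trials all three
boundaries are recovered within ±2 frames; at default noise the landing
boundary has a few-frame early bias (the smoother sees the touch-down
spike slightly before it happens).

## Postural state space

Frames are centered on their landmark centroid (optional rotation
normalization aligns the hip→shoulder axis), flattened to 2L-vectors, and
embedded by PCA (SVD of the column-centered pool; dimension chosen by a
90% explained-variance target capped at 5). Dispersion is the per-bin
Euclidean distance of each trial's bin-averaged score to the across-trial
centroid, summarized by median and IQR; the similarity matrix is the
all-pairs distance matrix of the trial-averaged embedding (a per-trial
variant averages per-trial matrices). Changepoints of the similarity
matrix minimize the total within-segment sum of pairwise distances by
exact dynamic programming over contiguous segmentations, either at a
fixed segment count (default 4) or with a linear per-segment penalty;
tests verify the DP against exhaustive enumeration.

## Configuration modes (clustering)

Pooled frames are clustered on a symmetric unit-weight kNN graph (k = 15)
by Leiden community detection with the RB-configuration quality at
resolution 0.1, followed by merging of clusters holding under 2% of
frames into the nearest retained centroid. Two practical choices matter
and are deliberate:

* **Bounded fit sample.** The RB quality's merge penalty grows with
  graph size while the edge count across a blob's internal interfaces
  grows only like √n, so the resolution at which a fixed geometric
  structure fragments depends on how many frames are pooled. The
  partition is therefore fitted on a bounded random subsample (1000
  frames; adjacent frames are strongly correlated, so the subsample
  carries the full structure) and remaining frames are assigned to the
  nearest cluster centroid.
* **Consensus over subsamples.** Community detection near a quality
  plateau is draw-sensitive, so the fit is repeated over 7 seeded
  subsamples; the modal cluster count wins and the best-quality modal
  partition is kept. Everything is deterministic given the seed.

On default synthetic cohorts this recovers exactly four configuration
modes — crouched preparation, extended propulsion (absorbing the brief
extension peak), flexed flight, and re-extended landing — with the
residual draw-to-draw variability of the statistic itself (a fifth
cluster appears in roughly 1% of cohort/seed combinations, always a
split of one posture mode).

## AR-HMM

Emissions are Gaussian autoregressions `x_t | z_t=k ~ N(A_k φ_t + b_k,
Σ_k)` with `φ_t` the stacked p previous frames; the first p frames are
conditioned on, not modeled. Inference is EM: scaled forward–backward
for posteriors and expected transitions; per-state weighted least squares
for `(A_k, b_k)` with a small ridge on the normal equations; weighted
residual covariance plus `1e-6·I`; transition rows from expected counts
plus a sticky pseudo-count κ = 10 on the diagonal (encouraging the
dwell-and-switch structure of phase-locked behavior); best of 5 random
restarts by final log-likelihood. Viterbi decoding runs in log space.
Defaults K = 6, p = 1, tolerance 1e-6.

With κ = 0 the EM is exact maximum likelihood and the data log-likelihood
is non-decreasing every iteration (asserted in tests); with κ > 0 the
M-step maximizes a penalized objective, so the tracked data likelihood
may dip by a vanishing amount near convergence. Forward–backward and
Viterbi are verified against exhaustive enumeration over all K^T state
sequences on small instances to 1e-10, and a planted well-separated
3-state model at T = 3000 is recovered with >90% frame-wise Viterbi
accuracy and transition rows within 0.1 total variation.

## EMG quantification

Envelopes are centered sliding RMS (default 20 ms) with truncated
windows at the edges. Burst peaks are window maxima with half-peak
onset/offset crossings; the extensor window is the propulsion phase
(ending at takeoff), while the flexor flight window is extended 30 ms
before flight onset to capture the pre-flight co-activation burst.

Distance tuning is fitted as a random-intercept model by REML,
profiling the single variance ratio λ = σ_u²/σ_e²: for fixed λ each
animal's covariance `I + λ11'` inverts in closed form, so the GLS
estimate, profiled residual variance, and REML criterion are cheap and
the scalar profile is minimized over log λ (with an explicit λ = 0
boundary comparison). The Wald test on β1 uses the normal approximation
without a Satterthwaite degrees-of-freedom correction; with ~10 animals
its null rejection rate runs slightly above nominal (5–8% observed at
α = 0.05), which the calibration tests bound. The model is fitted on raw
envelope-peak units rather than z-scored peaks: under the
amplitude-modulated-noise model the baseline RMS standard deviation is
estimation noise, and dividing by it would destroy the planted slope's
units and make recovery of β ill-defined.

The suppression index is `SI = 1 − mean(RMS in epoch)/mean(RMS in
control window)`; the pipeline's control window is the same epoch of the
unstimulated recording, so complete envelope suppression gives SI near 1
(slightly below, because the centered RMS window bleeds across the epoch
edges).

## Perturbation statistics

Welch and paired t tests, one-way ANOVA and Tukey HSD go through
scipy.stats; Benjamini–Hochberg through statsmodels. Hedges' g uses the
pooled-SD standardized mean difference with `J = 1 − 3/(4·df − 1)`
(df = n1+n2−2; at 6 vs 6 animals, J = 1 − 3/39 ≈ 0.923). Movement onset
latency is the first sustained excursion (3 frames) beyond 3 baseline
SDs after stimulation onset, with the baseline SD floored at a tiny
relative value so noiseless traces are handled; because detection waits
for the threshold crossing, measured latencies exceed the injected
latency by a frame or two in the noiseless case and by a few more under
noise. Animal-level means, not trials, are the statistical unit for
cross-condition tests.

## What the synthetic validation shows — and does not

Passing tests establish that the implementations are correct (oracle
equivalences), that the analysis pipeline recovers planted structure
under the stated noise model, and that the statistical tests are
calibrated. They do not establish that real gap-crossing data satisfies
the generator's assumptions: real tracking noise is heteroscedastic and
occlusion-prone, real posture variability is not Gaussian or
phase-stationary, real EMG has colored noise, motion artifacts and
crosstalk, and real phase boundaries have no ground truth. Quantities
tied to the real data of the original experiments (specific regression
coefficients, F and t statistics) depend on unreleased recordings and
are represented here only by their synthetic analogues.

## Problem sizes

Default validation sizes were chosen to make the statistics stable while
keeping the full suite fast: cohorts of 6 animals × 2 trials × 3
distances for the posture analyses, 10 × 10 × 3 replicate cohorts for
slope recovery (50–100 replicates), T = 3000 frames for AR-HMM state
recovery, 2000 replicates for Welch calibration and 200 for the
mixed-model null.
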