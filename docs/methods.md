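# Methods

## The task model

A trial presents a checkerboard whose contrast sweeps linearly between 10%
and 100% with constant absolute slope `(upper − lower) / half_cycle`,
reflecting at the bounds; the half-cycle period is drawn from {6, 7, 8, 9} s
per trial so elapsed time carries no information about contrast. The
participant stops the sweep to choose the on-screen contrast `x_t`. A hidden
target `r_t` (constant within a block, drawn uniformly on [25, 85]% so that
the full triangle always fits inside the contrast range) determines the
whole-cent reward through the symmetric triangular mapping

    R(r, x) = round(25 − (5/3)·|r − x|)   if |r − x| < 15,   else 0.

Rounding is *half-up* and isolated in a single helper; the tie rule is not
observable in ordinary use because bin-center distances never land exactly
on a half-cent, but it fixes the edges of the feedback-consistency windows
(e.g. full reward extends to |r − x| ≤ 0.3).

Blocks end after 25 trials or once cumulative stimulus presentation
exceeds 180 s, whichever comes first.

### Contrast grid

Beliefs live on a grid of J = ceil((upper − lower)/width) equal bins. With
the canonical (10, 100, 0.61) this gives J = 148. We tile the interval with
the *effective* width (upper − lower)/J ≈ 0.6081 rather than the nominal
0.61 so the bins partition [10, 100] exactly; bin 83 (1-based) is then
centered at 60.17 ≈ 60.2% contrast. The nominal 0.61% is kept as the
constructor argument because it is the conventional "largest width that
resolves adjacent cent values" (the analytic resolution limit at slope 5/3
is 0.6; the extra 0.01 is historical and we keep it as given).

## Belief updating under response uncertainty

Prior beliefs θ_t are a PMF over the grid, initialized uniform at each
block start (posterior of trial t is prior of trial t+1 otherwise). The
update for feedback f_t after true choice x_t marginalizes over which
contrast the participant *believed* they chose:

    θ_{t+1}(j) ∝ θ_t(j) · Σ_{j*} 1[R(c_j, c_{j*}) = f_t] · w_{j*}(x_t, σ)

**Discretization convention.** The candidate weights w_{j*} are Gaussian
*bin masses* — density at the bin center times the effective bin width —
renormalized over the grid so that they form a proper PMF over candidate
bins despite truncation at the grid bounds, and the true chosen contrast
enters as its continuous value, not its bin center. This combination is a
deliberate design choice with three consequences: (i) the weights are a
legitimate subjective probability distribution over candidates; (ii) the
prior predictive over the 26 feedback values sums to one identically
(every candidate bin maps to exactly one feedback value), making feedback
surprise a proper self-information without any ad-hoc normalization; and
(iii) the single-update worked example on the 148-bin grid reproduces the
reference values 0.007 / 0.026 / 0.013 at printed precision, which the
unnormalized or bin-center variants do not (they give 0.025).

At σ = 0 the weights collapse to a one-hot indicator and some feedback
values become logically impossible; an impossible update raises a typed
`DegenerateUpdateError`. During model fitting a likelihood floor of 1e−12
per bin keeps the sequential updates and choice probabilities finite at
extreme parameter values.

**Choice rule.** Choice probabilities are the prior blurred by the same
σ-Gaussian: a discrete convolution over bins, truncated at the bounds and
renormalized (the normalization constant absorbs the truncated tails; no
wraparound). One σ per participant is shared between updating and choice.

**WSLS heuristic.** The comparison model keeps no belief distribution:
after any rewarded trial the choice PMF is the σ-Gaussian centered on the
previous chosen bin; after a loss or at a block start it is uniform. This
keeps the two models' choice probabilities on the same footing with the
same single parameter.

## Model fitting and comparison

σ is estimated per participant by maximizing the summed log choice
probability of the observed chosen bins (blocks re-initialized to uniform,
beliefs updated with the observed feedback after each trial). The search
is bounded on [0.1, 50]% contrast and uses derivative-free bounded Brent
minimization on seeded random subintervals (`n_starts`), deterministic
given the seed and converged to xatol = 1e−6 on σ; the contract is
reproducibility and tolerance, not a specific optimizer. Estimates pinned
at a bound are flagged.

Models are compared by BIC = k·ln(n) − 2·lnL with k = 1 and n = the
participant's trial count (per-participant BIC implies per-participant n).
Cohort summaries report total log-likelihood, total BIC, and the count of
participants each model fits best; |ΔBIC| < 0.01 counts as a tie and is
reported separately.

## Belief variables

Per trial: uncertainty `H` = Shannon entropy of the prior (bits, log2 as
defined); update size `I` = H(prior) − H(posterior) (bits; can be negative
if feedback broadens belief); Bayesian surprise `I_KL` = KL(prior ‖
posterior) in nats (natural log, and note the argument order — this
follows the source definition, which is the reverse of some "Bayesian
surprise" conventions); feedback surprise `S` = −log2 of the prior
predictive probability of the observed cent value, with the predictive
normalized over the 26 possible feedback values (a no-op under the weight
convention above, kept as a guard). Zero-probability events report `inf`
rather than raising; 0·log 0 ≡ 0 throughout.

## Synthetic data

**Agents.** Simulated participants choose by sampling the model's choice
PMF in contrast space (Bayesian with σ, WSLS with σ, or uniform-random).
Defaults are 16 participants × 15 blocks and σ = 13% contrast — the design
scale and a cohort-typical response-uncertainty level. Response time is
back-computed as the first moment the sweep reaches the chosen contrast
(solved exactly on the unfolded trajectory); it exists for every in-grid
choice within 18 s and only feeds the block-duration rule. Simulated
agents respond faster than humans deliberate, so blocks typically reach
the 25-trial cap (~375 trials/participant) rather than the 180 s cap
(humans averaged ~18 trials/block); fitting and recovery behavior is
insensitive to this difference.

**Epochs.** Synthetic feedback-locked epochs span −1500 to +1500 ms
(default 128 Hz). Planted signals: at designated fronto-central sites a
Gaussian bump (latency 350 ms, SD 45 ms — inside the 300–450 ms analysis
window) whose peak is `α_P3 + β_P3·z(I) + √(1−β_P3²)·η`; at designated
central/parietal sites a linear ramp over [−500, 0] ms whose window mean
is `α_SPN + β_SPN·z(H) + √(1−β_SPN²)·η` (β_SPN < 0 for the empirical
direction), returning to baseline within 200 ms after feedback. η is unit
trial-level noise, z(·) is the within-participant z-score, so the planted
betas are in the standardized units the regression pipeline reports and
the single-trial amplitude SD is 1 by construction. White sensor noise
(default SD 0.2, optional AR(1)) is added everywhere; all other
electrodes carry sensor noise only. The generator emulates the
amplitude–predictor dependence and nothing else: no volume conduction, no
correlated electrodes, no artifacts, no 1/f spectrum, no CSD transform —
so passing recovery tests validate the statistical pipeline, not claims
about real EEG.

The default planted effect sizes (+0.27 for P3 at FCz, −0.06 for SPN at
C3/P4) are the reported empirical magnitudes for these components and make
the default cohort a realistic difficulty: the SPN effect sits near the
detection margin of a single 16-participant cohort.

## ERP statistics

P3 = max over 300–450 ms minus the mean of [−200, 0] ms; SPN = mean over
[−500, 0] ms minus the mean of [−1500, −1300] ms ("0–200 ms prefeedback"
and "1300–1500 ms prefeedback" read as those windows). Amplitudes are
z-normalized within participant; predictors are standardized within
participant; each participant × electrode regression uses iteratively
reweighted least squares with the bisquare (Tukey biweight) influence
function, c = 4.685, scale re-estimated each iteration as MAD/0.6745
about zero, intercept included, convergence at Δβ < 1e−8. The update-size
measures I and I_KL are never co-included as predictors. Group inference:
one-sample t tests of participant betas against zero, Bonferroni-corrected
within each component's electrode family (4 for P3: FCz, Cz, CPz, Pz; 10
for SPN: F3…O2 — electrodes only, not predictors), α = 0.05. The
trial-number control designates trials 1–5/6–10/11–15 as early/middle/late,
median-splits I within participant, computes per-participant cell means
first, and runs a 3 × 2 repeated-measures ANOVA on them.

## Numerical and design notes

* Likelihood tables (feedback-consistency indicators over all bin pairs)
  are cached per grid/mapping, so an update is one matrix–vector product.
* Belief PMFs are validated (non-negative, sum to 1 within 1e−10) and
  immutable; entropies are clamped only by arithmetic, never post-hoc.
* The SPN regression uses belief uncertainty as the sole predictor; the P3
  regression uses reward, I (or I_KL) and S.
* The sigma search interval [0.1, 50] comfortably brackets plausible
  response uncertainty; recovery simulations across σ ∈ [5, 20] show
  median absolute error well under 2% contrast at session-scale data.
* Simulation-based test sizes (20 recovery agents, 50 identifiability
  replicates, 3 pooled planted cohorts, 1000 null replicates for the
  family-wise-error check) were chosen as the smallest sizes at which each
  property is statistically decidable; the family-wise-error bound is
  judged by a one-sided binomial consistency test at α = 0.01 because a
  rate estimated from 1000 draws fluctuates around its true value.

## Known limitations

* No deposited behavioral or EEG data exist for this task; all empirical
  statistics from the original study (fitted σ per participant, table
  likelihoods, regression t values) are out of scope and are used only as
  plausibility scales for simulations.
* The grid estimator assumes the response-uncertainty Gaussian is shared
  between updating and choice and constant across the session.
* Direction-biased updating variants (beliefs biased by the direction of
  contrast movement at choice time) are not implemented.
* The epoch generator's planted linearity makes recovered betas directly
  comparable to planted ones; real CSD-ERP amplitudes need not be linear
  in model variables.
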