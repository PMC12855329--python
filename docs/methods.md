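# Methods

This note records the modelling choices behind `pbac`: what is simulated,
how the signal pipelines and learning models are specified, which knobs
matter, and what the validation suite does and does not establish.

## Task and coordinate frame

The simulated court uses a right-handed frame with the origin on the court
midline at floor level: x lateral (positive right), y up, z toward the front
wall.  The viewer stands at z = 0.  Two release holes sit ±3.67 m from the
midline on the front wall; their angular separation is ~85° of visual angle.
The wall distance is not an independent datum — it is forced by those two
numbers, d = 3.67 / tan(85°/2) ≈ 4.005 m, and the geometry module derives it
that way (an explicitly configured distance must agree within 0.01 m).  The
hole height is likewise unconstrained by the printed design; it defaults to
the interception height (1.5 m, chest height) and is configurable.

Each ball flies from its hole to a point 0.75 m lateral (release side) and
1.5 m high at the viewer plane.  Lateral and depth velocity components are
constant; height follows gravity with the initial vertical velocity chosen
to hit the end point, and the flight time T solves arc-length/T = 10 m/s to
1e-6 (Brent's method on a bracketing interval below the sag-dominated
branch; with gravity off, T reduces exactly to chord/speed, which the tests
use as the solver oracle).  Two average-speed roots exist in principle — a
flat, fast trajectory and a high lob; the solver takes the flat branch,
which is the one a ball machine would produce.

Blocks follow the fixed protocol: 10 practice trials (8/2 side split), then
three 50-trial blocks of 40 expected / 10 unexpected trials in a
pseudo-random permutation (fixed counts, not iid draws, because the design
prescribes exact per-block counts and prespecified orders; no max-run
constraint is imposed).  Onset delays are drawn uniformly on [0, 5] s,
continuous.  Allocation:

* probability block — expected trials release from the counterbalanced
  likely side, unexpected from the other;
* gaze-contingent block — the gaze side is read from the raw (unfiltered)
  horizontal in-world gaze sample 50 ms before release; expected trials
  release from that side, unexpected from the opposite.  A sample exactly
  at the midline classifies left (the rule is stated only for strict
  inequalities) and is logged; a blink at the gate falls back to the last
  valid sample;
* matched block — replays the gaze-contingent block's release sides
  trial-by-trial and inherits its labels.

## Synthetic agents

Agents exist so the full stack can run closed-loop with known ground truth.
Each carries a generative learner over the binary ball side (3-level HGF by
default; 2-level and Rescorla–Wagner available), chooses a gaze side through
the unit-square sigmoid with decisiveness ζ, fixates the corresponding hole
with Gaussian lateral noise (default SD 0.15 m), and after release pursues
the ball: gaze holds the fixation until release + pursuit_lag (default
120 ms, a reaction-time-scale lag), then relaxes toward the current ball
position with the same time constant.  Incongruent trials therefore begin
with the full ~85° gaze–ball error and only partially recover within the
~0.5 s flight, reproducing the qualitative expected/unexpected tracking
asymmetry.  Interception is a Bernoulli outcome (default 0.8 congruent /
0.4 incongruent — chosen as a realistic large behavioural effect, since the
design's hypotheses concern hit proportions, not racquet physics).

Pupil traces are baseline (3.5 mm) + gain × surprisal × kernel + white
noise, where surprisal is the Shannon surprisal −log p of the observed side
under the agent's pre-trial prediction, and the kernel is a gamma-shaped
impulse with unit peak ~1 s after release (latency 1.0 s, width 0.5 s —
physiologically plausible for phasic, arousal-linked dilation; no
quantitative pupil model is prescribed by the design, so these are artifact
choices validated by recovery tests).  The default gain is 0.4 mm per nat.
Blinks are contiguous 100–300 ms missing runs at a default 10 events/min,
shared between gaze and pupil streams and across eyes.

What the generator does *not* emulate: saccade dynamics, tonic pupil drift,
luminance responses, asymmetric eye validity, tracker-specific noise
spectra, or any strategic (cost-sensitive) component of gaze choice.
Passing tests therefore demonstrate internal consistency of the pipeline
and estimators under a plausible generative model, not fidelity to any
particular human dataset.

## Signal pipelines

Gaze: three-frame moving median, then a second-order low-pass Butterworth
at 15 Hz.  Pupil: missing/blink runs padded by 150 ms on each side
(symmetric, the padding is stated without sides), each gap bridged by a
least-squares line over up to 100 ms of valid flanking samples, then a
second-order 10 Hz low-pass, then binocular averaging.  Both filters are
applied zero-phase (forward–backward) so that peak latencies are not
shifted; the pupil filter order is unstated by the design and set to 2.
Missing samples are bridged for filtering and restored as missing.  Data
are recorded at 90 Hz and never resampled.

Windows: predictive gaze is the mean filtered gaze x over the half-open
[release − 50 ms, release) window (4–5 samples at 90 Hz), classified right
if > 0, left if < 0 (exactly 0 → left, logged).  The pupil baseline is the
mean over [release − 200 ms, release); the surprisal peak is the maximum
over [release, arrival + 3 s] minus that baseline.  The gaze–ball error is
the per-frame angle between the two unit vectors, minimised over release →
contact (or until the ball passes the racquet plane on misses); invalid
frames are skipped.  The per-trial missing fraction used by QC is the
post-padding missing proportion averaged over eyes.

## Learning models and fitting

The binary HGF updates are the standard one-step variational scheme (see
README for the equations); the 4-level variant couples levels 3–4 with its
own fixed κ = 1 and offset ω₄.  Any non-positive predicted or posterior
precision marks the parameter point invalid, and the fitting layer assigns
it −∞ joint density.  α₂ is defined as 1/π₂, the effective weight on the
level-1 prediction error — positive by construction, so the convention of
reporting learning-rate magnitudes makes any sign-flip rule a no-op (the
extraction API flags this).  ε₂/ε₃ are the belief increments μᵢ − μ̂ᵢ.

Free parameters carry Gaussian priors in an unconstrained space: ω₂ ~
N(−3, 4²), ω₃ ~ N(−6, 3²), ω₄ ~ N(−6, 3²), logit(α) ~ N(0, 2²) for
Rescorla–Wagner, (β₀, log μ) ~ N(−2.3, 1.5²) for Sutton K1, and log ζ ~
N(log 2, 1.5²) everywhere.  κ is fixed at 1 with zero variance (a
deliberate complexity reduction for low-trial designs), and initial beliefs
are wide (σ₂⁰ = 1, σ₃⁰ = 1).  MAP estimation uses Nelder-Mead with seeded
multistarts (first start at the prior means, the rest jittered by half a
prior SD; 1e-6 tolerances).  The log-model evidence is the Laplace
approximation at the MAP with a central-finite-difference Hessian (step
1e-4); non-positive-definite Hessians are regularised by eigenvalue
flooring at 1e-8 and flagged.  `ideal_observer_priors` optimises the
initial tendency and the ω's to minimise accumulated Shannon surprise over
given input sequences and returns the resulting posterior means as prior
means, falling back to neutral values on optimiser failure.

Random-effects model selection runs the variational Dirichlet scheme under
a uniform Dirichlet(1) prior.  Exceedance probabilities come from
Monte-Carlo draws over the fitted Dirichlet (10⁶ by default; the two-model
case uses the exact Beta tail probability), the Bayes omnibus risk from the
free-energy comparison of the random-effects model against the
equal-frequency null, and PXP_k = EP_k (1 − BOR) + BOR/K.  Family-level
inference pools Dirichlet mass over model families, with each family's
share of the uniform prior entering the protected value.

## Cleaning and statistics

Trials with a missing fraction strictly above 25 % are discarded;
participants with strictly more than a third of trials removed are
excluded.  Winsorization replaces values whose |z| exceeds 3 — z computed
from the full sample mean and SD (ddof = 1; the pooling level is otherwise
unspecified, and the screen is applied per metric within each
condition × expectedness cell) — with 1 % beyond the next most extreme
retained score, sign-aware so that "1 % larger" means 1 % further from zero
on either tail even for negative-valued metrics.  The rule is a single
pass and idempotent on screened data.

Repeated-measures ANOVAs (partial eta squared), paired/one-sample t-tests
and correlations are delegated to pingouin; paired Cohen's d is reported in
the d_z convention (mean difference over the SD of differences) with a 95 %
CI.  Post-hoc Δ-score comparisons are Bonferroni-corrected within each
ANOVA's family.  Bayes factors are provided only as the BIC approximation
exp((BIC_null − BIC_alt)/2) and are labelled a substitute in the output:
they are prior-free and will not numerically match fully Bayesian values.

## Validation studies and problem sizes

The suite validates each layer at deliberately small, fixed sizes:

* single-step HGF equivalence against a stateless hand-derived oracle over
  a grid of > 100 parameter points at 1e-10;
* reduction limits — Sutton K1 with zero meta-rate equals Rescorla–Wagner
  exactly; a 3-level filter with ω₃ → −∞ *and a pinned zero-variance third
  level* (μ₃⁰ = 0, σ₃⁰ → 0) matches the 2-level filter to 1e-6.  The
  zero-variance pin is required: with a finite σ₃⁰ the third-level mean
  still moves and perturbs the level-2 prediction variance;
* model-selection symmetry (equal evidences → PXP = 1/K) at 10⁶ draws;
* parameter recovery — 20 agents, 150 trials, ω₂ spanning [−5.5, −1.5] —
  and model recovery — 20 agents per generator, HGF3 vs Rescorla–Wagner,
  compared at family level.  Both use a stimulus sequence with alternating
  stable and volatile phases (majority probability 0.9; switches every 10
  trials inside two volatile spans).  A single stationary 80/20 block
  leaves the volatility hierarchy weakly identified at this scale, so the
  recovery studies define their own input; the session generator's
  protocol remains the static three-block design;
* pupil-gain recovery within 2 % on 100 noiseless trials, with strict
  monotonicity of peak in injected surprisal;
* an end-to-end three-agent run checking artifact completeness, a positive
  expected-trial interception advantage in every block, larger
  unexpected-trial pupil responses, and sign-stable conclusions with
  Winsorization on and off.

## Known limitations

Group-level fits are per-participant MAP, not hierarchical empirical
Bayes.  The Laplace evidence is a local approximation and can misrank
models whose posteriors are strongly non-Gaussian.  The Sutton K1
implementation follows the original single-cue formulation (rate clipped
at 1 and flagged); toolbox variants differ in the trace-decay form.  The
agents' gaze model is kinematically minimal, and the interception model is
probabilistic rather than mechanical, so absolute effect sizes produced by
the generator are design choices, not predictions.
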