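# Methods

This note documents the models implemented in `torchsearch`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Task environment

The search display is modeled as eight areas of interest (AOIs) on a 2×4
grid: hiding locations 0–3 on the top row, cue locations 4–7 directly
beneath them, one cue per screen column. Moves are restricted to
4-connected neighbors (no diagonal moves, no staying in place), so corner
locations have two available moves and inner locations three. The single
adjacency the task geometry pins down — location 0 neighboring 1 and 4 — is
consistent with this choice; diagonal connectivity is the main alternative
and is deliberately excluded (it would shorten paths and flatten the
distinction between rows).

Two condition rules govern reward:

* **Skewed** — one predetermined target location for the whole block;
  transitioning into it is immediately rewarded.
* **Uniform** — the target is the column-pair of the episode's cue, and
  reward is *gated*: it is delivered only if the cue location was visited
  earlier in the episode. The gate is a latent flag, not part of any state
  the agent observes, which makes the process non-Markovian from the
  agent's perspective.

Episode setup draws the start uniformly from all 8 locations and the cue
uniformly from the 4 cue locations (also in Skewed episodes, where it is
irrelevant to reward but still indexes the Q-table). Starting on the cue
sets the gate; starting on the target grants nothing — reward requires a
transition *into* the target. Episodes are capped at 100 steps (an
ε-greedy walk on an 8-node graph terminates almost surely, but the cap
bounds the worst case); capped episodes count at the cap in any mean.

## Q-learning agent

A dense table Q(s, a, c) over (state, destination, cue) is initialized to
zero and updated by one-step temporal difference with learning rate α,
discount γ, and bootstrap max over the neighbors of the next state. Action
selection is ε-greedy with ε = 0.5 at **both** training and test time (the
frozen-Q evaluation freezes the values, not the exploration rate); a
pure-greedy evaluation mode exists behind a flag. Greedy ties are broken
uniformly at random — with a zero-initialized table, the early policy is
therefore an unbiased random walk, and the learning trajectory runs from
random to directed exploration, which is exactly the range of behavior the
complexity analysis feeds on.

The protocol trains each model for 300 episodes, then evaluates the frozen
table on 1000 episodes, reporting mean steps-to-target. The grid search
spans α ∈ [0, 1] and γ ∈ [0.5, 1]; the default resolution is 0.05 (231
cells), trained and evaluated independently per condition with the pooled
mean across conditions as the cell score. At this resolution the full
protocol takes well under a minute on one CPU; a 0.01 grid is a config
change away and takes proportionally longer.

## Scan-path complexity

A visit sequence is summarized by an 8×8 row-stochastic transition matrix.
The estimator is a fixed-emission discrete Markov model: each location is
its own state (identity emission), so the states are fully observed and
each EM iteration's expected transition counts equal the empirical counts —
the fit's optimum is the (smoothed) count estimate in closed form. The
model is still run with 30 random initializations, each drawing a random
row-stochastic starting matrix that doubles as a randomized Dirichlet
prior with per-cell mean 0.5; the resulting scatter of estimates around the
maximum-likelihood solution supplies the between-initialization spread used
for confidence intervals. With the pseudocount set to zero every
initialization returns the pure count estimate exactly. An independent
cross-check in the test suite verifies that an external EM implementation
(hmmlearn's `CategoricalHMM` with the emission matrix pinned to identity)
lands on the same estimate.

Conventions, all chosen once and fixed:

* **Entropy**: H(P) = −Σ_ij P_ij ln P_ij over all 64 cells, natural
  logarithm, 0·ln 0 = 0. The reported scale is **log-entropy**, ln H(P),
  under which the uniform (random-search) matrix scores
  ln(8·ln 8) ≈ 2.8116.
* **Pooling**: when the complexity of a learned strategy is computed, all
  training episodes of a condition are concatenated into one long sequence
  before counting, as a session of trials forms one scan path; the seam
  transitions (last state of one episode to first state of the next) are
  counted. Per-sequence counting, which drops the seams, is the default
  everywhere else and a flag on every estimator.
* **Zero rows**: a row with no observations falls back to the uniform
  distribution — the maximum-entropy choice — rather than being undefined.
* **Self-transitions**: consecutive identical fixations are retained by
  default; a `collapse_repeats` flag merges them so a matrix describes eye
  movements rather than dwells. The toddler-versus-adult matrix contrast
  uses collapsed matrices, since dwelling behavior would otherwise dominate
  the diagonal and mask where the movements differ.

A caveat on absolute levels: the log-entropy of an *estimated* matrix
depends on the estimator's conventions — smoothing mass, pooling, and how
much probability lands outside the support of the walk. Under the
conventions above, sequences confined to the 4-connected graph have
row support of at most three neighbors plus seam transitions, which caps
the attainable log-entropy well below the 2.81 uniform bound. Orderings and
condition differences are robust to these conventions; absolute levels are
not comparable across implementations with different smoothing, and the
acceptance suite documents where our levels sit relative to the published
ones.

The group-level analysis regresses per-initialization log-entropies on
group, condition, and their interaction (OLS), compared by AIC against an
intercept-only null. The matrix contrast fits a logistic regression on the
binary outcome "first group's probability exceeds the second's", per
ordered cell (exact ties at 1e−12 dropped), on indicators for the
destination being a cue versus a target location. Because those two
indicators partition the destinations, the model is fitted without an
intercept and each coefficient is the log-odds for its destination type;
swapping the inputs flips both signs.

## Synthetic cohort generator

The generator stands in for raw eye-tracking data. It emulates the study
conditions — 60 toddlers with ages uniform on [18, 36] months, 42 adults,
two within-subject conditions in counterbalanced order, 2 blocks × 4 test
trials per condition, Skewed blocks holding one target column and Uniform
blocks shuffling columns — and the qualitative structure the analyses
assume. It is a first-order biased walk over the 8 AOIs, not a model of
oculomotor control.

Per trial:

* The first fixation lands in the correct column with probability
  p_anticipate (Skewed: 0.22 + 0.30·a, where a is adaptivity; Uniform:
  0.25, the four-column chance level).
* Fixation durations are log-normal (toddler median 0.50 s, adult 0.26 s,
  σ_log 0.5). Consecutive same-AOI fixations occur with a staying
  probability (toddler 0.55, adult 0.25); moves prefer grid-adjacent AOIs
  (weight ×3) and are biased toward cue locations (toddlers ×1.35;
  additionally ×(1 + 2·a) in Uniform before the cue is found) or target
  locations (adults ×1.3; the known/indicated target ×(1 + 4.5·a) in
  Skewed and ×(1 + 5·a) in Uniform once the cue is found).
* **Engagement**: a trial is actively searched with probability 0.40
  (toddlers) / 0.75 (adults); otherwise the participant mostly stares
  (stay probability 0.945) without strategic biases. Engaged toddlers lapse
  into the same staring dynamics after a 5 s attention span. Toddlers are
  additionally more engaged in the familiar Skewed context, by
  0.24·(1 − a) — a familiarity effect that fades as strategic adaptivity
  takes over.
* **Adaptivity** a ramps logistically with toddler age, centered at 24
  months with a ±3-month width (0.12 → 0.88 across the ramp); adults have
  a = 1. All condition-linked biases scale with a, so condition effects on
  scanning grow with age and the condition×age interaction becomes
  statistically detectable near the ramp center at these sample sizes.
* Between-participant heterogeneity (condition-independent): engagement ~
  Beta around the group mean (concentration 8), staying probability
  jittered (SD 0.06), fixation tempo jittered (log-SD 0.15). This is what
  gives the participant-clustered standard errors something real to absorb.

Scoring applies the gaze-contingent rules deterministically: success
requires 200 ms of continuous dwell on the target (consecutive same-AOI
fixations accumulate), preceded in Uniform by 150 ms on the correct cue;
the criterion must complete within the 10 s window, and dwell credit starts
only after a 0.8 s onset latency (stimulus onset and orienting), so no
trial resolves in the first moments. Scanning counts between-column
movements over the whole path; an anticipatory look is a first fixation in
the correct column. `derive_trial_dvs` and the simulator share one scorer,
so re-deriving the DVs from a generated sequence reproduces the trial
record exactly.

The default parameters were calibrated once so that the generated grand
means sit near the descriptive anchors of the modeled study — success
≈ 0.43, time-to-target ≈ 3.09 s, scanning ≈ 2.72, anticipatory looks
≈ 0.30, each within ±30% — and so that the Johnson–Neyman boundary
recovered from generated cohorts lies near the 24-month ramp center. A
**null mode** zeroes every condition-linked parameter (cue attraction,
target knowledge, guided search, the familiarity boost, the anticipation
gap) while keeping group differences and heterogeneity; it is the
type-I-error testbed for the regression stage.

What the generator does **not** emulate: saccade kinematics and latencies,
calibration error, off-screen looks and data loss, pixel-level gaze
coordinates, block-order fatigue, and any dependence of fixation durations
on content. Passing tests therefore show that the analysis pipeline
recovers the structure this generator encodes — not that it would recover
the same structure from real recordings.

## Regression models

GLMs are fitted by iteratively reweighted least squares via statsmodels:
logistic for success and anticipatory looks, Gaussian for time-to-target
(successful trials only), Poisson for scanning counts. The original
random-effects structure is replaced by fixed-effects models with
participant-clustered sandwich standard errors — the package's claims are
about effect directions and recovery on synthetic data, not
coefficient-for-coefficient replication. The AIC ladder (null, condition,
condition+age, condition×age) is fitted on one shared set of observations;
ΔAIC is anchored at the null. Condition contrasts within a group are
unadjusted Wald tests (the contrast set is small and pre-specified;
Bonferroni is a caller-side option). The Johnson–Neyman procedure evaluates
the conditional condition effect β_c + age·β_int on an age grid with
delta-method standard errors from the fitted (cluster-robust) covariance; a
boundary is reported only when the significant region is contiguous and
one-sided on the grid, otherwise all region edges are listed.

## Numerical choices and problem sizes

* Acceptance-scale runs use the 0.05 grid (231 cells, 300 train / 1000
  test episodes per cell per condition, ~30 s) and 300-episode training for
  the complexity targets; the test suite's simulation studies use 400
  replications for type-I error and coverage, 150 for AIC model recovery,
  and the median over 5 cohorts for the Johnson–Neyman check — sizes at
  which the binomial noise is comfortably inside each stated tolerance.
* EM tolerance 1e−4, at most 100 iterations (convergence is effectively
  one step, see above); entropy validation requires rows to sum to 1 within
  1e−9; matrix-contrast ties use 1e−12.
* All randomness flows through numpy Generators; library code never seeds
  itself. The CLI derives stage-scoped child streams from the master seed,
  so stages are reproducible independently of execution order.

## Known limitations

* Absolute log-entropy levels are estimator-convention-dependent (see
  above); cross-implementation comparisons should use orderings and
  within-implementation differences.
* The Q-table cannot represent the Uniform gate (the flag is not in its
  index), so the "most efficient" learned Uniform strategy is the best
  policy *within this representation*, not the task's global optimum.
* The generator's engagement/attention-span machinery is a coarse stand-in
  for toddler inattention; it was chosen for its effect on trial-level DV
  distributions, not as a cognitive model.
* Gaussian errors for time-to-target ignore the variable's skew and
  censoring at 10 s; at these effect sizes that approximation is adequate
  for direction-level claims only.
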