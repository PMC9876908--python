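# Methods

## The task

The environment is a sequential two-choice Markov decision task: from a
fixed start state `S0` the agent picks left or right, transitions to one of
two stage-2 states with probabilities 0.7 (common) / 0.3 (rare), picks
again, and lands in an outcome state paying 0, 10 or 25 yen. All model
learning operates on rewards rescaled to the unitless values {0, 0.4, 1}.

The canonical layout shipped in `data/canonical_task.yaml` is pinned by the
task's two published optimal values — Q\*(S0, right) = 14.5 yen and a best
stage-2 value of 17.5 yen at (R1, left) — computed by exact backward
induction. Those two constraints do not determine the left branch uniquely;
the shipped left branch satisfies the remaining requirement
Q\*(S0, left) < Q\*(S0, right) with Q\*(S0, left) = 9.25 yen, and the whole
layout is overridable via a YAML config, which is the source of truth for
tests. The human task's 2-second response deadline and repeat-on-miss rule
are not modelled: no learner equation consumes missed trials, and simulated
agents always respond.

## The learners

Three learners share one state container (SARSA values, FORWARD values,
transition estimates):

- **SARSA (model-free).** Q(s,a) ← Q(s,a) + α·δ, with
  δ = r(s′) + γ·Q(s′,a′) − Q(s,a) and γ fixed at 1 (both choices of a trial
  resolve at once, so discounting has no role). The stage-1 update
  bootstraps on the *chosen* stage-2 action (on-policy, as the model's name
  implies) using its pre-update value; the stage-2 update is terminal.
- **FORWARD (model-based).** Transition estimates move toward the observed
  successor by η·(1 − T) while the non-visited successor is scaled by
  (1 − η), keeping each row exactly stochastic. Values come from a backward
  Bellman sweep Q(s,a) = Σ T(s,a,s′)·[E[r(s′)] + max Q(s′,·)]. Outcome
  rewards are treated as known to the learner (outcome figures have fixed
  reward associations); a learn-rewards toggle is deliberately absent —
  only the transition model is learned.
- **HYBRID.** Q = w·Q_FWD + (1 − w)·Q_SARSA with w ∈ [0, 1]; w = 0 and
  w = 1 reduce to the pure learners (the silent component still updates).

Actions are sampled from a softmax with inverse temperature β, computed
with max-subtraction. Within a trial the order is: emit both choice
probabilities from the current hybrid values (the standard likelihood
convention — values *before* that trial's updates), update the transition
model at both stages, re-sweep the FORWARD values in full (≤10 state-action
pairs, so no incremental bookkeeping is worth it), then apply the two SARSA
updates in temporal order.

Initial values are Q_SARSA = Q_FWD = 0 and T = 0.5/0.5. Note one
consequence: because Q_FWD is recomputed from T after every trial, the very
first sweep maps Q_FWD from the all-zero initialization onto the values
implied by uniform transition estimates, even when η = 0. From trial 2
onward a non-learning agent's choice probabilities are exactly constant.

## Parameter estimation

Estimates are MAP: minimize the teacher-forced negative log likelihood of
both choices of every trial plus negative log prior densities, under
0 < α, η, w < 1 and 0 < β < 10 (L-BFGS-B, a 1e-6 interior margin on the
open bounds, objective tolerance 1e-8). Priors: Beta(2,2) on α and η,
Gamma on β, no penalty on w (it is only box-constrained). The gamma prior's
(2, 3) is read as shape 2, scale 3 — mode at β = 3, mean 6 — because
whole-session β estimates of 3.6–5.2 and the β < 10 bound make the
shape/rate reading (mean 2/3) untenable; the rate parameterization remains
selectable in `PriorSpec`.

Sessions are fitted in 40-trial blocks. The learner state at the end of a
block, replayed under that block's fitted parameters, initializes the next
block; the fitted parameters also seed the next block's optimizer. Block 1
uses 10 restarts (the incoming start, the prior mode, and Latin-hypercube
draws); later blocks, already warm-started, use 4. A single constrained
optimizer call would match the original description; the restarts only
guard against local minima and the fitted optimum is restart-idempotent.

The fixed-effects variant shares one parameter vector across a group,
summing likelihoods with per-participant carryover states and a *single*
prior penalty, so the regularization strength does not grow with group
size when the parameters are shared.

Model comparison uses BIC = 2·NLL + k·ln(n) with n = 2 observations per
trial and k = 2 (SARSA: α, β), 2 (FORWARD: η, β) or 4 (HYBRID). Diagnostic
surfaces: Spearman rank-correlation matrices of per-participant estimates
(constant columns are flagged NaN, never silently zero) and a
bias/RMSE/rank-correlation recovery report.

## SVO scoring

The slider measure's six primary items ship as a data file; the angle is
atan2(mean other-payoff − 50, mean self-payoff − 50) in degrees. The
bundled menu reproduces the measure's archetype angles (complete
individualism 7.82°, perfect altruism 61.39°, competitiveness −16.26°),
which pins down the item table. Strict classification keeps only
pronounced groups — prosocial at ≥ 37.48° (inequity aversion), proself at
≤ 7.82° — with boundary angles included in the named group, since an
archetypal responder must fall in its own category; the conventional split
is prosocial strictly above 22.45°. Exact-boundary results carry an
`at_boundary` flag.

## Behavioral metrics

The reward learning curve is a 20-trial moving average in one-trial steps.
The even window is centered with ten elements before and nine after the
current trial, truncating at the series edges to the available elements
(the convention of the original analysis environment's moving mean); the
centering is configurable and recorded in the output. RT summaries are per
40-trial block with stage-2 RTs split by transition type; the session's
first trial is excluded, missing RTs are ignored, and empty cells yield
NaN. Group comparisons are per-trial Wilcoxon rank-sum tests on
per-participant values (not pooled trials). Mixed-model and ANOVA
inference is out of scope by design: the module emits tidy long-format
tables ready for any standard mixed-model routine.

## Simulation study

The model-based condition runs HYBRID agents with w = 1 in the first
40-trial block and 0.5 thereafter; the model-free condition starts at
w = 0; both use α = η = 0.2, β = 5. Learning speed per repetition is the
slope b of a/(1 + exp(−b·x)) − a/2 fitted to the stage-1 value difference
Q(1,R) − Q(1,L), which is recorded at the moment of each first-stage choice
and therefore starts at 0. Sigmoid fits start at (a = 2·max|y|, b = 0.05)
with bounds a ∈ (0, 10], b ∈ (0, 5]; flat series are flagged
unidentifiable, and failed fits are excluded from slope comparisons and
counted in the report. Slopes are compared with a Wilcoxon rank-sum test
and early reward with a one-sided two-sample t-test on per-repetition
means over trials 1–40.

The reference condition size is 10,000 repetitions; the default desk runs
and the acceptance suite use 1,000 (and unit tests a few hundred), where
both the early-reward and slope contrasts already resolve at p < 0.001.
One caveat worth recording: the origin-sigmoid slope is amplitude
invariant, so it separates schedules by the *shape* of the learning curve.
It cleanly separates w = 1 from w = 0 starts, and the group-anchored
contrast at the simulation learning rates, but it is not a robust
discriminator of mid-range w contrasts under fast learning rates
(α ≈ 0.45), where curves differ mostly in amplitude.

## Synthetic cohorts

The generator produces complete participant datasets (trial log with RTs,
six SVO slider responses, group label, true per-block parameters) so the
whole pipeline is testable without any download. Group parameter
distributions are truncated normals around per-block means anchored to the
study population's whole-session estimates (proself α 0.34, η 0.49,
β 5.21, w 0.49; prosocial α 0.33, η 0.48, β 4.58, w 0.40), spread over
blocks with the qualitative within-session pattern: α decreasing, β
increasing, w decreasing from an elevated proself first-block value (0.80
vs 0.45). SVO angles are drawn from truncated-normal clusters (proself
centered at 2.5°, prosocial at 45°) and converted to slider allocations by
coordinate descent on the item menu to within 1°.

The RT model is wholly invented — the study treats RTs only statistically.
RT1 decays from 700 ms toward a 485 ms asymptote with a 50-trial time
constant; RT2 is 500 ms plus 330 ms times the learner's transition
surprise 1 − T(S0, a1, s2) (evaluated pre-update), Gaussian noise,
truncated to [150, 2000] ms. These constants were chosen once to reproduce
the qualitative late-session ordering RT1 < RT2-common < RT2-rare and the
practice trend, and are config-exposed.

What passing tests on synthetic cohorts do *not* show: real participants
are not stationary HYBRID agents with blockwise-constant parameters, real
RTs have heavy tails, lapses and missed trials, and real SVO responses are
not noiseless projections of a latent angle. The generator validates the
pipeline's correctness and recovery behavior, not claims about human data.

## Problem sizes

Defaults were chosen so a full desk run stays in the minutes range: the
BIC comparison uses 30 agents x 200 trials x 3 models; recovery uses two
40-agent groups fitted on their first block (block-1 estimates do not
depend on later trials); the simulation contrast uses 1,000 repetitions
per schedule. All sizes are arguments, and the 10,000-repetition reference
run remains feasible.
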