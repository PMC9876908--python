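# twostep

Model-based vs model-free reinforcement learning analysis for the
sequential two-choice Markov decision task, with social value orientation
(SVO) group classification.

## The problem

In a two-stage probabilistic decision task, a participant chooses left or
right, transitions to one of two second-stage states (70% common / 30%
rare), chooses again, and earns 0, 10 or 25 yen. Behavior in such tasks
mixes two learning systems: a **model-free** system that reinforces
rewarded actions via reward prediction errors (SARSA), and a
**model-based** system that learns the transition structure via state
prediction errors and plans through it (FORWARD). The HYBRID model mixes
their state-action values with a weight *w* ∈ [0, 1],

    Q_SARSA(s,a) ← Q_SARSA(s,a) + α·[r(s′) + γ·Q_SARSA(s′,a′) − Q_SARSA(s,a)]
    T(s,a,s′)    ← T(s,a,s′) + η·[1 − T(s,a,s′)]      (non-visited: ×(1−η))
    Q_FWD(s,a)   = Σ_s′ T(s,a,s′)·[E[r(s′)] + max_a′ Q_FWD(s′,a′)]
    Q_HYB        = w·Q_FWD + (1−w)·Q_SARSA
    P(s,a)       = exp(β·Q(s,a)) / Σ_a′ exp(β·Q(s,a′))

with γ fixed at 1 and rewards rescaled to {0, 0.4, 1} for learning. The
free parameters (α, η, β, w) are estimated per 40-trial block by MAP —
negative log likelihood plus Beta(2,2) priors on α, η and a Gamma(shape 2,
scale 3) prior on β, under 0 < α, η, w < 1 and 0 < β < 10 — with value and
parameter carryover between blocks, and the three models are compared by
BIC. Participants are classified prosocial / proself from their SVO slider
angle (strict thresholds 37.48° / 7.82°; conventional split 22.45°).

The package is aimed at researchers who want to fit, compare and
recover-test these learners on trial logs — their own, the deposited
study data (via a column-mapping adapter), or fully synthetic cohorts
generated by the built-in simulator.

## Worked example

```python
import numpy as np
from twostep import build_canonical_task, ground_truth_values
from twostep.fitting import BlockScheme, PriorSpec, fit_participant_blockwise
from twostep.synthetic_data import SyntheticCohortSpec, generate_cohort

config = build_canonical_task()
q = ground_truth_values(config, units="yen")
print(f"Q*(S0,right) = {q[('S0','right')]:.2f} yen; "
      f"Q*(S0,left) = {q[('S0','left')]:.2f} yen; "
      f"best stage-2 value = {q[('R1','left')]:.2f} yen")

spec = SyntheticCohortSpec(n_proself=1, n_prosocial=0, seed=42)
participant = generate_cohort(spec, config)[0]
print(f"{participant.participant_id}: group={participant.group_label}, "
      f"SVO angle = {participant.svo_angle_deg:.2f} deg, "
      f"true block-1 w = {participant.true_params[0].w:.2f}")

result = fit_participant_blockwise(
    participant, BlockScheme(), PriorSpec(), "hybrid", config,
    rng=np.random.default_rng(0),
)
print(result.params_frame()[["block", "alpha", "eta", "beta", "w", "nll"]]
      .round(3).to_string(index=False))
```

prints

```
Q*(S0,right) = 14.50 yen; Q*(S0,left) = 9.25 yen; best stage-2 value = 17.50 yen
S001: group=proself, SVO angle = 3.91 deg, true block-1 w = 0.95
 block  alpha   eta  beta     w    nll
     1  0.369 0.309 3.824 0.800 48.057
     2  0.528 0.386 5.614 0.377 33.893
     3  0.080 0.483 7.672 0.437 35.235
     4  0.500 0.369 8.393 1.000 19.852
     5  0.451 0.352 5.215 0.360 41.798
```

The first line is the task's ground truth: the right first-stage choice is
optimal (14.5 vs 9.25 yen), and the best second-stage action is worth 17.5
yen. The synthetic participant is a proself-group HYBRID agent (SVO angle
3.91° ≤ 7.82°) whose generating model-based weight started high (0.95);
the block-1 MAP estimate (ŵ = 0.80) tracks it, while single-subject
40-trial blocks leave visible estimation noise in the later blocks — which
is exactly why group-level recovery and BIC comparisons in the test suite
use cohorts of 30–80 agents.

A command-line layer wraps the same functions:

```sh
twostep generate --n-proself 40 --n-prosocial 40 --seed 0 --out data/
twostep fit --model hybrid --input data/trials.csv --seed 0 --out fits.csv
twostep simulate --schedule mb --reps 1000 --seed 0 --out sim/
```

## Layout

- `twostep.task_env` — task layout, transition sampling, optimal values, trial-log CSV
- `twostep.learners` — SARSA / FORWARD / HYBRID updates, softmax, generative mode
- `twostep.fitting` — blockwise MAP, fixed effects, BIC, recovery diagnostics
- `twostep.svo` — slider scoring and group classification
- `twostep.behavior_metrics` — moving-average reward, RT block summaries, rank-sum comparisons
- `twostep.simulation_study` — weight-schedule simulations and sigmoid learning-speed fits
- `twostep.synthetic_data` — synthetic cohort generator and dataset I/O

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
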