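"""SARSA, FORWARD and HYBRID value learners with softmax action selection.

The model-free SARSA learner updates state-action values from reward
prediction errors:

    Q_SARSA(s,a) <- Q_SARSA(s,a) + alpha * delta_RPE
    delta_RPE    =  r(s') + gamma * Q_SARSA(s',a') - Q_SARSA(s,a)

The model-based FORWARD learner maintains transition-probability estimates
T(s,a,s') driven by state prediction errors (delta_SPE = 1 - T(s,a,s'))
and derives values by a Bellman sweep:

    Q_FWD(s,a) = sum_s' T(s,a,s') * [E[r(s')] + max_a' Q_FWD(s',a')]

The HYBRID learner mixes the two with a weight w in [0,1]:

    Q_HYB = w * Q_FWD + (1-w) * Q_SARSA

Actions are drawn from a softmax with inverse temperature beta.  All
learning operates on the rescaled rewards {0, 0.4, 1}; the discount factor
gamma is fixed at 1 because both choices of a trial are resolved at once.

Operations exist in two modes: teacher-forced (:func:`process_trial`, used
for likelihood computation along an observed trial log) and generative
(:func:`act_episode`, sampling actions and transitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task_env import (
    ACTIONS,
    CompiledTask,
    TaskConfig,
    TrialRecord,
    compile_task,
    sample_transition,
)

_A = {"left": 0, "right": 1}


@dataclass(frozen=True)
class LearnerParams:
    """Free parameters of the HYBRID learner family.

    alpha : model-free learning rate, in (0,1)
    eta   : model-based (transition) learning rate, in (0,1)
    beta  : softmax inverse temperature, in (0,10)
    w     : model-based weight, in [0,1]
    gamma : discount factor, fixed at 1
    """

    alpha: float
    eta: float
    beta: float
    w: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0,1]")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta={self.eta} outside [0,1]")
        if not (0.0 <= self.beta <= 10.0):
            raise ValueError(f"beta={self.beta} outside [0,10]")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"w={self.w} outside [0,1]")
        if self.gamma != 1.0:
            raise ValueError("gamma is fixed at 1")


@dataclass
class LearnerState:
    """Mutable value and transition-model state of one learner.

    Values are stored as small nested lists indexed by the compiled task's
    (state, action) ordering; ``t_first[si][a]`` is the estimated
    probability of the first-listed successor (the second is its
    complement, so each row is exactly stochastic by construction).
    """

    task: CompiledTask
    params: LearnerParams
    q_sarsa: list = field(default_factory=list)
    q_fwd: list = field(default_factory=list)
    t_first: list = field(default_factory=list)

    @classmethod
    def fresh(cls, config: TaskConfig | CompiledTask, params: LearnerParams) -> "LearnerState":
        """All Q values 0, transition estimates uniform (0.5 / 0.5)."""
        task = config if isinstance(config, CompiledTask) else compile_task(config)
        n = task.n_states
        return cls(
            task=task,
            params=params,
            q_sarsa=[[0.0, 0.0] for _ in range(n)],
            q_fwd=[[0.0, 0.0] for _ in range(n)],
            t_first=[[0.5, 0.5] for _ in range(n)],
        )

    def copy(self) -> "LearnerState":
        return LearnerState(
            task=self.task,
            params=self.params,
            q_sarsa=[row[:] for row in self.q_sarsa],
            q_fwd=[row[:] for row in self.q_fwd],
            t_first=[row[:] for row in self.t_first],
        )

    # -- dict-style views --------------------------------------------------

    def q_sarsa_table(self) -> dict[tuple[str, str], float]:
        return {
            (s, a): self.q_sarsa[si][ai]
            for si, s in enumerate(self.task.states)
            for a, ai in _A.items()
        }

    def q_fwd_table(self) -> dict[tuple[str, str], float]:
        return {
            (s, a): self.q_fwd[si][ai]
            for si, s in enumerate(self.task.states)
            for a, ai in _A.items()
        }

    def t_hat(self, state: str, action: str, successor: str) -> float:
        si = self.task.state_index[state]
        ai = _A[action]
        names = self.task.succ_name[si][ai]
        if successor == names[0]:
            return self.t_first[si][ai]
        if successor == names[1]:
            return 1.0 - self.t_first[si][ai]
        raise ValueError(f"{successor!r} is not a successor of ({state!r}, {action!r})")

    def t_hat_table(self) -> dict[tuple[str, str, str], float]:
        out = {}
        for si, s in enumerate(self.task.states):
            for a, ai in _A.items():
                n0, n1 = self.task.succ_name[si][ai]
                out[(s, a, n0)] = self.t_first[si][ai]
                out[(s, a, n1)] = 1.0 - self.t_first[si][ai]
        return out


# -- elementary operations -------------------------------------------------


def softmax_probs(q_values, beta: float):
    """Softmax choice probabilities exp(beta*Q) / sum exp(beta*Q).

    Accepts a sequence ordered as ``ACTIONS`` or a mapping action->value;
    returns the same container type.  Uses max-subtraction for overflow
    safety.
    """
    if isinstance(q_values, dict):
        keys = list(q_values)
        vals = [q_values[k] for k in keys]
        m = max(beta * v for v in vals)
        ex = [math.exp(beta * v - m) for v in vals]
        z = sum(ex)
        return {k: e / z for k, e in zip(keys, ex)}
    vals = list(q_values)
    m = max(beta * v for v in vals)
    ex = [math.exp(beta * v - m) for v in vals]
    z = sum(ex)
    return [e / z for e in ex]


def sarsa_update(
    state: LearnerState,
    s: str,
    a: str,
    r_next: float,
    s_next: str | None,
    a_next: str | None,
) -> tuple[LearnerState, float]:
    """One SARSA temporal-difference update on Q(s,a); returns delta_RPE.

    ``s_next``/``a_next`` are ``None`` at a terminal transition, in which
    case the bootstrap term is zero.  ``r_next`` is in scaled units.
    """
    new = state.copy()
    task = new.task
    si, ai = task.state_index[s], _A[a]
    if (s_next is None) != (a_next is None):
        raise ValueError("s_next and a_next must both be None (terminal) or both given")
    boot = 0.0
    if s_next is not None:
        boot = new.q_sarsa[task.state_index[s_next]][_A[a_next]]
    delta = r_next + state.params.gamma * boot - new.q_sarsa[si][ai]
    new.q_sarsa[si][ai] += state.params.alpha * delta
    return new, delta


def forward_transition_update(
    state: LearnerState, s: str, a: str, s_observed: str
) -> tuple[LearnerState, float]:
    """Update T(s,a,.) toward the observed successor; returns delta_SPE.

    The observed entry moves toward 1 by eta * (1 - T); the non-visited
    successor is scaled by (1 - eta), so the row remains stochastic.
    """
    new = state.copy()
    task = new.task
    si, ai = task.state_index[s], _A[a]
    names = task.succ_name[si][ai]
    if s_observed not in names:
        raise ValueError(f"{s_observed!r} is not a successor of ({s!r}, {a!r})")
    eta = state.params.eta
    t0 = new.t_first[si][ai]
    t_obs = t0 if s_observed == names[0] else 1.0 - t0
    delta = 1.0 - t_obs
    t_obs_new = t_obs + eta * delta
    new.t_first[si][ai] = t_obs_new if s_observed == names[0] else 1.0 - t_obs_new
    return new, delta


def _forward_sweep(q_fwd: list, t_first: list, task: CompiledTask) -> None:
    """In-place backward Bellman sweep of Q_FWD from current T estimates."""
    n = task.n_states
    v2 = [0.0] * n
    for si in range(1, n):
        rs = task.r_scaled[si]
        for ai in (0, 1):
            t = t_first[si][ai]
            q_fwd[si][ai] = t * rs[ai][0] + (1.0 - t) * rs[ai][1]
        v2[si] = q_fwd[si][0] if q_fwd[si][0] >= q_fwd[si][1] else q_fwd[si][1]
    for ai in (0, 1):
        t = t_first[0][ai]
        i0, i1 = task.succ_idx[0][ai]
        q_fwd[0][ai] = t * v2[i0] + (1.0 - t) * v2[i1]


def forward_values(state: LearnerState, config: TaskConfig | None = None) -> dict:
    """Q_FWD(state, action) table from the current transition estimates.

    E[r] is the known scaled reward for outcome states and 0 for stage-2
    states; the max over an empty action set (outcomes) is 0.
    """
    new = state.copy()
    _forward_sweep(new.q_fwd, new.t_first, new.task)
    return new.q_fwd_table()


def hybrid_values(q_fwd: dict, q_sarsa: dict, w: float) -> dict:
    """Elementwise convex combination w*Q_FWD + (1-w)*Q_SARSA."""
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w={w} outside [0,1]")
    if set(q_fwd) != set(q_sarsa):
        raise ValueError("q_fwd and q_sarsa must have identical keys")
    return {k: w * q_fwd[k] + (1.0 - w) * q_sarsa[k] for k in q_fwd}


# -- per-trial kernel ------------------------------------------------------


def _compile_trial(trial: TrialRecord, task: CompiledTask) -> tuple:
    """(a1, s2_index, slot1, a2, slot2, r_scaled) integer view of a trial."""
    a1 = _A[trial.a1]
    s2i = task.state_index[trial.s2]
    names1 = task.succ_name[0][a1]
    if trial.s2 not in names1:
        raise ValueError(f"trial {trial.trial_index}: illegal stage-1 successor")
    slot1 = names1.index(trial.s2)
    a2 = _A[trial.a2]
    names2 = task.succ_name[s2i][a2]
    if trial.s3 not in names2:
        raise ValueError(f"trial {trial.trial_index}: illegal stage-2 successor")
    slot2 = names2.index(trial.s3)
    r = task.config.reward_scaled[trial.reward_yen]
    return a1, s2i, slot1, a2, slot2, r


def _step(
    q_s: list,
    q_f: list,
    t_first: list,
    task: CompiledTask,
    alpha: float,
    eta: float,
    beta: float,
    w: float,
    a1: int,
    s2i: int,
    slot1: int,
    a2: int,
    slot2: int,
    r: float,
) -> tuple[float, float]:
    """Teacher-forced single-trial update; returns (P(a1), P(a2)).

    Choice probabilities are emitted from the hybrid values *before* this
    trial's updates.  Update order within the trial: transition model for
    both observed transitions, FORWARD value sweep, then the SARSA updates
    in temporal order (stage 1 bootstrapping on the chosen stage-2 action's
    pre-update value, stage 2 terminal).
    """
    wc = 1.0 - w
    # stage-1 choice probability under current hybrid values
    h0 = w * q_f[0][0] + wc * q_s[0][0]
    h1 = w * q_f[0][1] + wc * q_s[0][1]
    d = beta * (h1 - h0)
    p_right = 1.0 / (1.0 + math.exp(-d)) if d > -700 else 0.0
    p1 = p_right if a1 == 1 else 1.0 - p_right
    # stage-2 choice probability
    h0 = w * q_f[s2i][0] + wc * q_s[s2i][0]
    h1 = w * q_f[s2i][1] + wc * q_s[s2i][1]
    d = beta * (h1 - h0)
    p_right = 1.0 / (1.0 + math.exp(-d)) if d > -700 else 0.0
    p2 = p_right if a2 == 1 else 1.0 - p_right
    # transition-model updates (state prediction errors), both stages
    t0 = t_first[0][a1]
    t_obs = t0 if slot1 == 0 else 1.0 - t0
    t_obs += eta * (1.0 - t_obs)
    t_first[0][a1] = t_obs if slot1 == 0 else 1.0 - t_obs
    t0 = t_first[s2i][a2]
    t_obs = t0 if slot2 == 0 else 1.0 - t0
    t_obs += eta * (1.0 - t_obs)
    t_first[s2i][a2] = t_obs if slot2 == 0 else 1.0 - t_obs
    _forward_sweep(q_f, t_first, task)
    # SARSA updates: stage 1 (r=0, bootstrap on chosen a2), then stage 2 (terminal)
    q2 = q_s[s2i][a2]
    q_s[0][a1] += alpha * (q2 - q_s[0][a1])
    q_s[s2i][a2] += alpha * (r - q2)
    return p1, p2


def process_trial(
    state: LearnerState, trial: TrialRecord, config: TaskConfig | None = None
) -> tuple[LearnerState, tuple[float, float]]:
    """Teacher-forced update over one observed trial.

    Returns the updated learner state and the stage-1 and stage-2 choice
    probabilities of the observed actions under the *pre-update* hybrid
    values (the standard likelihood convention).
    """
    new = state.copy()
    p = state.params
    probs = _step(
        new.q_sarsa, new.q_fwd, new.t_first, new.task,
        p.alpha, p.eta, p.beta, p.w, *_compile_trial(trial, new.task),
    )
    return new, probs


def act_episode(
    state: LearnerState,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    trial_index: int = 1,
) -> tuple[TrialRecord, LearnerState]:
    """Generative mode: sample one trial from the learner's softmax policy."""
    if rng is None:
        raise ValueError("act_episode requires an explicit rng")
    task = state.task
    cfg = config if config is not None else task.config
    p = state.params
    w, wc, beta = p.w, 1.0 - p.w, p.beta
    q_s, q_f = state.q_sarsa, state.q_fwd

    def p_right(si: int) -> float:
        h0 = w * q_f[si][0] + wc * q_s[si][0]
        h1 = w * q_f[si][1] + wc * q_s[si][1]
        d = beta * (h1 - h0)
        return 1.0 / (1.0 + math.exp(-d)) if d > -700 else 0.0

    a1 = "right" if rng.random() < p_right(0) else "left"
    s2 = sample_transition(cfg, cfg.start_state, a1, rng)
    a2 = "right" if rng.random() < p_right(task.state_index[s2]) else "left"
    s3 = sample_transition(cfg, s2, a2, rng)
    trial = TrialRecord(
        trial_index=trial_index,
        s1=cfg.start_state,
        a1=a1,
        s2=s2,
        transition_type=cfg.transition_type(cfg.start_state, a1, s2),
        a2=a2,
        s3=s3,
        reward_yen=cfg.reward_yen[s3],
    )
    new, _ = process_trial(state, trial)
    return trial, new
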