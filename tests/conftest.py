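import math

import numpy as np
import pytest

from twostep.task_env import ACTIONS, build_canonical_task


@pytest.fixture(scope="session")
def canonical():
    return build_canonical_task()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent straight-line oracle for the teacher-forced hybrid learner.
#
# Deliberately written against the TaskConfig interface with plain dicts and
# no code shared with twostep.learners: emits both choice probabilities from
# the current hybrid values, then updates the transition model at both
# stages, recomputes the FORWARD values by explicit enumeration, and applies
# the SARSA updates in temporal order (stage-1 bootstrap on the chosen
# stage-2 action's pre-update value; stage-2 terminal).
# ---------------------------------------------------------------------------


class OracleLearner:
    def __init__(self, config, alpha, eta, beta, w):
        self.config = config
        self.alpha, self.eta, self.beta, self.w = alpha, eta, beta, w
        states = config.nonterminal_states
        self.q_sarsa = {(s, a): 0.0 for s in states for a in ACTIONS}
        self.q_fwd = {(s, a): 0.0 for s in states for a in ACTIONS}
        self.T = {}
        for s in states:
            for a in ACTIONS:
                for nxt, _ in config.successors(s, a):
                    self.T[(s, a, nxt)] = 0.5

    def hybrid(self, s, a):
        return self.w * self.q_fwd[(s, a)] + (1 - self.w) * self.q_sarsa[(s, a)]

    def choice_prob(self, s, chosen):
        num = math.exp(self.beta * self.hybrid(s, chosen))
        den = sum(math.exp(self.beta * self.hybrid(s, a)) for a in ACTIONS)
        return num / den

    def t_update(self, s, a, observed):
        for nxt, _ in self.config.successors(s, a):
            if nxt == observed:
                self.T[(s, a, nxt)] += self.eta * (1.0 - self.T[(s, a, nxt)])
            else:
                self.T[(s, a, nxt)] *= 1.0 - self.eta

    def recompute_forward(self):
        cfg = self.config
        for s2 in cfg.stage2_states:
            for a in ACTIONS:
                self.q_fwd[(s2, a)] = sum(
                    self.T[(s2, a, o)] * cfg.scaled_reward(o)
                    for o, _ in cfg.successors(s2, a)
                )
        for a in ACTIONS:
            total = 0.0
            for s2, _ in cfg.successors(cfg.start_state, a):
                total += self.T[(cfg.start_state, a, s2)] * max(
                    self.q_fwd[(s2, aa)] for aa in ACTIONS
                )
            self.q_fwd[(cfg.start_state, a)] = total

    def process(self, trial):
        cfg = self.config
        p1 = self.choice_prob(cfg.start_state, trial.a1)
        p2 = self.choice_prob(trial.s2, trial.a2)
        self.t_update(cfg.start_state, trial.a1, trial.s2)
        self.t_update(trial.s2, trial.a2, trial.s3)
        self.recompute_forward()
        boot = self.q_sarsa[(trial.s2, trial.a2)]
        self.q_sarsa[(cfg.start_state, trial.a1)] += self.alpha * (
            boot - self.q_sarsa[(cfg.start_state, trial.a1)]
        )
        r = cfg.scaled_reward(trial.s3)
        self.q_sarsa[(trial.s2, trial.a2)] += self.alpha * (r - boot)
        return p1, p2


def oracle_nll(config, trials, alpha, eta, beta, w):
    learner = OracleLearner(config, alpha, eta, beta, w)
    nll = 0.0
    for t in trials:
        p1, p2 = learner.process(t)
        nll -= math.log(p1) + math.log(p2)
    return nll


@pytest.fixture(scope="session")
def oracle():
    return oracle_nll


def random_trials(config, n, rng):
    """Fuzzed but structurally valid trial logs (uniform random choices)."""
    from twostep.task_env import simulate_episode

    uniform = {
        s: {"left": 0.5, "right": 0.5} for s in config.nonterminal_states
    }
    return [simulate_episode(config, uniform, rng, i + 1) for i in range(n)]


@pytest.fixture(scope="session")
def make_random_trials():
    return random_trials
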