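"""Learner equations: SARSA, FORWARD, HYBRID, softmax, trial processing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostep.learners import (
    LearnerParams,
    LearnerState,
    act_episode,
    forward_transition_update,
    forward_values,
    hybrid_values,
    process_trial,
    sarsa_update,
    softmax_probs,
)
from twostep.task_env import ACTIONS, ground_truth_values

PARAMS = LearnerParams(alpha=0.5, eta=0.2, beta=5.0, w=0.5)


def fresh(canonical, **kw):
    base = dict(alpha=0.5, eta=0.2, beta=5.0, w=0.5)
    base.update(kw)
    return LearnerState.fresh(canonical, LearnerParams(**base))


# -- SARSA -------------------------------------------------------------------


def test_sarsa_terminal_update(canonical):
    state = fresh(canonical, alpha=0.5)
    new, delta = sarsa_update(state, "R1", "left", 1.0, None, None)
    assert delta == pytest.approx(1.0)
    assert new.q_sarsa_table()[("R1", "left")] == pytest.approx(0.5)
    # only the touched entry changed
    changed = {
        k for k in new.q_sarsa_table()
        if new.q_sarsa_table()[k] != state.q_sarsa_table()[k]
    }
    assert changed == {("R1", "left")}


def test_sarsa_zero_learning_rate(canonical):
    state = fresh(canonical, alpha=0.0)
    new, delta = sarsa_update(state, "R1", "left", 1.0, None, None)
    assert delta == pytest.approx(1.0)
    assert new.q_sarsa_table() == state.q_sarsa_table()


def test_sarsa_converges_geometrically(canonical):
    state = fresh(canonical, alpha=0.3)
    for k in range(1, 60):
        state, _ = sarsa_update(state, "L1", "right", 0.4, None, None)
        expected = 0.4 * (1 - (1 - 0.3) ** k)
        assert state.q_sarsa_table()[("L1", "right")] == pytest.approx(expected)
    assert state.q_sarsa_table()[("L1", "right")] == pytest.approx(0.4, abs=1e-6)


def test_sarsa_bootstrap_uses_next_pair(canonical):
    state = fresh(canonical, alpha=1.0)
    state, _ = sarsa_update(state, "R1", "left", 1.0, None, None)  # Q(R1,left)=1
    new, delta = sarsa_update(state, "S0", "right", 0.0, "R1", "left")
    assert delta == pytest.approx(1.0)  # 0 + gamma*1 - 0
    assert new.q_sarsa_table()[("S0", "right")] == pytest.approx(1.0)


# -- FORWARD -----------------------------------------------------------------


def test_forward_update_example(canonical):
    state = fresh(canonical, eta=0.2)
    first = canonical.successors("S0", "left")[0][0]
    new, spe = forward_transition_update(state, "S0", "left", first)
    assert spe == pytest.approx(0.5)
    assert new.t_hat("S0", "left", first) == pytest.approx(0.6)
    other = canonical.successors("S0", "left")[1][0]
    assert new.t_hat("S0", "left", other) == pytest.approx(0.4)


def test_forward_update_full_learning_rate(canonical):
    state = fresh(canonical, eta=1.0)
    new, _ = forward_transition_update(state, "R1", "right", "O25")
    assert new.t_hat("R1", "right", "O25") == pytest.approx(1.0)
    assert new.t_hat("R1", "right", "O0") == pytest.approx(0.0)


def test_forward_update_illegal_successor(canonical):
    with pytest.raises(ValueError, match="successor"):
        forward_transition_update(fresh(canonical), "S0", "left", "O25")


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 1), st.integers(0, 1),
                          st.floats(0.05, 0.95)), min_size=1, max_size=60))
def test_t_hat_rows_remain_stochastic(updates):
    from twostep.task_env import build_canonical_task

    canonical = build_canonical_task()
    state = fresh(canonical)
    states = canonical.nonterminal_states
    for si, ai, slot, eta in updates:
        state.params = LearnerParams(alpha=0.5, eta=eta, beta=5.0, w=0.5)
        s = states[si]
        a = ACTIONS[ai]
        observed = canonical.successors(s, a)[slot][0]
        state, _ = forward_transition_update(state, s, a, observed)
    table = state.t_hat_table()
    for s in states:
        for a in ACTIONS:
            row = [table[(s, a, nxt)] for nxt, _ in canonical.successors(s, a)]
            assert abs(sum(row) - 1.0) < 1e-9
            assert all(0.0 <= t <= 1.0 for t in row)


def test_forward_values_with_true_transitions_match_ground_truth(canonical):
    state = fresh(canonical)
    # plant the true transition table
    for si, s in enumerate(state.task.states):
        for ai, a in enumerate(ACTIONS):
            state.t_first[si][ai] = canonical.successors(s, a)[0][1]
    q = forward_values(state)
    truth = ground_truth_values(canonical, units="scaled")
    for k in truth:
        assert q[k] == pytest.approx(truth[k], abs=1e-12)
    assert q[("R1", "left")] == pytest.approx(0.7)


def test_forward_values_uniform_transitions(canonical):
    q = forward_values(fresh(canonical))
    assert q[("R1", "left")] == pytest.approx(0.5)  # 0.5*1 + 0.5*0


# -- HYBRID and softmax -------------------------------------------------------


def test_hybrid_endpoints_and_midpoint():
    q_f = {("S0", "left"): 0.7}
    q_s = {("S0", "left"): 0.3}
    assert hybrid_values(q_f, q_s, 0.0)[("S0", "left")] == 0.3
    assert hybrid_values(q_f, q_s, 1.0)[("S0", "left")] == 0.7
    assert hybrid_values(q_f, q_s, 0.5)[("S0", "left")] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        hybrid_values(q_f, q_s, 1.2)


@settings(max_examples=50, derandomize=True)
@given(
    st.floats(0, 1), st.floats(-1, 1), st.floats(-1, 1)
)
def test_hybrid_is_convex_combination(w, qf, qs):
    out = hybrid_values({"k": qf}, {"k": qs}, w)["k"]
    assert min(qf, qs) - 1e-12 <= out <= max(qf, qs) + 1e-12


def test_softmax_symmetry_and_closed_form():
    assert softmax_probs([0.4, 0.4], 3.0) == pytest.approx([0.5, 0.5])
    assert softmax_probs([0.9, 0.1], 0.0) == pytest.approx([0.5, 0.5])
    p = softmax_probs([0.7, 0.3], 5.0)
    assert p[0] == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), abs=1e-10)
    assert p[0] == pytest.approx(0.88080, abs=1e-5)


@settings(max_examples=40, derandomize=True)
@given(st.floats(0.05, 0.95), st.floats(-0.9, 0.9))
def test_softmax_monotone_in_beta(qa, gap):
    qb = qa - abs(gap)
    betas = [0.0, 1.0, 3.0, 7.0, 10.0]
    probs = [softmax_probs([qa, qb], b)[0] for b in betas]
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


# -- trial processing ---------------------------------------------------------


def test_fresh_state_emits_half_probabilities(canonical, rng, make_random_trials):
    trial = make_random_trials(canonical, 1, rng)[0]
    for beta in (0.5, 3.0, 9.0):
        _, (p1, p2) = process_trial(fresh(canonical, beta=beta), trial)
        assert p1 == pytest.approx(0.5)
        assert p2 == pytest.approx(0.5)


def test_zero_learning_rates_freeze_probabilities(canonical, rng, make_random_trials):
    """With alpha=eta=0 nothing is learned: the transition estimates stay
    uniform and SARSA values stay zero, so from the first FORWARD value
    sweep onward every state's emitted probabilities are constant."""
    state = fresh(canonical, alpha=0.0, eta=0.0)
    seen: dict[tuple[str, str, str, str], tuple[float, float]] = {}
    trials = make_random_trials(canonical, 60, rng)
    state, _ = process_trial(state, trials[0])  # initial zeros -> swept values
    frozen_t = state.t_hat_table()
    frozen_q = state.q_sarsa_table()
    for trial in trials[1:]:
        state, probs = process_trial(state, trial)
        key = (trial.a1, trial.s2, trial.a2, trial.s3)
        if key in seen:
            assert probs == pytest.approx(seen[key], abs=1e-15)
        seen[key] = probs
    assert state.t_hat_table() == frozen_t
    assert state.q_sarsa_table() == frozen_q


def test_process_trial_matches_oracle_stepwise(canonical, rng, oracle,
                                               make_random_trials):
    """Trial-by-trial choice probabilities equal the straight-line oracle."""
    from tests.conftest import OracleLearner

    trials = make_random_trials(canonical, 20, rng)
    state = fresh(canonical, alpha=0.5, eta=0.2, beta=5.0, w=0.5)
    ref = OracleLearner(canonical, 0.5, 0.2, 5.0, 0.5)
    for trial in trials:
        state, (p1, p2) = process_trial(state, trial)
        q1, q2 = ref.process(trial)
        assert p1 == pytest.approx(q1, abs=1e-12)
        assert p2 == pytest.approx(q2, abs=1e-12)


def test_w_zero_trajectory_equals_pure_sarsa(canonical, rng, make_random_trials):
    """With w=0 choices depend only on SARSA values: perturbing the
    transition model post hoc leaves emitted probabilities unchanged."""
    trials = make_random_trials(canonical, 40, rng)
    state_a = fresh(canonical, w=0.0)
    state_b = fresh(canonical, w=0.0, eta=0.9)  # very different forward model
    for trial in trials:
        state_a, pa = process_trial(state_a, trial)
        state_b, pb = process_trial(state_b, trial)
        assert pa == pytest.approx(pb, abs=1e-12)
    # SARSA values still updated silently under w=1
    state_c = fresh(canonical, w=1.0)
    for trial in trials:
        state_c, _ = process_trial(state_c, trial)
    assert any(v != 0.0 for v in state_c.q_sarsa_table().values())


def test_act_episode_deterministic_and_symmetric_start(canonical):
    t1, _ = act_episode(fresh(canonical), rng=np.random.default_rng(7))
    t2, _ = act_episode(fresh(canonical), rng=np.random.default_rng(7))
    assert t1 == t2
    rng = np.random.default_rng(11)
    rights = sum(
        act_episode(fresh(canonical), rng=rng)[0].a1 == "right" for _ in range(4000)
    )
    assert abs(rights / 4000 - 0.5) < 0.03


def test_act_episode_argmax_limit(canonical):
    """With a large value gap and sharp softmax the better action dominates."""
    state = fresh(canonical, beta=10.0, w=0.0)
    si = state.task.state_index["S0"]
    state.q_sarsa[si][1] = 1.0  # right much better
    rng = np.random.default_rng(3)
    rights = sum(
        act_episode(state.copy(), rng=rng)[0].a1 == "right" for _ in range(500)
    )
    assert rights / 500 > 0.99


def test_learner_params_bounds():
    with pytest.raises(ValueError):
        LearnerParams(alpha=1.5, eta=0.5, beta=5.0, w=0.5)
    with pytest.raises(ValueError):
        LearnerParams(alpha=0.5, eta=0.5, beta=11.0, w=0.5)
    with pytest.raises(ValueError):
        LearnerParams(alpha=0.5, eta=0.5, beta=5.0, w=0.5, gamma=0.9)
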