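"""Sequential two-choice Markov decision task environment.

The task is a two-layer probabilistic decision tree: from a fixed start
state the agent chooses left or right, transitions to one of two stage-2
states (70% common / 30% rare), chooses again, and lands in an outcome
state paying 0, 10 or 25 yen.  For model fitting the rewards are rescaled
to the unitless values {0, 0.4, 1}.

This module owns the task layout (:class:`TaskConfig`), transition
sampling, exact optimal state-action values by backward induction, and the
trial-log CSV dialect shared by the whole package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ACTIONS = ("left", "right")

TRIAL_LOG_COLUMNS = [
    "participant_id", "trial", "a1", "s2", "transition",
    "a2", "s3", "reward_yen", "rt1_ms", "rt2_ms",
]


class TaskStructureError(ValueError):
    """Raised when a task layout violates the two-stage tree structure."""


@dataclass(frozen=True)
class TaskConfig:
    """Full state/action/transition/reward layout of the two-stage task.

    ``transitions`` maps ``(state, action)`` to a tuple of
    ``(next_state, probability)`` pairs; every pair must have exactly two
    successors whose probabilities sum to one.  ``reward_scaled`` maps each
    yen amount onto the unitless reward used by the learning models.
    """

    start_state: str
    stage2_states: tuple[str, ...]
    outcome_states: tuple[str, ...]
    transitions: Mapping[tuple[str, str], tuple[tuple[str, float], ...]]
    reward_yen: Mapping[str, float]
    reward_scaled: Mapping[float, float]
    n_trials: int = 200

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def nonterminal_states(self) -> tuple[str, ...]:
        return (self.start_state, *self.stage2_states)

    def successors(self, state: str, action: str) -> tuple[tuple[str, float], ...]:
        try:
            return self.transitions[(state, action)]
        except KeyError:
            raise TaskStructureError(
                f"no transition defined for state {state!r}, action {action!r}"
            ) from None

    def common_successor(self, state: str, action: str) -> str:
        """Successor with the largest transition probability (ties: first listed)."""
        succ = self.successors(state, action)
        return max(succ, key=lambda sp: sp[1])[0]

    def transition_type(self, state: str, action: str, next_state: str) -> str:
        if next_state not in [s for s, _ in self.successors(state, action)]:
            raise TaskStructureError(
                f"{next_state!r} is not a successor of ({state!r}, {action!r})"
            )
        return "common" if next_state == self.common_successor(state, action) else "rare"

    def scaled_reward(self, outcome_state: str) -> float:
        return self.reward_scaled[self.reward_yen[outcome_state]]

    def validate(self) -> None:
        for s in self.nonterminal_states:
            for a in ACTIONS:
                succ = self.successors(s, a)
                if len(succ) != 2:
                    raise TaskStructureError(
                        f"({s!r}, {a!r}) must have exactly two successors, got {len(succ)}"
                    )
                total = sum(p for _, p in succ)
                if abs(total - 1.0) > 1e-12:
                    raise TaskStructureError(
                        f"({s!r}, {a!r}) transition probabilities sum to {total}, not 1"
                    )
                if any(p < 0 for _, p in succ):
                    raise TaskStructureError(f"({s!r}, {a!r}) has a negative probability")
        for s, a in self.transitions:
            if s not in self.nonterminal_states:
                raise TaskStructureError(f"transition from unknown state {s!r}")
        # stage wiring: start -> stage2 -> outcome
        for a in ACTIONS:
            for nxt, _ in self.successors(self.start_state, a):
                if nxt not in self.stage2_states:
                    raise TaskStructureError(
                        f"start-state successor {nxt!r} is not a stage-2 state"
                    )
        for s in self.stage2_states:
            for a in ACTIONS:
                for nxt, _ in self.successors(s, a):
                    if nxt not in self.outcome_states:
                        raise TaskStructureError(
                            f"stage-2 successor {nxt!r} is not an outcome state"
                        )
        for o in self.outcome_states:
            if o not in self.reward_yen:
                raise TaskStructureError(f"outcome state {o!r} has no yen reward")
            if self.reward_yen[o] not in self.reward_scaled:
                raise TaskStructureError(
                    f"yen amount {self.reward_yen[o]!r} has no scaled reward"
                )


@dataclass
class TrialRecord:
    """One trial of the task: states, actions, reward and reaction times."""

    trial_index: int
    s1: str
    a1: str
    s2: str
    transition_type: str
    a2: str
    s3: str
    reward_yen: float
    rt1_ms: float | None = None
    rt2_ms: float | None = None

    def validate(self, config: TaskConfig) -> None:
        if self.s1 != config.start_state:
            raise TaskStructureError(f"trial starts in {self.s1!r}, not the start state")
        if self.s2 not in [s for s, _ in config.successors(self.s1, self.a1)]:
            raise TaskStructureError(
                f"trial {self.trial_index}: {self.s2!r} not reachable from "
                f"({self.s1!r}, {self.a1!r})"
            )
        if self.s3 not in [s for s, _ in config.successors(self.s2, self.a2)]:
            raise TaskStructureError(
                f"trial {self.trial_index}: {self.s3!r} not reachable from "
                f"({self.s2!r}, {self.a2!r})"
            )
        expected = config.transition_type(self.s1, self.a1, self.s2)
        if self.transition_type != expected:
            raise TaskStructureError(
                f"trial {self.trial_index}: transition_type {self.transition_type!r} "
                f"should be {expected!r}"
            )
        if self.reward_yen != config.reward_yen[self.s3]:
            raise TaskStructureError(
                f"trial {self.trial_index}: reward {self.reward_yen!r} does not match "
                f"outcome {self.s3!r}"
            )


# -- config I/O ------------------------------------------------------------


def _config_from_dict(d: dict) -> TaskConfig:
    transitions = {
        (state, action): tuple((nxt, float(p)) for nxt, p in pairs)
        for state, by_action in d["transitions"].items()
        for action, pairs in by_action.items()
    }
    return TaskConfig(
        start_state=d["start_state"],
        stage2_states=tuple(d["stage2_states"]),
        outcome_states=tuple(d["outcome_states"]),
        transitions=transitions,
        reward_yen={k: float(v) for k, v in d["reward_yen"].items()},
        reward_scaled={float(k): float(v) for k, v in d["reward_scaled"].items()},
        n_trials=int(d.get("n_trials", 200)),
    )


def config_to_dict(config: TaskConfig) -> dict:
    by_state: dict[str, dict[str, list]] = {}
    for (s, a), pairs in config.transitions.items():
        by_state.setdefault(s, {})[a] = [[nxt, p] for nxt, p in pairs]
    return {
        "start_state": config.start_state,
        "stage2_states": list(config.stage2_states),
        "outcome_states": list(config.outcome_states),
        "transitions": by_state,
        "reward_yen": dict(config.reward_yen),
        "reward_scaled": dict(config.reward_scaled),
        "n_trials": config.n_trials,
    }


def load_task_config(path: str | Path) -> TaskConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def save_task_config(config: TaskConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def build_canonical_task() -> TaskConfig:
    """The canonical 70/30, {0,10,25}-yen task layout shipped with the package."""
    text = resources.files("twostep.data").joinpath("canonical_task.yaml").read_text()
    return _config_from_dict(yaml.safe_load(text))


# -- dynamics --------------------------------------------------------------


def sample_transition(
    config: TaskConfig, state: str, action: str, rng: np.random.Generator
) -> str:
    """Sample one successor of ``(state, action)`` from the transition table."""
    succ = config.successors(state, action)
    u = rng.random()
    acc = 0.0
    for nxt, p in succ:
        acc += p
        if u < acc:
            return nxt
    return succ[-1][0]


def ground_truth_values(config: TaskConfig, units: str = "yen") -> dict[tuple[str, str], float]:
    """Optimal Q*(state, action) by backward induction over the two-stage tree.

    ``units`` selects the yen rewards or the rescaled {0, 0.4, 1} rewards; the
    two tables are related by applying the reward map before induction.
    """
    if units not in ("yen", "scaled"):
        raise ValueError(f"units must be 'yen' or 'scaled', got {units!r}")

    def reward(outcome: str) -> float:
        r = config.reward_yen[outcome]
        return config.reward_scaled[r] if units == "scaled" else r

    q: dict[tuple[str, str], float] = {}
    for s in config.stage2_states:
        for a in ACTIONS:
            q[(s, a)] = sum(p * reward(nxt) for nxt, p in config.successors(s, a))
    v2 = {s: max(q[(s, a)] for a in ACTIONS) for s in config.stage2_states}
    for a in ACTIONS:
        q[(config.start_state, a)] = sum(
            p * v2[nxt] for nxt, p in config.successors(config.start_state, a)
        )
    return q


PolicyLike = Callable[[str], Mapping[str, float]] | Mapping[str, Mapping[str, float]]


def _policy_dist(policy: PolicyLike, state: str) -> Mapping[str, float]:
    dist = policy(state) if callable(policy) else policy[state]
    total = sum(dist.get(a, 0.0) for a in ACTIONS)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"policy probabilities at {state!r} sum to {total}, not 1")
    return dist


def _sample_action(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    return "left" if rng.random() < dist.get("left", 0.0) else "right"


def simulate_episode(
    config: TaskConfig,
    policy: PolicyLike,
    rng: np.random.Generator,
    trial_index: int = 1,
) -> TrialRecord:
    """Roll one trial of the task under an arbitrary stochastic policy."""
    s1 = config.start_state
    a1 = _sample_action(_policy_dist(policy, s1), rng)
    s2 = sample_transition(config, s1, a1, rng)
    a2 = _sample_action(_policy_dist(policy, s2), rng)
    s3 = sample_transition(config, s2, a2, rng)
    return TrialRecord(
        trial_index=trial_index,
        s1=s1,
        a1=a1,
        s2=s2,
        transition_type=config.transition_type(s1, a1, s2),
        a2=a2,
        s3=s3,
        reward_yen=config.reward_yen[s3],
    )


# -- compiled index used by the learners -----------------------------------


@dataclass(frozen=True)
class CompiledTask:
    """Integer-indexed view of a :class:`TaskConfig` for the trial-loop kernels.

    Non-terminal states are ordered ``[start, *stage2]``.  For each
    (state, action) the two successors keep their listed order; ``p_first``
    is the probability of slot 0.  Stage-2 rows carry the successors'
    scaled and yen rewards per slot.
    """

    config: TaskConfig
    states: tuple[str, ...]
    state_index: Mapping[str, int]
    succ_idx: tuple  # succ_idx[si][a] -> (idx, idx) into states, stage-1 row only
    succ_name: tuple  # succ_name[si][a] -> (name, name) for all rows
    p_first: tuple  # p_first[si][a] -> float
    common_slot: tuple  # common_slot[si][a] -> 0 or 1
    r_scaled: tuple  # r_scaled[si][a] -> (float, float), stage-2 rows only
    r_yen: tuple

    @property
    def n_states(self) -> int:
        return len(self.states)


def compile_task(config: TaskConfig) -> CompiledTask:
    states = config.nonterminal_states
    index = {s: i for i, s in enumerate(states)}
    succ_idx, succ_name, p_first, common_slot, r_scaled, r_yen = [], [], [], [], [], []
    for si, s in enumerate(states):
        row_idx, row_name, row_p, row_c, row_rs, row_ry = [], [], [], [], [], []
        for a in ACTIONS:
            succ = config.successors(s, a)
            names = tuple(nxt for nxt, _ in succ)
            row_name.append(names)
            row_p.append(succ[0][1])
            row_c.append(0 if succ[0][1] >= succ[1][1] else 1)
            if si == 0:
                row_idx.append(tuple(index[n] for n in names))
                row_rs.append((0.0, 0.0))
                row_ry.append((0.0, 0.0))
            else:
                row_idx.append((-1, -1))
                row_rs.append(tuple(config.scaled_reward(n) for n in names))
                row_ry.append(tuple(config.reward_yen[n] for n in names))
        succ_idx.append(tuple(row_idx))
        succ_name.append(tuple(row_name))
        p_first.append(tuple(row_p))
        common_slot.append(tuple(row_c))
        r_scaled.append(tuple(row_rs))
        r_yen.append(tuple(row_ry))
    return CompiledTask(
        config=config,
        states=states,
        state_index=index,
        succ_idx=tuple(succ_idx),
        succ_name=tuple(succ_name),
        p_first=tuple(p_first),
        common_slot=tuple(common_slot),
        r_scaled=tuple(r_scaled),
        r_yen=tuple(r_yen),
    )


# -- trial-log CSV dialect -------------------------------------------------


def trials_to_frame(
    trials: Sequence[TrialRecord], participant_id: str | int
) -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "trial": t.trial_index,
            "a1": t.a1,
            "s2": t.s2,
            "transition": t.transition_type,
            "a2": t.a2,
            "s3": t.s3,
            "reward_yen": t.reward_yen,
            "rt1_ms": t.rt1_ms,
            "rt2_ms": t.rt2_ms,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def frame_to_trials(
    df: pd.DataFrame, config: TaskConfig, validate: bool = True
) -> list[TrialRecord]:
    trials = []
    for pos, row in enumerate(df.itertuples(index=False)):
        if row.transition not in ("common", "rare"):
            raise ValueError(
                f"row {pos}: malformed transition label {row.transition!r}"
            )
        rec = TrialRecord(
            trial_index=int(row.trial),
            s1=config.start_state,
            a1=str(row.a1),
            s2=str(row.s2),
            transition_type=str(row.transition),
            a2=str(row.a2),
            s3=str(row.s3),
            reward_yen=float(row.reward_yen),
            rt1_ms=None if pd.isna(row.rt1_ms) else float(row.rt1_ms),
            rt2_ms=None if pd.isna(row.rt2_ms) else float(row.rt2_ms),
        )
        if validate:
            try:
                rec.validate(config)
            except TaskStructureError as exc:
                raise TaskStructureError(f"row {pos}: {exc}") from None
        trials.append(rec)
    return trials


def write_trial_log(
    path: str | Path, cohort: Mapping[str | int, Sequence[TrialRecord]]
) -> None:
    frames = [trials_to_frame(trials, pid) for pid, trials in cohort.items()]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRIAL_LOG_COLUMNS)
    )
    # %.17g preserves float64 values exactly across the CSV round trip
    out.to_csv(path, index=False, float_format="%.17g")


def read_trial_log(
    path: str | Path, config: TaskConfig
) -> dict[str, list[TrialRecord]]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} missing columns: {missing}")
    return {
        str(pid): frame_to_trials(grp.sort_values("trial"), config)
        for pid, grp in df.groupby("participant_id", sort=True)
    }
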