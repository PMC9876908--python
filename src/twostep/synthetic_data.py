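"""Synthetic cohort generator: trial logs, reaction times, SVO responses.

Produces complete participant datasets with the statistical structure the
analysis pipeline assumes, so every stage is testable without any
download.  Each synthetic participant is a HYBRID agent with per-block
parameters sampled from group-specific truncated normals.  Group defaults
are anchored to whole-session estimates from the study population
(proself: alpha 0.34, eta 0.49, beta 5.21, w 0.49; prosocial: alpha 0.33,
eta 0.48, beta 4.58, w 0.40), with the qualitative within-session pattern
of a decreasing alpha, an increasing beta, and a first-block w elevation
for the proself group.

Reaction times follow an invented generative model (the study treats RTs
only statistically): RT1 decays with practice toward an asymptote, and RT2
increases with the learner's transition surprise 1 - T(S0, a1, s2), which
reproduces the qualitative late-session ordering RT1 < RT2-common <
RT2-rare.  SVO angles are drawn from bimodal group clusters and converted
to slider allocations by coordinate descent on the item menu.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .learners import LearnerParams, LearnerState, process_trial, softmax_probs
from .svo import SliderResponse, load_item_table, svo_angle
from .task_env import (
    TaskConfig,
    TrialRecord,
    compile_task,
    read_trial_log,
    sample_transition,
    write_trial_log,
)
from . import svo as _svo


@dataclass(frozen=True)
class ParamDistribution:
    """Per-block truncated-normal means/SDs for one group's (alpha, eta, beta, w)."""

    alpha_mean: tuple[float, ...]
    eta_mean: tuple[float, ...]
    beta_mean: tuple[float, ...]
    w_mean: tuple[float, ...]
    alpha_sd: float = 0.06
    eta_sd: float = 0.06
    beta_sd: float = 0.6
    w_sd: float = 0.10


# Whole-session anchors 0.34/0.49/5.21/0.49 (proself) and 0.33/0.48/4.58/0.40
# (prosocial), spread over blocks with decreasing alpha, increasing beta and
# an elevated proself first-block w.
PROSELF_DEFAULTS = ParamDistribution(
    alpha_mean=(0.45, 0.38, 0.32, 0.29, 0.26),
    eta_mean=(0.49, 0.49, 0.49, 0.49, 0.49),
    beta_mean=(4.0, 4.8, 5.4, 5.8, 6.0),
    w_mean=(0.80, 0.52, 0.45, 0.40, 0.36),
)
PROSOCIAL_DEFAULTS = ParamDistribution(
    alpha_mean=(0.44, 0.37, 0.31, 0.28, 0.25),
    eta_mean=(0.48, 0.48, 0.48, 0.48, 0.48),
    beta_mean=(3.4, 4.2, 4.8, 5.2, 5.4),
    w_mean=(0.45, 0.44, 0.41, 0.38, 0.35),
)


@dataclass(frozen=True)
class RtModel:
    """Generative reaction-time model (milliseconds).

    RT1 decays from ``rt1_start`` toward ``rt1_asym`` with time constant
    ``rt1_tau`` trials; RT2 is ``rt2_base`` plus ``rt2_surprise_coef``
    times the transition surprise.  Gaussian noise, truncated to
    [150, 2000] ms.
    """

    rt1_start: float = 700.0
    rt1_asym: float = 485.0
    rt1_tau: float = 50.0
    rt1_sd: float = 80.0
    rt2_base: float = 500.0
    rt2_surprise_coef: float = 330.0
    rt2_sd: float = 100.0
    floor_ms: float = 150.0
    cap_ms: float = 2000.0


@dataclass(frozen=True)
class SvoAngleDistribution:
    """Truncated-normal angle clusters per group (degrees)."""

    proself_mean: float = 2.5
    proself_sd: float = 4.0
    proself_range: tuple[float, float] = (-16.0, 6.5)
    prosocial_mean: float = 45.0
    prosocial_sd: float = 6.0
    prosocial_range: tuple[float, float] = (39.0, 61.0)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_proself: int = 40
    n_prosocial: int = 40
    proself_params: ParamDistribution = PROSELF_DEFAULTS
    prosocial_params: ParamDistribution = PROSOCIAL_DEFAULTS
    rt_model: RtModel = RtModel()
    svo_angles: SvoAngleDistribution = SvoAngleDistribution()
    n_trials: int = 200
    block_size: int = 40
    seed: int = 0


@dataclass
class ParticipantDataset:
    """Synthetic twin of one deposited participant record."""

    participant_id: str
    group_label: str
    svo_responses: list[SliderResponse]
    trials: list[TrialRecord]
    true_params: list[LearnerParams]  # one per block
    svo_angle_deg: float | None = None


def _trunc_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Rejection-sampled truncated normal (narrow tails; cheap at these widths)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def sample_block_params(
    dist: ParamDistribution, rng: np.random.Generator
) -> list[LearnerParams]:
    n_blocks = len(dist.w_mean)
    out = []
    for k in range(n_blocks):
        out.append(
            LearnerParams(
                alpha=_trunc_normal(dist.alpha_mean[k], dist.alpha_sd, 0.02, 0.98, rng),
                eta=_trunc_normal(dist.eta_mean[k], dist.eta_sd, 0.02, 0.98, rng),
                beta=_trunc_normal(dist.beta_mean[k], dist.beta_sd, 0.05, 9.95, rng),
                w=_trunc_normal(dist.w_mean[k], dist.w_sd, 0.02, 0.98, rng),
            )
        )
    return out


def generate_rts(
    transition_type: str,
    trial_index: int,
    surprise: float,
    rt_model: RtModel,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Sample (rt1_ms, rt2_ms) for one trial.

    ``surprise`` is 1 minus the learner's estimated probability of the
    observed stage-1 transition, evaluated before the trial's update.
    """
    if not (0.0 <= surprise <= 1.0):
        raise ValueError(f"surprise {surprise} outside [0,1]")
    m = rt_model
    rt1 = (
        m.rt1_asym
        + (m.rt1_start - m.rt1_asym) * math.exp(-(trial_index - 1) / m.rt1_tau)
        + rng.normal(0.0, m.rt1_sd)
    )
    rt2 = m.rt2_base + m.rt2_surprise_coef * surprise + rng.normal(0.0, m.rt2_sd)
    clip = lambda x: float(min(max(x, m.floor_ms), m.cap_ms))
    return clip(rt1), clip(rt2)


def generate_svo_responses(
    target_angle: float,
    item_table: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    tolerance: float = 1.0,
) -> list[SliderResponse]:
    """Slider allocations whose SVO angle lands within ``tolerance`` degrees
    of the target, found by coordinate descent over the item options."""
    if item_table is None:
        item_table = load_item_table()
    items = {
        int(iid): list(grp[["self_payoff", "other_payoff"]].itertuples(index=False, name=None))
        for iid, grp in item_table.groupby("item_id")
    }
    ids = sorted(items)

    def angle_of(ch: dict) -> float:
        ms = sum(v[0] for v in ch.values()) / len(ch)
        mo = sum(v[1] for v in ch.values()) / len(ch)
        return math.degrees(math.atan2(mo - 50.0, ms - 50.0))

    def descend(choice: dict) -> dict:
        for _ in range(8):  # coordinate-descent passes
            improved = False
            for iid in ids:
                current = abs(angle_of(choice) - target_angle)
                for opt in items[iid]:
                    trial = dict(choice)
                    trial[iid] = opt
                    if abs(angle_of(trial) - target_angle) < current - 1e-12:
                        choice[iid] = opt
                        current = abs(angle_of(trial) - target_angle)
                        improved = True
            if not improved:
                break
        return choice

    # greedy start: per-item option whose own angle best matches the target;
    # a few deterministic random restarts escape local optima
    start = {
        iid: min(
            items[iid],
            key=lambda so: abs(
                math.degrees(math.atan2(so[1] - 50.0, so[0] - 50.0)) - target_angle
            ),
        )
        for iid in ids
    }
    local = np.random.default_rng(abs(int(round(target_angle * 1000))) + 7)
    best = descend(dict(start))
    for _ in range(6):
        if abs(angle_of(best) - target_angle) <= tolerance:
            break
        candidate = {
            iid: items[iid][int(local.integers(len(items[iid])))] for iid in ids
        }
        candidate = descend(candidate)
        if abs(angle_of(candidate) - target_angle) < abs(angle_of(best) - target_angle):
            best = candidate
    achieved = angle_of(best)
    if abs(achieved - target_angle) > tolerance:
        raise ValueError(
            f"target angle {target_angle:.2f} deg unattainable on the item menu "
            f"(best {achieved:.2f})"
        )
    return [
        SliderResponse(item_id=iid, self_payoff=float(best[iid][0]),
                       other_payoff=float(best[iid][1]))
        for iid in ids
    ]


def _generate_trials(
    config: TaskConfig,
    params_per_block: Sequence[LearnerParams],
    block_size: int,
    n_trials: int,
    rt_model: RtModel,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    task = compile_task(config)
    state = LearnerState.fresh(task, params_per_block[0])
    trials = []
    for i in range(1, n_trials + 1):
        block = min((i - 1) // block_size, len(params_per_block) - 1)
        state.params = params_per_block[block]
        p = state.params
        hyb1 = {
            a: p.w * state.q_fwd_table()[(config.start_state, a)]
            + (1 - p.w) * state.q_sarsa_table()[(config.start_state, a)]
            for a in ("left", "right")
        }
        probs1 = softmax_probs(hyb1, p.beta)
        a1 = "right" if rng.random() < probs1["right"] else "left"
        s2 = sample_transition(config, config.start_state, a1, rng)
        surprise = 1.0 - state.t_hat(config.start_state, a1, s2)
        hyb2 = {
            a: p.w * state.q_fwd_table()[(s2, a)]
            + (1 - p.w) * state.q_sarsa_table()[(s2, a)]
            for a in ("left", "right")
        }
        probs2 = softmax_probs(hyb2, p.beta)
        a2 = "right" if rng.random() < probs2["right"] else "left"
        s3 = sample_transition(config, s2, a2, rng)
        transition = config.transition_type(config.start_state, a1, s2)
        rt1, rt2 = generate_rts(transition, i, surprise, rt_model, rng)
        trial = TrialRecord(
            trial_index=i,
            s1=config.start_state,
            a1=a1,
            s2=s2,
            transition_type=transition,
            a2=a2,
            s3=s3,
            reward_yen=config.reward_yen[s3],
            rt1_ms=rt1,
            rt2_ms=rt2,
        )
        state, _ = process_trial(state, trial)
        trials.append(trial)
    return trials


def generate_participant(
    participant_id: str,
    group_label: str,
    spec: SyntheticCohortSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    item_table: pd.DataFrame | None = None,
) -> ParticipantDataset:
    dist = spec.proself_params if group_label == "proself" else spec.prosocial_params
    ang = spec.svo_angles
    if group_label == "proself":
        target = _trunc_normal(ang.proself_mean, ang.proself_sd, *ang.proself_range, rng)
    else:
        target = _trunc_normal(
            ang.prosocial_mean, ang.prosocial_sd, *ang.prosocial_range, rng
        )
    params = sample_block_params(dist, rng)
    trials = _generate_trials(
        config, params, spec.block_size, spec.n_trials, spec.rt_model, rng
    )
    responses = generate_svo_responses(target, item_table, rng)
    return ParticipantDataset(
        participant_id=participant_id,
        group_label=group_label,
        svo_responses=responses,
        trials=trials,
        true_params=params,
        svo_angle_deg=svo_angle(responses, item_table, validate=False),
    )


def generate_cohort(
    spec: SyntheticCohortSpec, config: TaskConfig, seed: int | None = None
) -> list[ParticipantDataset]:
    """Full synthetic cohort: one independent random stream per participant."""
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    n_total = spec.n_proself + spec.n_prosocial
    streams = root.spawn(n_total) if n_total else []
    item_table = load_item_table()
    cohort = []
    labels = ["proself"] * spec.n_proself + ["prosocial"] * spec.n_prosocial
    for idx, (label, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        cohort.append(
            generate_participant(f"S{idx + 1:03d}", label, spec, config, rng, item_table)
        )
    return cohort


# -- file round-trip -------------------------------------------------------


def write_dataset(cohort: Sequence[ParticipantDataset], out_dir: str | Path) -> None:
    """Write trials.csv, svo.csv and truth.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trial_log(out / "trials.csv", {d.participant_id: d.trials for d in cohort})
    _svo.responses_to_frame(
        {d.participant_id: d.svo_responses for d in cohort}
    ).to_csv(out / "svo.csv", index=False)
    truth = {
        d.participant_id: {
            "group_label": d.group_label,
            "svo_angle_deg": d.svo_angle_deg,
            "true_params": [
                {"alpha": p.alpha, "eta": p.eta, "beta": p.beta, "w": p.w}
                for p in d.true_params
            ],
        }
        for d in cohort
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def read_dataset(in_dir: str | Path, config: TaskConfig) -> list[ParticipantDataset]:
    """Inverse of :func:`write_dataset`; field-for-field round trip."""
    src = Path(in_dir)
    trials = read_trial_log(src / "trials.csv", config)
    responses = _svo.read_responses(src / "svo.csv")
    truth = json.loads((src / "truth.json").read_text())
    cohort = []
    for pid in sorted(trials):
        info = truth[pid]
        cohort.append(
            ParticipantDataset(
                participant_id=pid,
                group_label=info["group_label"],
                svo_responses=responses.get(pid, []),
                trials=trials[pid],
                true_params=[LearnerParams(**p) for p in info["true_params"]],
                svo_angle_deg=info.get("svo_angle_deg"),
            )
        )
    return cohort


def adapt_trial_log(
    df: pd.DataFrame, column_map: dict[str, str], config: TaskConfig
) -> dict[str, list[TrialRecord]]:
    """Best-effort adapter for externally deposited trial logs.

    ``column_map`` maps the external file's column names onto the package's
    canonical trial-log header; unmapped canonical RT columns are treated
    as missing.
    """
    from .task_env import TRIAL_LOG_COLUMNS, frame_to_trials

    renamed = df.rename(columns=column_map)
    for col in ("rt1_ms", "rt2_ms"):
        if col not in renamed.columns:
            renamed[col] = np.nan
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in renamed.columns]
    if missing:
        raise ValueError(f"adapted trial log still missing columns: {missing}")
    return {
        str(pid): frame_to_trials(grp.sort_values("trial"), config)
        for pid, grp in renamed.groupby("participant_id", sort=True)
    }
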