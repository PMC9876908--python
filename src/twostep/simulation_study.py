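"""Model-based vs model-free simulation experiment.

HYBRID agents are simulated with a blockwise weight schedule: the
model-based condition sets w = 1 for the first 40-trial block and 0.5
thereafter, the model-free condition w = 0 then 0.5, with alpha = eta =
0.2 and beta = 5 in both.  Each repetition is an independent agent playing
200 trials of the canonical task.

Learning speed is summarized per repetition by the stage-1 value
difference Q(1,R) - Q(1,L) (recorded at the moment of each first-stage
choice, so it starts at 0), fitted with a sigmoid constrained through the
origin,

    f(x) = a / (1 + exp(-b x)) - a / 2,

whose slope b is the learning-speed statistic; slopes are compared across
conditions with a Wilcoxon rank-sum test, and early-session rewards with a
trial-pooled two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import ranksums, ttest_ind

from .learners import LearnerParams, _step
from .task_env import CompiledTask, TaskConfig, compile_task

MB_SCHEDULE = (1.0, 0.5, 0.5, 0.5, 0.5)
MF_SCHEDULE = (0.0, 0.5, 0.5, 0.5, 0.5)


@dataclass(frozen=True)
class SimSpec:
    """One simulation condition: a weight schedule and fixed learner params."""

    weight_schedule: tuple[float, ...] = MB_SCHEDULE
    alpha: float = 0.2
    eta: float = 0.2
    beta: float = 5.0
    n_reps: int = 10_000
    n_trials: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= w <= 1.0) for w in self.weight_schedule):
            raise ValueError("all schedule weights must lie in [0,1]")
        if self.n_trials % len(self.weight_schedule) != 0:
            raise ValueError("n_trials must divide evenly into schedule blocks")


@dataclass
class SimResult:
    """Pooled per-repetition trajectories of one condition."""

    spec: SimSpec
    rewards_yen: np.ndarray  # (n_reps, n_trials)
    q_right: np.ndarray  # hybrid Q(1,R) at each first-stage choice
    q_left: np.ndarray


@dataclass
class SigmoidFit:
    a: float
    b: float
    success: bool
    residual_norm: float


def _simulate_rep(
    task: CompiledTask,
    schedule: tuple[float, ...],
    alpha: float,
    eta: float,
    beta: float,
    n_trials: int,
    rng: np.random.Generator,
    rewards: np.ndarray,
    q_right: np.ndarray,
    q_left: np.ndarray,
) -> None:
    """One agent, recording yen rewards and pre-choice hybrid stage-1 values."""
    n = task.n_states
    q_s = [[0.0, 0.0] for _ in range(n)]
    q_f = [[0.0, 0.0] for _ in range(n)]
    t_first = [[0.5, 0.5] for _ in range(n)]
    block_len = n_trials // len(schedule)
    u = rng.random(4 * n_trials)  # a1, s2, a2, s3 draws per trial
    ui = 0
    for i in range(n_trials):
        w = schedule[i // block_len]
        wc = 1.0 - w
        h0 = w * q_f[0][0] + wc * q_s[0][0]
        h1 = w * q_f[0][1] + wc * q_s[0][1]
        q_left[i] = h0
        q_right[i] = h1
        d = beta * (h1 - h0)
        pr = 1.0 / (1.0 + math.exp(-d)) if d > -700 else 0.0
        a1 = 1 if u[ui] < pr else 0
        ui += 1
        slot1 = 0 if u[ui] < task.p_first[0][a1] else 1
        ui += 1
        s2i = task.succ_idx[0][a1][slot1]
        h0 = w * q_f[s2i][0] + wc * q_s[s2i][0]
        h1 = w * q_f[s2i][1] + wc * q_s[s2i][1]
        d = beta * (h1 - h0)
        pr = 1.0 / (1.0 + math.exp(-d)) if d > -700 else 0.0
        a2 = 1 if u[ui] < pr else 0
        ui += 1
        slot2 = 0 if u[ui] < task.p_first[s2i][a2] else 1
        ui += 1
        r = task.r_scaled[s2i][a2][slot2]
        rewards[i] = task.r_yen[s2i][a2][slot2]
        _step(q_s, q_f, t_first, task, alpha, eta, beta, w,
              a1, s2i, slot1, a2, slot2, r)


def run_weight_schedule_sim(
    spec: SimSpec, config: TaskConfig, seed: int | None = None
) -> SimResult:
    """Run ``spec.n_reps`` independent agents under the weight schedule."""
    task = compile_task(config)
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    streams = root.spawn(spec.n_reps)
    rewards = np.empty((spec.n_reps, spec.n_trials))
    q_right = np.empty_like(rewards)
    q_left = np.empty_like(rewards)
    for rep in range(spec.n_reps):
        rng = np.random.default_rng(streams[rep])
        _simulate_rep(
            task, spec.weight_schedule, spec.alpha, spec.eta, spec.beta,
            spec.n_trials, rng, rewards[rep], q_right[rep], q_left[rep],
        )
    return SimResult(spec=spec, rewards_yen=rewards, q_right=q_right, q_left=q_left)


def q_difference_trajectory(result: SimResult) -> np.ndarray:
    """Per-repetition Q(1,R) - Q(1,L), recorded before each trial's update
    (hence 0 on the first trial)."""
    return result.q_right - result.q_left


def fit_origin_sigmoid(x: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Nonlinear least-squares fit of a/(1+exp(-b x)) - a/2.

    Degenerate inputs (a flat series) leave the slope unidentifiable and
    are flagged rather than fitted.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit the sigmoid")
    ymax = float(np.max(np.abs(y)))
    if ymax == 0.0 or np.ptp(y) == 0.0:
        return SigmoidFit(a=0.0, b=float("nan"), success=False,
                          residual_norm=float(np.linalg.norm(y)))

    def f(x, a, b):
        return a / (1.0 + np.exp(-np.clip(b * x, -700, 700))) - a / 2.0

    p0 = (min(2.0 * ymax, 9.9), 0.05)
    try:
        popt, _ = optimize.curve_fit(
            f, x, y, p0=p0, bounds=([1e-9, 1e-9], [10.0, 5.0]), maxfev=2000
        )
        resid = float(np.linalg.norm(y - f(x, *popt)))
        return SigmoidFit(a=float(popt[0]), b=float(popt[1]), success=True,
                          residual_norm=resid)
    except RuntimeError:
        return SigmoidFit(a=float("nan"), b=float("nan"), success=False,
                          residual_norm=float("nan"))


def fit_slopes(result: SimResult) -> tuple[np.ndarray, int]:
    """Per-repetition sigmoid slopes of the Q-difference learning curves.

    Returns the slopes of successful fits and the count of excluded
    (failed or degenerate) fits.
    """
    qd = q_difference_trajectory(result)
    x = np.arange(qd.shape[1], dtype=float)  # origin at the first choice
    slopes = []
    failed = 0
    for rep in range(qd.shape[0]):
        fit = fit_origin_sigmoid(x, qd[rep])
        if fit.success and np.isfinite(fit.b):
            slopes.append(fit.b)
        else:
            failed += 1
    return np.array(slopes), failed


def compare_learning_speed(
    slopes_mb: np.ndarray, slopes_mf: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test on slope distributions (mb vs mf)."""
    slopes_mb = np.asarray(slopes_mb, float)
    slopes_mf = np.asarray(slopes_mf, float)
    if slopes_mb.size == 0 or slopes_mf.size == 0:
        raise ValueError("both slope samples must be nonempty")
    if np.ptp(np.concatenate([slopes_mb, slopes_mf])) == 0.0:
        raise ValueError("all slopes tied; rank-sum statistic undefined")
    res = ranksums(slopes_mb, slopes_mf, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def compare_early_reward(
    result_mb: SimResult,
    result_mf: SimResult,
    trials: slice = slice(0, 40),
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided t-test on per-repetition mean reward over the early trials."""
    a = result_mb.rewards_yen[:, trials].mean(axis=1)
    b = result_mf.rewards_yen[:, trials].mean(axis=1)
    res = ttest_ind(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def recovery_sim_from_group_params(
    proself_params: list[LearnerParams],
    prosocial_params: list[LearnerParams],
    config: TaskConfig,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate both groups from per-block fitted parameters and compare.

    ``*_params`` give one LearnerParams per block (the blockwise w carries
    the group's schedule; alpha/eta/beta are taken from the first block's
    entry, matching the fixed-effects usage).  Returns a two-row summary
    with early-session mean reward and median Q-difference slope per
    group, plus the test statistics of the between-group comparisons.
    """
    results = {}
    for label, plist in (("proself", proself_params), ("prosocial", prosocial_params)):
        spec = SimSpec(
            weight_schedule=tuple(p.w for p in plist),
            alpha=plist[0].alpha,
            eta=plist[0].eta,
            beta=plist[0].beta,
            n_reps=n_reps,
            n_trials=config.n_trials,
            seed=seed,
        )
        results[label] = run_weight_schedule_sim(spec, config)
    slopes = {}
    excluded = {}
    for label, res in results.items():
        slopes[label], excluded[label] = fit_slopes(res)
    t_stat, t_p = compare_early_reward(results["proself"], results["prosocial"])
    z_stat, z_p = compare_learning_speed(slopes["proself"], slopes["prosocial"])
    rows = []
    for label in ("proself", "prosocial"):
        rows.append(
            {
                "group": label,
                "early_reward_mean_yen": float(
                    results[label].rewards_yen[:, :40].mean()
                ),
                "slope_median": float(np.median(slopes[label])),
                "n_slope_fits": int(slopes[label].size),
                "n_excluded_fits": excluded[label],
                "reward_t": t_stat,
                "reward_p": t_p,
                "slope_z": z_stat,
                "slope_p": z_p,
            }
        )
    return pd.DataFrame(rows)


def result_to_frame(result: SimResult) -> pd.DataFrame:
    """Per-rep long table (rep, trial, reward_yen, q_right, q_left)."""
    n_reps, n_trials = result.rewards_yen.shape
    rep = np.repeat(np.arange(n_reps), n_trials)
    trial = np.tile(np.arange(1, n_trials + 1), n_reps)
    return pd.DataFrame(
        {
            "rep": rep,
            "trial": trial,
            "reward_yen": result.rewards_yen.ravel(),
            "q_right": result.q_right.ravel(),
            "q_left": result.q_left.ravel(),
        }
    )
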