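"""MAP estimation of learner parameters, blockwise with carryover, plus BIC.

Parameters are estimated per 40-trial block by minimizing the negative log
posterior: the teacher-forced negative log likelihood of both choices of
every trial plus negative log prior densities — Beta(2,2) for the learning
rates alpha and eta, Gamma(shape=2, scale=3) for the inverse temperature
beta; the weight w carries no prior penalty and is merely box-constrained.
Bounds: 0 < alpha, eta, w < 1 and 0 < beta < 10.

The learner state (Q values and transition estimates) at the end of each
block, evaluated under that block's fitted parameters, is carried over as
the initial state of the next block; the fitted parameters also seed the
next block's optimizer.  A fixed-effects variant shares one parameter
vector across a group, summing likelihoods with a single prior penalty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc, spearmanr

from .learners import LearnerParams, LearnerState, _compile_trial, _step
from .task_env import CompiledTask, TaskConfig, TrialRecord, compile_task

Model = Literal["sarsa", "forward", "hybrid"]

_MODELS = ("sarsa", "forward", "hybrid")

# free parameters per model (names within the LearnerParams vector)
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "sarsa": ("alpha", "beta"),
    "forward": ("eta", "beta"),
    "hybrid": ("alpha", "eta", "beta", "w"),
}

_EPS = 1e-6
_BOUNDS = {"alpha": (0.0, 1.0), "eta": (0.0, 1.0), "beta": (0.0, 10.0), "w": (0.0, 1.0)}


@dataclass(frozen=True)
class PriorSpec:
    """Priors for MAP regularization.

    ``gamma_parameterization`` selects how the (2, 3) of the inverse
    temperature's gamma prior is read: ``"scale"`` (shape 2, scale 3; mode
    at beta=3) or ``"rate"`` (shape 2, rate 3).  The scale reading is the
    default: its mode sits where whole-session estimates of beta actually
    fall, while the rate reading would concentrate mass below 1.
    """

    alpha_shape: tuple[float, float] = (2.0, 2.0)
    eta_shape: tuple[float, float] = (2.0, 2.0)
    beta_gamma: tuple[float, float] = (2.0, 3.0)
    gamma_parameterization: Literal["scale", "rate"] = "scale"

    def _log_beta_pdf(self, x: float, shape: tuple[float, float]) -> float:
        a, b = shape
        if not (0.0 < x < 1.0):
            raise ValueError(f"learning rate {x} outside the open unit interval")
        lognorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        return lognorm + (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x)

    def _log_gamma_pdf(self, x: float) -> float:
        shape, second = self.beta_gamma
        scale = second if self.gamma_parameterization == "scale" else 1.0 / second
        if x <= 0.0:
            raise ValueError(f"inverse temperature {x} must be positive")
        return (
            -math.lgamma(shape)
            - shape * math.log(scale)
            + (shape - 1.0) * math.log(x)
            - x / scale
        )

    def neg_log_prior(self, params: LearnerParams, model: Model = "hybrid") -> float:
        """-log prior density over the model's free parameters; w contributes 0."""
        total = 0.0
        names = MODEL_FREE_PARAMS[model]
        if "alpha" in names:
            total -= self._log_beta_pdf(params.alpha, self.alpha_shape)
        if "eta" in names:
            total -= self._log_beta_pdf(params.eta, self.eta_shape)
        if "beta" in names:
            total -= self._log_gamma_pdf(params.beta)
        return total

    @property
    def modes(self) -> dict[str, float]:
        """Analytic prior modes: Beta(2,2) -> 0.5; Gamma(2, scale 3) -> 3."""
        a, b = self.alpha_shape
        shape, second = self.beta_gamma
        scale = second if self.gamma_parameterization == "scale" else 1.0 / second
        return {
            "alpha": (a - 1.0) / (a + b - 2.0),
            "eta": (self.eta_shape[0] - 1.0) / (sum(self.eta_shape) - 2.0),
            "beta": (shape - 1.0) * scale,
        }


@dataclass(frozen=True)
class BlockScheme:
    """Blocking of a session into fitting windows (default 40-trial blocks)."""

    block_size: int = 40
    carryover: bool = True

    def n_blocks(self, n_trials: int) -> int:
        if n_trials < self.block_size:
            raise ValueError(
                f"need at least {self.block_size} trials, got {n_trials}"
            )
        return n_trials // self.block_size

    def block_slices(self, n_trials: int) -> list[slice]:
        return [
            slice(k * self.block_size, (k + 1) * self.block_size)
            for k in range(self.n_blocks(n_trials))
        ]


@dataclass
class BlockFit:
    """MAP estimate for one block of one participant (or one group)."""

    block: int
    model: str
    params_hat: LearnerParams
    nll: float
    nlp: float
    bic: float
    n_obs: int
    carry_state: LearnerState
    n_restarts_used: int
    converged: bool


@dataclass
class FitResult:
    """Sequence of per-block MAP fits for one participant."""

    participant_id: str
    model: str
    blocks: list[BlockFit]

    @property
    def total_nll(self) -> float:
        return sum(b.nll for b in self.blocks)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            rows.append(
                {
                    "participant_id": self.participant_id,
                    "block": b.block,
                    "model": self.model,
                    "alpha": b.params_hat.alpha,
                    "eta": b.params_hat.eta,
                    "beta": b.params_hat.beta,
                    "w": b.params_hat.w,
                    "nll": b.nll,
                    "bic": b.bic,
                    "converged": b.converged,
                }
            )
        return pd.DataFrame(rows)


# -- likelihood ------------------------------------------------------------


def _effective_params(params: LearnerParams, model: Model) -> tuple[float, float, float, float]:
    """(alpha, eta, beta, w) actually used by each model family."""
    if model == "sarsa":
        return params.alpha, params.eta, params.beta, 0.0
    if model == "forward":
        return params.alpha, params.eta, params.beta, 1.0
    if model == "hybrid":
        return params.alpha, params.eta, params.beta, params.w
    raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")


def _nll_compiled(
    compiled_trials: Sequence[tuple],
    task: CompiledTask,
    alpha: float,
    eta: float,
    beta: float,
    w: float,
    q_s: list,
    q_f: list,
    t_first: list,
) -> float:
    """Fast inner loop: NLL over pre-compiled trials, mutating the arrays."""
    nll = 0.0
    log = math.log
    for tr in compiled_trials:
        p1, p2 = _step(q_s, q_f, t_first, task, alpha, eta, beta, w, *tr)
        if p1 <= 0.0 or p2 <= 0.0:
            raise FloatingPointError("zero-probability event in teacher-forced pass")
        nll -= log(p1) + log(p2)
    return nll


def trial_log_likelihood(
    params: LearnerParams,
    trials: Sequence[TrialRecord],
    init: LearnerState,
    model: Model = "hybrid",
    config: TaskConfig | None = None,
) -> tuple[float, LearnerState]:
    """Teacher-forced negative log likelihood of both choices of each trial.

    The SARSA model scores choices through the w=0 path and the FORWARD
    model through w=1; the full learner state is updated either way.
    Returns the NLL and the learner state after the last trial.
    """
    alpha, eta, beta, w = _effective_params(params, model)
    end = init.copy()
    compiled = [_compile_trial(t, end.task) for t in trials]
    nll = _nll_compiled(compiled, end.task, alpha, eta, beta, w,
                        end.q_sarsa, end.q_fwd, end.t_first)
    end.params = replace(params, w=w)
    return nll, end


def neg_log_posterior(
    params: LearnerParams,
    trials: Sequence[TrialRecord],
    init: LearnerState,
    priors: PriorSpec,
    model: Model = "hybrid",
    config: TaskConfig | None = None,
) -> float:
    nll, _ = trial_log_likelihood(params, trials, init, model, config)
    return nll + priors.neg_log_prior(params, model)


def bic(nll: float, k_params: int, n_obs: int) -> float:
    """Bayesian information criterion 2*NLL + k*ln(n); n = 2 choices/trial."""
    if n_obs <= 0:
        raise ValueError(f"n_obs must be positive, got {n_obs}")
    return 2.0 * nll + k_params * math.log(n_obs)


# -- optimization ----------------------------------------------------------


def _pack(params: LearnerParams, names: tuple[str, ...]) -> np.ndarray:
    return np.array([getattr(params, n) for n in names])


def _unpack(x: np.ndarray, names: tuple[str, ...], base: LearnerParams) -> LearnerParams:
    return replace(base, **{n: float(v) for n, v in zip(names, x)})


def _clip_to_bounds(x: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    lo = np.array([_BOUNDS[n][0] + _EPS for n in names])
    hi = np.array([_BOUNDS[n][1] - _EPS for n in names])
    return np.clip(x, lo, hi)


def _restart_points(
    names: tuple[str, ...],
    first: np.ndarray,
    priors: PriorSpec,
    n_restarts: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """First start as given, then the prior mode, then Latin-hypercube draws."""
    pts = [_clip_to_bounds(first, names)]
    modes = priors.modes
    mode_pt = np.array([modes.get(n, 0.5) for n in names])
    if n_restarts >= 2:
        pts.append(_clip_to_bounds(mode_pt, names))
    extra = n_restarts - len(pts)
    if extra > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        unit = sampler.random(extra)
        lo = np.array([_BOUNDS[n][0] for n in names])
        hi = np.array([_BOUNDS[n][1] for n in names])
        for row in unit:
            pts.append(_clip_to_bounds(lo + row * (hi - lo), names))
    return pts


def fit_map_block(
    trials: Sequence[TrialRecord],
    init_state: LearnerState,
    init_params: LearnerParams,
    priors: PriorSpec,
    model: Model = "hybrid",
    config: TaskConfig | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
    block: int = 1,
) -> BlockFit:
    """Bound-constrained MAP fit of one block from multiple starts.

    The best optimum over all restarts is returned; the carryover state is
    recomputed by replaying the block under the fitted parameters.  With an
    empty trial list the objective reduces to the prior, whose optimum is
    the analytic prior mode.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    names = MODEL_FREE_PARAMS[model]
    task = init_state.task
    compiled = [_compile_trial(t, task) for t in trials]
    base = init_params
    prior_of = priors.neg_log_prior

    def objective(x: np.ndarray) -> float:
        p = _unpack(_clip_to_bounds(x, names), names, base)
        alpha, eta, beta, w = _effective_params(p, model)
        q_s = [row[:] for row in init_state.q_sarsa]
        q_f = [row[:] for row in init_state.q_fwd]
        t_f = [row[:] for row in init_state.t_first]
        nll = _nll_compiled(compiled, task, alpha, eta, beta, w, q_s, q_f, t_f)
        return nll + prior_of(p, model)

    bounds = [(_BOUNDS[n][0] + _EPS, _BOUNDS[n][1] - _EPS) for n in names]
    best = None
    any_converged = False
    for x0 in _restart_points(names, _pack(init_params, names), priors, n_restarts, rng):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-8, "gtol": 1e-7},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params_hat = _unpack(_clip_to_bounds(best.x, names), names, base)
    nll, end_state = trial_log_likelihood(params_hat, trials, init_state, model)
    n_obs = 2 * len(trials)
    return BlockFit(
        block=block,
        model=model,
        params_hat=params_hat,
        nll=nll,
        nlp=nll + priors.neg_log_prior(params_hat, model),
        bic=bic(nll, len(names), n_obs) if n_obs else float("nan"),
        n_obs=n_obs,
        carry_state=end_state,
        n_restarts_used=n_restarts,
        converged=any_converged,
    )


_DEFAULT_START = dict(alpha=0.5, eta=0.5, beta=3.0, w=0.5)


def fit_participant_blockwise(
    dataset,
    scheme: BlockScheme,
    priors: PriorSpec,
    model: Model = "hybrid",
    config: TaskConfig | None = None,
    n_restarts_first: int = 10,
    n_restarts_later: int = 4,
    rng: np.random.Generator | None = None,
    participant_id: str | None = None,
) -> FitResult:
    """Sequential per-block MAP fits with parameter and state carryover.

    ``dataset`` is a ParticipantDataset or a plain list of TrialRecord.
    With ``scheme.carryover`` on, each block starts from the previous
    block's end state (replayed under its fitted parameters) and its
    optimizer starts from the previous estimates; with carryover off every
    block starts fresh.
    """
    trials = list(getattr(dataset, "trials", dataset))
    pid = participant_id or str(getattr(dataset, "participant_id", "participant"))
    if config is None:
        config = getattr(dataset, "config", None)
    task = compile_task(config) if config is not None else None
    if task is None:
        raise ValueError("a TaskConfig is required (explicitly or via the dataset)")
    if rng is None:
        rng = np.random.default_rng(0)

    start_params = LearnerParams(**_DEFAULT_START)
    state = LearnerState.fresh(task, start_params)
    params = start_params
    fits: list[BlockFit] = []
    for k, sl in enumerate(scheme.block_slices(len(trials)), start=1):
        init_state = state if scheme.carryover else LearnerState.fresh(task, start_params)
        init_params = params if scheme.carryover else start_params
        n_restarts = n_restarts_first if (k == 1 or not scheme.carryover) else n_restarts_later
        fit = fit_map_block(
            trials[sl], init_state, init_params, priors, model,
            n_restarts=n_restarts, rng=rng, block=k,
        )
        fits.append(fit)
        state, params = fit.carry_state, fit.params_hat
    return FitResult(participant_id=pid, model=model, blocks=fits)


def fit_fixed_effects(
    group,
    scheme: BlockScheme,
    priors: PriorSpec,
    model: Model = "hybrid",
    config: TaskConfig | None = None,
    n_restarts_first: int = 10,
    n_restarts_later: int = 4,
    rng: np.random.Generator | None = None,
) -> list[BlockFit]:
    """Population-level fixed-effects fit: one shared parameter vector per block.

    Minimizes the summed negative log likelihood across the group's
    members plus a single prior penalty (the regularization does not grow
    with group size); each member keeps its own carryover state.
    """
    trial_lists = [list(getattr(d, "trials", d)) for d in group]
    if not trial_lists:
        raise ValueError("fit_fixed_effects requires a nonempty group")
    if config is None:
        config = getattr(group[0], "config", None)
    if config is None:
        raise ValueError("a TaskConfig is required (explicitly or via the datasets)")
    task = compile_task(config)
    if rng is None:
        rng = np.random.default_rng(0)

    names = MODEL_FREE_PARAMS[model]
    n_trials = min(len(t) for t in trial_lists)
    start_params = LearnerParams(**_DEFAULT_START)
    states = [LearnerState.fresh(task, start_params) for _ in trial_lists]
    params = start_params
    bounds = [(_BOUNDS[n][0] + _EPS, _BOUNDS[n][1] - _EPS) for n in names]
    out: list[BlockFit] = []
    for k, sl in enumerate(scheme.block_slices(n_trials), start=1):
        compiled_block = [
            [_compile_trial(t, task) for t in trials[sl]] for trials in trial_lists
        ]

        def objective(x: np.ndarray) -> float:
            p = _unpack(_clip_to_bounds(x, names), names, params)
            alpha, eta, beta, w = _effective_params(p, model)
            total = priors.neg_log_prior(p, model)
            for compiled, st in zip(compiled_block, states):
                q_s = [row[:] for row in st.q_sarsa]
                q_f = [row[:] for row in st.q_fwd]
                t_f = [row[:] for row in st.t_first]
                total += _nll_compiled(compiled, task, alpha, eta, beta, w, q_s, q_f, t_f)
            return total

        n_restarts = n_restarts_first if k == 1 else n_restarts_later
        best = None
        any_converged = False
        for x0 in _restart_points(names, _pack(params, names), priors, n_restarts, rng):
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-8, "gtol": 1e-7},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        params = _unpack(_clip_to_bounds(best.x, names), names, params)
        nll = 0.0
        new_states = []
        for trials, st in zip(trial_lists, states):
            nll_i, end = trial_log_likelihood(params, trials[sl], st, model)
            nll += nll_i
            new_states.append(end)
        states = new_states if scheme.carryover else [
            LearnerState.fresh(task, start_params) for _ in trial_lists
        ]
        n_obs = 2 * sum(len(c) for c in compiled_block)
        out.append(
            BlockFit(
                block=k, model=model, params_hat=params, nll=nll,
                nlp=nll + priors.neg_log_prior(params, model),
                bic=bic(nll, len(names), n_obs), n_obs=n_obs,
                carry_state=states[0], n_restarts_used=n_restarts,
                converged=any_converged,
            )
        )
    return out


# -- diagnostics -----------------------------------------------------------

PARAM_NAMES = ("alpha", "eta", "beta", "w")


def parameter_correlations(
    fits: Sequence[FitResult], block: int
) -> tuple[pd.DataFrame, set[str]]:
    """Spearman rank-correlation matrix of per-participant estimates at a block.

    Returns the 4x4 symmetric matrix (unit diagonal) and the set of
    parameters whose estimates were constant across participants — their
    rows/columns are NaN, never silently zero.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 participants for rank correlations")
    cols = {
        n: np.array([getattr(f.blocks[block - 1].params_hat, n) for f in fits])
        for n in PARAM_NAMES
    }
    flagged = {n for n, v in cols.items() if np.ptp(v) == 0.0}
    mat = pd.DataFrame(
        np.eye(len(PARAM_NAMES)), index=PARAM_NAMES, columns=PARAM_NAMES
    )
    for i, a in enumerate(PARAM_NAMES):
        for j, b in enumerate(PARAM_NAMES):
            if i >= j:
                continue
            if a in flagged or b in flagged:
                rho = np.nan
            else:
                rho = spearmanr(cols[a], cols[b]).statistic
            mat.loc[a, b] = mat.loc[b, a] = rho
    for n in flagged:
        mat.loc[n, n] = np.nan
    return mat, flagged


def recovery_report(
    true_params: Sequence[LearnerParams],
    fitted_params: Sequence[LearnerParams],
) -> pd.DataFrame:
    """Bias, RMSE and rank correlation of fitted vs generating parameters.

    The rank correlation is NaN when either column is constant (e.g. when
    fitted equals truth exactly); this convention is stated in the output
    column ``rho_defined``.
    """
    if len(true_params) != len(fitted_params):
        raise ValueError("true and fitted parameter lists differ in length")
    rows = []
    for n in PARAM_NAMES:
        t = np.array([getattr(p, n) for p in true_params])
        f = np.array([getattr(p, n) for p in fitted_params])
        err = f - t
        if np.ptp(t) == 0.0 or np.ptp(f) == 0.0:
            rho, defined = np.nan, False
        else:
            rho, defined = spearmanr(t, f).statistic, True
        rows.append(
            {
                "param": n,
                "bias": float(np.mean(err)),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "rho": rho,
                "rho_defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("param")


# -- serialization ---------------------------------------------------------


def fit_results_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy CSV-ready table: participant, block, model, estimates, NLL, BIC."""
    if not fits:
        return pd.DataFrame(
            columns=["participant_id", "block", "model", "alpha", "eta",
                     "beta", "w", "nll", "bic", "converged"]
        )
    return pd.concat([f.params_frame() for f in fits], ignore_index=True)


def fit_result_to_json(fit: FitResult, path: str | Path) -> None:
    payload = {
        "participant_id": fit.participant_id,
        "model": fit.model,
        "blocks": [
            {
                "block": b.block,
                "alpha": b.params_hat.alpha,
                "eta": b.params_hat.eta,
                "beta": b.params_hat.beta,
                "w": b.params_hat.w,
                "nll": b.nll,
                "nlp": b.nlp,
                "bic": b.bic,
                "n_obs": b.n_obs,
                "converged": b.converged,
            }
            for b in fit.blocks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
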