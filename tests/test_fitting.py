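"""MAP machinery: likelihood, priors, optimizer, BIC, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from twostep.fitting import (
    BlockScheme,
    PriorSpec,
    bic,
    fit_fixed_effects,
    fit_map_block,
    fit_participant_blockwise,
    neg_log_posterior,
    parameter_correlations,
    recovery_report,
    trial_log_likelihood,
)
from twostep.learners import LearnerParams, LearnerState, act_episode

PRIORS = PriorSpec()


def fresh(canonical, **kw):
    base = dict(alpha=0.5, eta=0.5, beta=3.0, w=0.5)
    base.update(kw)
    return LearnerState.fresh(canonical, LearnerParams(**base))


def simulate_agent(canonical, params, n_trials, seed):
    state = LearnerState.fresh(canonical, params)
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        trial, state = act_episode(state, rng=rng, trial_index=i + 1)
        trials.append(trial)
    return trials


# -- likelihood ----------------------------------------------------------------


def test_empty_trials_nll_zero(canonical):
    init = fresh(canonical)
    nll, end = trial_log_likelihood(init.params, [], init, "hybrid")
    assert nll == 0.0
    assert end.q_sarsa == init.q_sarsa and end.t_first == init.t_first


def test_single_trial_symmetric_nll(canonical, rng, make_random_trials):
    trial = make_random_trials(canonical, 1, rng)
    for beta in (0.5, 5.0, 9.9):
        init = fresh(canonical, beta=beta)
        nll, _ = trial_log_likelihood(init.params, trial, init, "hybrid")
        assert nll == pytest.approx(-2.0 * math.log(0.5), abs=1e-12)


def test_nll_matches_oracle_over_random_parameters(canonical, oracle,
                                                   make_random_trials):
    """100 random parameter draws on fuzzed 20-trial logs agree to 1e-10."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        trials = make_random_trials(canonical, int(rng.integers(5, 21)), rng)
        alpha, eta, w = rng.uniform(0.02, 0.98, size=3)
        beta = rng.uniform(0.1, 9.9)
        params = LearnerParams(alpha=alpha, eta=eta, beta=beta, w=w)
        init = LearnerState.fresh(canonical, params)
        nll, _ = trial_log_likelihood(params, trials, init, "hybrid")
        assert nll == pytest.approx(
            oracle(canonical, trials, alpha, eta, beta, w), abs=1e-10
        )


def test_sarsa_and_forward_models_use_weight_endpoints(canonical, oracle,
                                                       make_random_trials):
    rng = np.random.default_rng(5)
    trials = make_random_trials(canonical, 20, rng)
    params = LearnerParams(alpha=0.3, eta=0.4, beta=4.0, w=0.7)
    init = LearnerState.fresh(canonical, params)
    nll_sarsa, _ = trial_log_likelihood(params, trials, init, "sarsa")
    nll_fwd, _ = trial_log_likelihood(params, trials, init, "forward")
    assert nll_sarsa == pytest.approx(
        oracle(canonical, trials, 0.3, 0.4, 4.0, 0.0), abs=1e-10
    )
    assert nll_fwd == pytest.approx(
        oracle(canonical, trials, 0.3, 0.4, 4.0, 1.0), abs=1e-10
    )


# -- priors --------------------------------------------------------------------


def test_neg_log_posterior_closed_form_on_empty_data(canonical):
    params = LearnerParams(alpha=0.5, eta=0.5, beta=3.0, w=0.5)
    init = LearnerState.fresh(canonical, params)
    value = neg_log_posterior(params, [], init, PRIORS, "hybrid")
    expected = (
        -math.log(1.5)  # Beta(2,2) density at 0.5
        - math.log(1.5)
        - stats.gamma.logpdf(3.0, a=2.0, scale=3.0)
    )
    assert value == pytest.approx(expected, abs=1e-12)
    # cross-check our closed forms against scipy's densities
    assert PRIORS.neg_log_prior(params, "hybrid") == pytest.approx(
        -stats.beta.logpdf(0.5, 2, 2) * 2 - stats.gamma.logpdf(3.0, a=2, scale=3),
        abs=1e-12,
    )


def test_prior_modes_are_analytic():
    assert PRIORS.modes == {"alpha": 0.5, "eta": 0.5, "beta": 3.0}
    rate_priors = PriorSpec(gamma_parameterization="rate")
    assert rate_priors.modes["beta"] == pytest.approx(1.0 / 3.0)


def test_posterior_bounded_below_by_nll_minus_max_prior(canonical, rng,
                                                        make_random_trials):
    trials = make_random_trials(canonical, 15, rng)
    params = LearnerParams(alpha=0.4, eta=0.6, beta=2.0, w=0.3)
    init = LearnerState.fresh(canonical, params)
    nll, _ = trial_log_likelihood(params, trials, init, "hybrid")
    nlp = neg_log_posterior(params, trials, init, PRIORS, "hybrid")
    max_log_prior = (
        stats.beta.logpdf(0.5, 2, 2) * 2 + stats.gamma.logpdf(3.0, a=2, scale=3)
    )
    assert nlp >= nll - max_log_prior - 1e-12


def test_prior_only_optimum_sits_at_prior_modes(canonical):
    """With no data the MAP estimate is the analytic prior mode."""
    init = fresh(canonical)
    start = LearnerParams(alpha=0.2, eta=0.8, beta=7.0, w=0.3)
    fit = fit_map_block(
        [], init, start, PRIORS, "hybrid", n_restarts=3,
        rng=np.random.default_rng(1),
    )
    assert fit.params_hat.alpha == pytest.approx(0.5, abs=1e-4)
    assert fit.params_hat.eta == pytest.approx(0.5, abs=1e-4)
    assert fit.params_hat.beta == pytest.approx(3.0, abs=1e-4)
    assert fit.nll == 0.0


# -- optimizer -----------------------------------------------------------------


def test_fit_map_block_idempotent_restart(canonical):
    params = LearnerParams(alpha=0.3, eta=0.3, beta=5.0, w=0.6)
    trials = simulate_agent(canonical, params, 40, seed=8)
    init = fresh(canonical)
    rng = np.random.default_rng(0)
    fit1 = fit_map_block(trials, init, init.params, PRIORS, "hybrid",
                         n_restarts=6, rng=rng)
    fit2 = fit_map_block(trials, init, fit1.params_hat, PRIORS, "hybrid",
                         n_restarts=1, rng=rng)
    assert fit2.nlp == pytest.approx(fit1.nlp, abs=1e-6)
    for name in ("alpha", "eta", "beta", "w"):
        assert getattr(fit2.params_hat, name) == pytest.approx(
            getattr(fit1.params_hat, name), abs=1e-3
        )


def test_blockwise_fit_returns_five_blocks(canonical):
    params = LearnerParams(alpha=0.3, eta=0.3, beta=5.0, w=0.5)
    trials = simulate_agent(canonical, params, 200, seed=2)
    result = fit_participant_blockwise(
        trials, BlockScheme(), PRIORS, "hybrid", canonical,
        n_restarts_first=3, n_restarts_later=2, rng=np.random.default_rng(0),
    )
    assert len(result.blocks) == 5
    assert [b.block for b in result.blocks] == [1, 2, 3, 4, 5]
    frame = result.params_frame()
    assert list(frame["block"]) == [1, 2, 3, 4, 5]
    assert frame["converged"].all()


def test_carryover_off_blocks_are_independent(canonical):
    params = LearnerParams(alpha=0.3, eta=0.3, beta=5.0, w=0.5)
    trials = simulate_agent(canonical, params, 80, seed=3)
    scheme = BlockScheme(carryover=False)
    full = fit_participant_blockwise(
        trials, scheme, PRIORS, "hybrid", canonical,
        n_restarts_first=3, rng=np.random.default_rng(0),
    )
    # fitting block 2 alone from a fresh state gives the same estimate
    init = fresh(canonical)
    alone = fit_map_block(
        trials[40:80], init, init.params, PRIORS, "hybrid",
        n_restarts=3, rng=np.random.default_rng(0),
    )
    assert alone.nlp == pytest.approx(full.blocks[1].nlp, abs=1e-5)


def test_fixed_effects_group_of_one_matches_individual(canonical):
    params = LearnerParams(alpha=0.25, eta=0.35, beta=4.0, w=0.5)
    trials = simulate_agent(canonical, params, 40, seed=11)
    rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
    single = fit_participant_blockwise(
        trials, BlockScheme(), PRIORS, "hybrid", canonical,
        n_restarts_first=4, rng=rng1,
    )
    group = fit_fixed_effects(
        [trials], BlockScheme(), PRIORS, "hybrid", canonical,
        n_restarts_first=4, rng=rng2,
    )
    assert group[0].nlp == pytest.approx(single.blocks[0].nlp, abs=1e-6)


def test_fixed_effects_duplicated_participant_same_argmin(canonical):
    """Doubling the likelihood changes the objective only through the fixed
    prior weight: each estimate minimizes its own posterior, the doubled
    NLL is exactly twice the per-copy NLL, and the two optima coincide when
    the prior penalty is the binding difference."""
    params = LearnerParams(alpha=0.25, eta=0.35, beta=4.0, w=0.5)
    trials = simulate_agent(canonical, params, 40, seed=13)
    single = fit_fixed_effects(
        [trials], BlockScheme(), PRIORS, "hybrid", canonical,
        n_restarts_first=4, rng=np.random.default_rng(0),
    )
    double = fit_fixed_effects(
        [trials, trials], BlockScheme(), PRIORS, "hybrid", canonical,
        n_restarts_first=4, rng=np.random.default_rng(0),
    )
    init = fresh(canonical)

    def nll_of(p):
        return trial_log_likelihood(p, trials[:40], init, "hybrid")[0]

    p1, p2 = single[0].params_hat, double[0].params_hat
    # doubled NLL is exactly twice the per-copy NLL at the doubled optimum
    assert double[0].nll == pytest.approx(2 * nll_of(p2), abs=1e-9)
    # each optimum beats the other under its own objective
    f_single = lambda p: nll_of(p) + PRIORS.neg_log_prior(p, "hybrid")
    f_double = lambda p: 2 * nll_of(p) + PRIORS.neg_log_prior(p, "hybrid")
    assert f_single(p1) <= f_single(p2) + 1e-6
    assert f_double(p2) <= f_double(p1) + 1e-6


# -- BIC and diagnostics --------------------------------------------------------


def test_bic_closed_form():
    assert bic(100.0, 4, 400) == pytest.approx(200 + 4 * math.log(400))
    assert bic(100.0, 4, 400) == pytest.approx(223.9659, abs=1e-3)
    assert bic(50.0, 0, 10) == 100.0
    with pytest.raises(ValueError):
        bic(1.0, 2, 0)


def _fake_fits(canonical, values):
    """FitResults with prescribed block-1 parameter vectors."""
    from twostep.fitting import BlockFit, FitResult

    out = []
    for i, (a, e, b, w) in enumerate(values):
        p = LearnerParams(alpha=a, eta=e, beta=b, w=w)
        blk = BlockFit(block=1, model="hybrid", params_hat=p, nll=0.0, nlp=0.0,
                       bic=0.0, n_obs=80, carry_state=fresh(canonical),
                       n_restarts_used=1, converged=True)
        out.append(FitResult(participant_id=f"P{i}", model="hybrid", blocks=[blk]))
    return out


def test_parameter_correlations_monotone_and_symmetric(canonical):
    vals = [(0.1 * k + 0.05, 0.9 - 0.1 * k, 1.0 + k, 0.5) for k in range(5)]
    fits = _fake_fits(canonical, vals)
    mat, flagged = parameter_correlations(fits, block=1)
    assert mat.loc["alpha", "eta"] == pytest.approx(-1.0)
    assert mat.loc["alpha", "beta"] == pytest.approx(1.0)
    assert (mat.values == mat.values.T).all() or np.allclose(
        mat.values, mat.values.T, equal_nan=True
    )
    assert flagged == {"w"}
    assert np.isnan(mat.loc["w", "alpha"])


def test_parameter_correlations_null_is_small(canonical):
    rng = np.random.default_rng(17)
    vals = [
        (rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9), rng.uniform(1, 9),
         rng.uniform(0.1, 0.9))
        for _ in range(60)
    ]
    mat, _ = parameter_correlations(_fake_fits(canonical, vals), block=1)
    off = [mat.loc[a, b] for a in mat.index for b in mat.columns if a < b]
    # 95% CI half-width for Spearman at n=60 is ~0.26
    assert all(abs(v) < 0.3 for v in off)


def test_recovery_report_trivial_and_shuffled():
    rng = np.random.default_rng(23)
    truth = [
        LearnerParams(alpha=a, eta=0.5, beta=5.0, w=w)
        for a, w in zip(rng.uniform(0.1, 0.9, 30), rng.uniform(0.1, 0.9, 30))
    ]
    report = recovery_report(truth, truth)
    assert (report["bias"] == 0).all()
    assert (report["rmse"] == 0).all()
    assert report.loc["alpha", "rho"] == pytest.approx(1.0)
    assert not report.loc["eta", "rho_defined"]  # constant column convention
    shuffled = list(truth)
    rng.shuffle(shuffled)
    rep2 = recovery_report(truth, shuffled)
    assert abs(rep2.loc["alpha", "rho"]) < 0.4
    with pytest.raises(ValueError):
        recovery_report(truth, truth[:-1])
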