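"""Discrete-choice model: likelihood, fitting, BIC, CV, outlier rule."""

import math

import numpy as np
import pytest

from utiladapt import (
    AgentConfig,
    DCMParams,
    UtilityCurve,
    bic,
    crossvalidate,
    expected_utility,
    fit_dcm,
    flag_outliers,
    neg_log_likelihood,
)
from utiladapt.agent import random_gamble_safe_pairs, simulate_choices
from utiladapt.dcm import DCMFit, FitError
from utiladapt.distributions import FULL, FULL_ALT, LOW, RewardOption

from conftest import CURVE_GRID


def _simulate(curve, lam, theta, n, seed, dist=FULL):
    rng = np.random.default_rng(seed)
    agent = AgentConfig(utility=curve, temperature=lam, side_bias=theta, seed=seed)
    pairs = random_gamble_safe_pairs(dist, n, rng)
    return simulate_choices(agent, pairs, dist, rng, "s", 0, "validation")


@pytest.mark.parametrize("family,params", CURVE_GRID[:6])
def test_eu_of_extremes_gamble_is_half(family, params):
    """The (min, max) equiprobable gamble is worth 0.5 utils under any
    anchored utility."""
    curve = UtilityCurve(family, params)
    for dist in (LOW, FULL, FULL_ALT):
        gamble = RewardOption.gamble(dist.min_ml, dist.max_ml)
        assert expected_utility(gamble, curve, dist) == pytest.approx(0.5, abs=1e-9)


def test_eu_examples(linear):
    assert expected_utility(RewardOption.safe(1.0), linear, FULL) == pytest.approx(1.0)
    gamble = RewardOption.gamble(0.2, 0.6)
    assert expected_utility(gamble, linear, FULL) == pytest.approx(
        0.5 * 0.2 + 0.5 * 0.6
    )


def test_nll_closed_forms(linear):
    trials = _simulate(linear, 5.0, 0.0, 100, seed=1)
    flat = DCMParams(utility=linear, temperature=0.0, side_bias=0.0)
    assert neg_log_likelihood(trials, flat, FULL) == pytest.approx(100 * math.log(2))

    # single trial at P(left) = 0.9, left chosen
    t = trials[0]
    p = 0.9
    theta = math.log(p / (1 - p))
    params = DCMParams(utility=linear, temperature=0.0, side_bias=theta)
    one = [t] if t.chosen == "left" else [
        type(t)(t.session_id, t.day_index, t.distribution, t.right, t.left,
                "left", t.sequence_tag)
    ]
    assert neg_log_likelihood(one, params, FULL) == pytest.approx(-math.log(0.9))


def test_nll_matches_per_trial_loop_oracle(prelec_s):
    trials = _simulate(prelec_s, 8.0, 0.3, 200, seed=2)
    params = DCMParams(utility=prelec_s, temperature=8.0, side_bias=0.3)
    total = 0.0
    for t in trials:
        eu_l = expected_utility(t.left, prelec_s, FULL)
        eu_r = expected_utility(t.right, prelec_s, FULL)
        p_left = 1.0 / (1.0 + math.exp(-8.0 * (eu_l - eu_r) - 0.3))
        total -= math.log(p_left if t.chosen == "left" else 1.0 - p_left)
    assert neg_log_likelihood(trials, params, FULL) == pytest.approx(total, rel=1e-10)


def test_bic_arithmetic_and_shuffle_invariance(linear, rng):
    fit = DCMFit(
        params=DCMParams(utility=linear, temperature=1.0, side_bias=0.0),
        neg_ll=69.31, n_trials=100, k=3, bic=0.0, cv_negll=None, converged=True,
    )
    assert bic(fit) == pytest.approx(3 * math.log(100) + 2 * 69.31)

    trials = _simulate(linear, 10.0, 0.0, 300, seed=3)
    f1 = fit_dcm(trials, "power1", FULL, n_starts=3, seed=0)
    shuffled = [trials[i] for i in rng.permutation(len(trials))]
    f2 = fit_dcm(shuffled, "power1", FULL, n_starts=3, seed=0)
    assert f1.bic == pytest.approx(f2.bic, abs=1e-6)


def test_fit_is_deterministic(prelec_s):
    trials = _simulate(prelec_s, 10.0, 0.0, 400, seed=4)
    f1 = fit_dcm(trials, "prelec2", FULL, n_starts=4, seed=7)
    f2 = fit_dcm(trials, "prelec2", FULL, n_starts=4, seed=7)
    assert f1.params == f2.params
    assert f1.neg_ll == f2.neg_ll


def test_fit_recovers_linear_agent(linear):
    """Generated by power1(alpha=1), lambda=10, theta=0 at n=5000: alpha back
    within 0.05, theta within 0.1."""
    trials = _simulate(linear, 10.0, 0.0, 5000, seed=5)
    fit = fit_dcm(trials, "power1", FULL, n_starts=5, seed=0)
    assert fit.params.utility.params[0] == pytest.approx(1.0, abs=0.05)
    assert fit.params.side_bias == pytest.approx(0.0, abs=0.1)
    assert fit.params.temperature == pytest.approx(10.0, rel=0.15)


def test_fit_rejects_tiny_sessions(linear):
    trials = _simulate(linear, 10.0, 0.0, 8, seed=6)
    with pytest.raises(FitError):
        fit_dcm(trials, "power1", FULL)


def test_likelihood_prefers_generating_parameters(prelec_s):
    """At large n the generating parameters beat +/-50% perturbations."""
    trials = _simulate(prelec_s, 10.0, 0.0, 4000, seed=7)
    base = DCMParams(utility=prelec_s, temperature=10.0, side_bias=0.0)
    nll0 = neg_log_likelihood(trials, base, FULL)
    for factor in (0.5, 1.5):
        pert = DCMParams(
            utility=UtilityCurve("prelec2", (2.0 * factor, 1.0 * factor)),
            temperature=10.0, side_bias=0.0,
        )
        assert neg_log_likelihood(trials, pert, FULL) > nll0


def test_cv_deterministic_and_flat_agent_scores_ln2(linear):
    trials = _simulate(linear, 0.0, 0.0, 300, seed=8)
    cv1 = crossvalidate(trials, "power1", FULL, seed=3, n_starts=2)
    cv2 = crossvalidate(trials, "power1", FULL, seed=3, n_starts=2)
    assert cv1 == cv2
    # per-trial held-out nll near ln 2: no structure to learn
    per_trial = cv1 / (len(trials) / 10)
    assert per_trial == pytest.approx(math.log(2), abs=0.05)


def test_cv_not_optimistic(prelec_s):
    trials = _simulate(prelec_s, 10.0, 0.0, 600, seed=9)
    fit = fit_dcm(trials, "prelec2", FULL, n_starts=3, seed=0)
    cv = crossvalidate(trials, "prelec2", FULL, seed=0, n_starts=3)
    train_per_trial = fit.neg_ll / fit.n_trials
    cv_per_trial = cv / (len(trials) / 10)
    assert cv_per_trial >= train_per_trial - 0.02


def test_recovery_error_decreases_with_n(prelec_s):
    meds = []
    for n in (200, 1000, 5000):
        errs = []
        for rep in range(8):
            trials = _simulate(prelec_s, 10.0, 0.0, n, seed=100 * n + rep)
            fit = fit_dcm(trials, "prelec2", FULL, n_starts=3, seed=rep)
            a, b = fit.params.utility.params
            errs.append(abs(a - 2.0) / 2.0 + abs(b - 1.0))
        meds.append(np.median(errs))
    assert meds[0] > meds[1] > meds[2]


def _fit_with_params(family, params):
    return DCMFit(
        params=DCMParams(utility=UtilityCurve(family, params), temperature=5.0,
                         side_bias=0.0),
        neg_ll=10.0, n_trials=100, k=4, bic=0.0, cv_negll=None, converged=True,
    )


def test_flag_outliers_identical_pool_keeps_all():
    fits = [_fit_with_params("prelec2", (2.0, 1.0)) for _ in range(5)]
    kept, excluded = flag_outliers(fits)
    assert len(kept) == 5 and not excluded


def test_flag_outliers_drops_planted_outlier(rng):
    # a realistic pool with one alpha 100x the rest
    fits = [
        _fit_with_params("prelec2", (float(a), float(b)))
        for a, b in zip(rng.lognormal(0.6, 0.2, 49), rng.lognormal(0.0, 0.2, 49))
    ]
    fits.append(_fit_with_params("prelec2", (min(180.0, 20.0), 1.0)))
    # param bounds cap at 20; plant the outlier at the cap, ~100x the ~1.8 mean
    kept, excluded = flag_outliers(fits)
    assert len(excluded) == 1
    assert excluded[0].params.utility.params[0] == 20.0
    assert "alpha" in excluded[0].excluded_reason


def test_flag_outliers_input_validation():
    fits = [_fit_with_params("prelec2", (2.0, 1.0))] * 2
    with pytest.raises(ValueError):
        flag_outliers(fits)
    mixed = [_fit_with_params("prelec2", (2.0, 1.0))] * 3 + [
        _fit_with_params("power1", (1.0,))
    ]
    with pytest.raises(ValueError):
        flag_outliers(mixed)
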