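"""Psychometric CE estimation and fractile bookkeeping."""

import numpy as np
import pytest

from utiladapt import (
    AgentConfig,
    FractileConfig,
    choice_ratios,
    fit_psychometric,
    generate_fractile_session,
    normalize_ce,
    run_fractile,
)
from utiladapt.distributions import FULL_ALT, HIGH, LOW, RewardOption
from utiladapt.psychometrics import (
    DegenerateFitError,
    InsufficientDataError,
    PsychometricError,
)
from utiladapt.trials import ChoiceTrial


def _trial(gamble, safe_ml, chose_safe, safe_side="left"):
    safe = RewardOption.safe(safe_ml)
    left, right = (safe, gamble) if safe_side == "left" else (gamble, safe)
    chosen = safe_side if chose_safe else ("right" if safe_side == "left" else "left")
    return ChoiceTrial("s", 0, "low", left, right, chosen, "fractile_step1")


GAMBLE = RewardOption.gamble(0.0, 0.5)


def test_choice_ratios_counts():
    trials = [
        _trial(GAMBLE, 0.2, True), _trial(GAMBLE, 0.2, True, "right"),
        _trial(GAMBLE, 0.2, False), _trial(GAMBLE, 0.2, False, "right"),
        _trial(GAMBLE, 0.1, False), _trial(GAMBLE, 0.3, False),
        _trial(GAMBLE, 0.4, False),
    ]
    rows = choice_ratios(trials, GAMBLE)
    assert rows == [(0.1, 0.0, 1), (0.2, 0.5, 4), (0.3, 0.0, 1), (0.4, 0.0, 1)]


def test_choice_ratios_requires_matching_trials():
    with pytest.raises(PsychometricError):
        choice_ratios([_trial(GAMBLE, 0.2, True)], RewardOption.gamble(0.1, 0.4))


def test_choice_ratios_increase_with_safe_magnitude(prelec_s, rng):
    agent = AgentConfig(utility=prelec_s, temperature=15.0, seed=2)
    sess = generate_fractile_session(agent, LOW, config=FractileConfig(repeats=10))
    rows = choice_ratios(
        [t for t in sess.trials if t.sequence_tag == "fractile_step1"], GAMBLE
    )
    props = [p for _, p, _ in rows]
    # monotone trend: Spearman-like check on the aggregate proportions
    assert np.corrcoef(np.arange(len(props)), props)[0, 1] > 0.7


def _logistic_rows(x0, sigma, safes, n):
    p = 1.0 / (1.0 + np.exp(-(np.asarray(safes) - x0) / sigma))
    return [(s, float(pi), n) for s, pi in zip(safes, p)]


def test_noiseless_recovery():
    """Exact logistic proportions recover the generating (x0, sigma)."""
    safes = np.round(np.arange(0.10, 0.45, 0.05), 3)
    rows = _logistic_rows(0.25, 0.05, safes, 20)
    fit = fit_psychometric(rows)
    assert fit.x0 == pytest.approx(0.25, abs=1e-6)
    assert fit.sigma == pytest.approx(0.05, rel=1e-4)
    assert fit.n_points == len(safes)
    # least-squares mode agrees on noiseless data
    fit_ls = fit_psychometric(rows, method="ls")
    assert fit_ls.x0 == pytest.approx(0.25, abs=1e-5)


def test_flat_ratios_flagged_degenerate():
    rows = [(s, 0.5, 10) for s in (0.1, 0.2, 0.3, 0.4)]
    with pytest.raises(DegenerateFitError):
        fit_psychometric(rows)


def test_insufficient_data_filter():
    rows = [(0.1, 0.0, 4), (0.3, 1.0, 4)]
    with pytest.raises(InsufficientDataError):
        fit_psychometric(rows)
    # enough rungs, but under-repeated
    rows = [(0.1, 0.0, 2), (0.2, 0.4, 2), (0.3, 0.9, 2), (0.4, 1.0, 2)]
    with pytest.raises(InsufficientDataError):
        fit_psychometric(rows)


def test_binomial_noise_recovery(rng):
    """x0 estimates from binomial samples (n=20 per rung) are unbiased and
    tight across 200 replicates."""
    safes = np.round(np.arange(0.05, 0.50, 0.05), 3)
    truth = 0.25
    p = 1.0 / (1.0 + np.exp(-(safes - truth) / 0.06))
    estimates = []
    for _ in range(200):
        k = rng.binomial(20, p)
        rows = [(s, ki / 20, 20) for s, ki in zip(safes, k)]
        try:
            estimates.append(fit_psychometric(rows).x0)
        except PsychometricError:
            continue
    estimates = np.array(estimates)
    assert len(estimates) > 190
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - truth) < 2 * se + 1e-3
    assert estimates.std(ddof=1) < 0.05


def test_fit_cross_checked_against_glm_logistic_regression(rng):
    """Binomial-ML fit agrees with statsmodels GLM logistic regression
    (x0 = -intercept/slope, sigma = 1/slope)."""
    import statsmodels.api as sm

    safes = np.round(np.arange(0.05, 0.50, 0.05), 3)
    p = 1.0 / (1.0 + np.exp(-(safes - 0.22) / 0.07))
    k = rng.binomial(40, p)
    rows = [(s, ki / 40, 40) for s, ki in zip(safes, k)]
    fit = fit_psychometric(rows)
    glm = sm.GLM(
        np.column_stack([k, 40 - k]),
        sm.add_constant(safes),
        family=sm.families.Binomial(),
    ).fit()
    x0_glm = -glm.params[0] / glm.params[1]
    sigma_glm = 1.0 / glm.params[1]
    assert fit.x0 == pytest.approx(x0_glm, abs=1e-4)
    assert fit.sigma == pytest.approx(sigma_glm, rel=1e-3)


def test_run_fractile_levels_and_ladder(risk_neutral_agent):
    """A risk-neutral agent's fractile ladder follows the EV midpoint
    recursion (0.0625, 0.125, 0.25, 0.375, 0.4375) ml in the low range."""
    sess = generate_fractile_session(
        risk_neutral_agent, LOW, config=FractileConfig(repeats=8)
    )
    points = run_fractile(sess.trials, LOW, min_repeats=4)
    by_level = {p.utility_level: p.ce_ml for p in points}
    assert set(by_level) == {0.125, 0.25, 0.5, 0.75, 0.875}
    expected = {0.125: 0.0625, 0.25: 0.125, 0.5: 0.25, 0.75: 0.375, 0.875: 0.4375}
    for level, ce in expected.items():
        assert by_level[level] == pytest.approx(ce, abs=0.05)
    # monotone CE ladder, and step/level bookkeeping consistent
    ces = [by_level[lv] for lv in sorted(by_level)]
    assert ces == sorted(ces)
    for p in points:
        assert p.utility_level in {1: {0.5}, 2: {0.25, 0.75}, 3: {0.125, 0.875}}[p.step]


def test_run_fractile_requires_step1():
    trials = [
        ChoiceTrial("s", 0, "low", RewardOption.safe(0.1),
                    RewardOption.gamble(0.0, 0.2), "left", "fractile_step2")
    ]
    with pytest.raises(PsychometricError):
        run_fractile(trials, LOW)


def test_run_fractile_discards_sparse_sessions(risk_neutral_agent):
    """Fewer than three reliably estimated utility levels discards the
    session."""
    sess = generate_fractile_session(
        risk_neutral_agent, LOW, config=FractileConfig(repeats=8)
    )
    step1_only = [t for t in sess.trials if t.sequence_tag == "fractile_step1"]
    with pytest.raises(PsychometricError):
        run_fractile(step1_only, LOW)


def test_normalize_ce_examples():
    assert normalize_ce(0.25, LOW) == pytest.approx(0.5)
    assert normalize_ce(0.5, HIGH) == pytest.approx(0.0)
    assert normalize_ce(0.46, FULL_ALT) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        normalize_ce(0.6, LOW)
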