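"""Simulated agents: logit choice rule, schedules, session generators."""

import math

import numpy as np
import pytest

from utiladapt import (
    AgentConfig,
    FractileConfig,
    UtilityCurve,
    build_schedule,
    choice_probability,
    generate_fractile_session,
    generate_validation_session,
    simulate_choices,
)
from utiladapt.distributions import FULL, HIGH, LOW, RewardOption


def test_build_schedule_multiweek_blocks():
    sched = build_schedule([(LOW, 22), (FULL, 31), (HIGH, 17)])
    assert len(sched) == 70
    assert [d for d, _ in sched] == list(range(70))
    labels = [dist.label for _, dist in sched]
    assert labels[:22] == ["low"] * 22
    assert labels[22:53] == ["full"] * 31
    assert labels[53:] == ["high"] * 17


def test_build_schedule_small_cases():
    assert build_schedule([(FULL, 1)]) == [(0, FULL)]
    sched = build_schedule([(LOW, 2), (HIGH, 2)])
    assert [(d, s.label) for d, s in sched] == [
        (0, "low"), (1, "low"), (2, "high"), (3, "high")
    ]
    with pytest.raises(ValueError):
        build_schedule([])
    with pytest.raises(ValueError):
        build_schedule([(LOW, 0)])


def test_choice_probability_degenerate_limits(linear):
    gamble = RewardOption.gamble(0.0, 1.0)
    safe = RewardOption.safe(0.3)
    indifferent = AgentConfig(utility=linear, temperature=0.0, side_bias=0.0)
    assert choice_probability(indifferent, gamble, safe, FULL) == pytest.approx(0.5)
    biased = AgentConfig(utility=linear, temperature=0.0, side_bias=30.0)
    assert choice_probability(biased, gamble, safe, FULL) == pytest.approx(1.0, abs=1e-9)


def test_choice_probability_matches_hand_coded_logit(linear):
    """Linear agent, lambda=10: EVs 0.6 vs 0.4 give the closed-form logit."""
    agent = AgentConfig(utility=linear, temperature=10.0, side_bias=0.0)
    left = RewardOption.safe(0.6)
    right = RewardOption.safe(0.4)
    expected = 1.0 / (1.0 + math.exp(-10.0 * (0.6 - 0.4)))
    assert choice_probability(agent, left, right, FULL) == pytest.approx(expected)


def test_choice_probability_increasing_in_eu_gap(linear):
    agent = AgentConfig(utility=linear, temperature=5.0)
    right = RewardOption.safe(0.5)
    probs = [
        choice_probability(agent, RewardOption.safe(m), right, FULL)
        for m in np.linspace(0.1, 0.9, 9)
    ]
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_simulated_frequency_matches_analytic_probability(rng):
    """Empirical choice fraction lands within 3 binomial SEs of the logit
    probability (Prelec alpha=2, lambda=8)."""
    agent = AgentConfig(utility=UtilityCurve("prelec2", (2.0, 1.0)), temperature=8.0)
    a = RewardOption.gamble(0.2, 0.9)
    b = RewardOption.safe(0.55)
    # hold sides fixed to compare against P(choose a-side)
    n = 10_000
    trials = simulate_choices(
        agent, [(a, b)] * n, FULL, rng, "s", 0, "validation"
    )
    frac_a = np.mean([
        (t.chosen == "left") == (t.left == a) for t in trials
    ])
    p = choice_probability(agent, a, b, FULL)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac_a - p) < 3 * se


def test_fair_coin_at_zero_temperature(linear, rng):
    agent = AgentConfig(utility=linear, temperature=0.0, side_bias=0.0)
    trials = simulate_choices(
        agent,
        [(RewardOption.safe(0.2), RewardOption.safe(0.8))] * 10_000,
        FULL, rng, "s", 0, "validation",
    )
    frac_left = np.mean([t.chosen == "left" for t in trials])
    assert abs(frac_left - 0.5) < 0.02


def test_session_regeneration_is_bitwise_identical(prelec_s):
    agent = AgentConfig(utility=prelec_s, temperature=10.0, seed=42)
    s1 = generate_fractile_session(agent, LOW, day_index=3)
    s2 = generate_fractile_session(agent, LOW, day_index=3)
    assert s1.trials == s2.trials
    assert s1.ce_by_level == s2.ce_by_level
    s3 = generate_fractile_session(agent, LOW, day_index=4)
    assert s3.trials != s1.trials


def test_fractile_session_structure(prelec_s):
    agent = AgentConfig(utility=prelec_s, temperature=12.0, seed=5)
    sess = generate_fractile_session(agent, LOW, day_index=0)
    step1 = [t for t in sess.trials if t.sequence_tag == "fractile_step1"]
    assert step1, "step-1 trials missing"
    # step-1 gamble spans the distribution extremes at p = 0.5 each
    risky = {t.right if t.left.is_safe else t.left for t in step1}
    assert risky == {RewardOption.gamble(0.0, 0.5)}
    for t in sess.trials:
        safe = t.left if t.left.is_safe else t.right
        gamble = t.right if t.left.is_safe else t.left
        assert safe.is_safe != gamble.is_safe  # exactly one safe per trial
        for m, _ in safe.outcomes + gamble.outcomes:
            assert LOW.contains(m)
        # safe rungs sit on the 0.05-ml ladder
        assert (safe.outcomes[0][0] / 0.05) == pytest.approx(
            round(safe.outcomes[0][0] / 0.05), abs=1e-6
        )


def test_risk_neutral_step1_ce_is_gamble_ev(risk_neutral_agent):
    """A near-deterministic EV maximizer's simulated step-1 CE in the low
    range sits at the (0, 0.5) gamble's EV, 0.25 ml, within one ladder step."""
    sess = generate_fractile_session(
        risk_neutral_agent, LOW, day_index=0, config=FractileConfig(repeats=8)
    )
    assert 0.5 in sess.ce_by_level
    assert sess.ce_by_level[0.5] == pytest.approx(0.25, abs=0.05)


def test_validation_session_magnitudes_within_distribution(prelec_s):
    agent = AgentConfig(utility=prelec_s, temperature=10.0, seed=9)
    trials = generate_validation_session(agent, HIGH, day_index=0)
    assert trials
    for t in trials:
        assert t.sequence_tag == "validation"
        for opt in (t.left, t.right):
            assert opt.within(HIGH)


def test_agent_config_validation(linear):
    with pytest.raises(ValueError):
        AgentConfig(utility=linear, temperature=-1.0)
    with pytest.raises(ValueError):
        AgentConfig(utility=linear, temperature=1.0, adaptation_mode="none")
    with pytest.raises(ValueError):
        AgentConfig(utility=linear, temperature=1.0, adaptation_mode="wat")


def test_partial_adaptation_anchors_interpolate(linear):
    agent = AgentConfig(
        utility=linear, temperature=1.0, adaptation_mode="partial",
        adaptation_weight=0.5, reference=FULL,
    )
    lo, hi = agent.anchors(LOW)
    assert lo == pytest.approx(0.0)
    assert hi == pytest.approx(0.75)  # halfway between 0.5 and 1.0
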