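"""Simulated decision-making agents and task-schedule generation.

An agent chooses between two reward options by a logit rule over expected
utilities,

    P(choose left) = 1 / (1 + exp(-lambda * (EU_left - EU_right) - theta)),

with temperature lambda (higher = more deterministic) and additive side bias
theta (theta > 0 biases toward the left option).  Expected utility is the
probability-weighted mean of U over the option's outcomes, with U evaluated
on magnitudes normalized by the agent's *effective anchors*:

- ``full`` adaptation: anchors are the current session's distribution
  (utility re-anchors to whatever range is in play);
- ``none``: anchors stay fixed at a reference distribution (the utility
  evaluates narrow-range magnitudes as segments of one absolute curve);
- ``partial``: anchors interpolate, weight * current + (1 - weight) * reference.

The generators produce the two session types of the task: three-step
fractile elicitation sequences (gamble vs. 0.05-ml safe ladders, chained
through simulated certainty equivalents) and out-of-sample validation
sequences over the four equivariant gambles.

Reproducibility: one top-level seed; the stream for day ``d`` is
``default_rng(SeedSequence([seed, d]))``, so any session can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .distributions import RewardDistribution, RewardOption
from .models import UtilityCurve
from .psychometrics import PsychometricError, choice_ratios, fit_psychometric
from .trials import ChoiceTrial
from .validation import design_gambles

__all__ = [
    "AgentConfig",
    "FractileConfig",
    "FractileSession",
    "build_schedule",
    "choice_probability",
    "simulate_choice",
    "simulate_choices",
    "generate_fractile_session",
    "generate_validation_session",
    "random_gamble_safe_pairs",
    "day_rng",
]


@dataclass(frozen=True)
class AgentConfig:
    """Ground-truth decision model of a simulated agent."""

    utility: UtilityCurve
    temperature: float  # lambda >= 0
    side_bias: float = 0.0  # theta
    adaptation_mode: str = "full"  # "none" | "full" | "partial"
    adaptation_weight: float = 1.0  # used by "partial"
    reference: RewardDistribution | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature (lambda) must be >= 0")
        if self.adaptation_mode not in ("none", "full", "partial"):
            raise ValueError(f"unknown adaptation_mode {self.adaptation_mode!r}")
        if self.adaptation_mode in ("none", "partial") and self.reference is None:
            raise ValueError(
                f"adaptation_mode={self.adaptation_mode!r} needs a reference "
                "distribution"
            )
        if self.adaptation_mode == "partial" and not 0.0 <= self.adaptation_weight <= 1.0:
            raise ValueError("adaptation_weight must lie in [0, 1]")

    def anchors(self, current: RewardDistribution) -> tuple[float, float]:
        """Effective (min, max) normalization anchors for a session."""
        if self.adaptation_mode == "full":
            return current.min_ml, current.max_ml
        ref = self.reference
        if self.adaptation_mode == "none":
            return ref.min_ml, ref.max_ml
        w = self.adaptation_weight
        return (
            w * current.min_ml + (1 - w) * ref.min_ml,
            w * current.max_ml + (1 - w) * ref.max_ml,
        )

    def utility_of_ml(self, m_ml, current: RewardDistribution):
        """Agent's subjective utility of magnitudes in ml (vectorized)."""
        lo, hi = self.anchors(current)
        x = np.clip((np.asarray(m_ml, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
        return self.utility(x)


def day_rng(seed: int, day_index: int) -> np.random.Generator:
    """Deterministic per-day random stream derived from a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, day_index]))


def build_schedule(
    blocks: list[tuple[RewardDistribution, int]],
) -> list[tuple[int, RewardDistribution]]:
    """Expand (distribution, n_days) blocks into an ordered day schedule."""
    if not blocks:
        raise ValueError("empty block list")
    schedule = []
    day = 0
    for dist, n_days in blocks:
        if n_days < 1:
            raise ValueError(f"block {dist.label!r} must span >= 1 day, got {n_days}")
        for _ in range(n_days):
            schedule.append((day, dist))
            day += 1
    return schedule


def _expected_utility_ml(
    agent: AgentConfig, option: RewardOption, current: RewardDistribution
) -> float:
    return float(
        sum(p * agent.utility_of_ml(m, current) for m, p in option.outcomes)
    )


def choice_probability(
    agent: AgentConfig,
    left: RewardOption,
    right: RewardOption,
    current: RewardDistribution,
) -> float:
    """Probability that the agent chooses the left option (logit rule)."""
    eu_l = _expected_utility_ml(agent, left, current)
    eu_r = _expected_utility_ml(agent, right, current)
    return float(expit(agent.temperature * (eu_l - eu_r) + agent.side_bias))


def simulate_choice(
    agent: AgentConfig,
    left: RewardOption,
    right: RewardOption,
    current: RewardDistribution,
    rng: np.random.Generator,
) -> str:
    """One Bernoulli draw from the logit choice rule."""
    p = choice_probability(agent, left, right, current)
    return "left" if rng.random() < p else "right"


def simulate_choices(
    agent: AgentConfig,
    pairs: list[tuple[RewardOption, RewardOption]],
    current: RewardDistribution,
    rng: np.random.Generator,
    session_id: str,
    day_index: int,
    sequence_tag: str,
) -> list[ChoiceTrial]:
    """Simulate a trial sequence (vectorized): random sides, logit choices.

    Each (a, b) pair is shown once, with a/b assigned uniformly to the
    left/right screen sides.
    """
    n = len(pairs)
    if n == 0:
        return []
    swap = rng.random(n) < 0.5
    lefts = [b if s else a for (a, b), s in zip(pairs, swap)]
    rights = [a if s else b for (a, b), s in zip(pairs, swap)]

    def pack(options):
        ms = np.zeros((n, 2))
        ps = np.zeros((n, 2))
        for i, opt in enumerate(options):
            for j, (m, p) in enumerate(opt.outcomes):
                ms[i, j] = m
                ps[i, j] = p
        return ms, ps

    ms_l, ps_l = pack(lefts)
    ms_r, ps_r = pack(rights)
    u_l = agent.utility_of_ml(ms_l, current)
    u_r = agent.utility_of_ml(ms_r, current)
    eu_l = np.sum(ps_l * u_l, axis=1)
    eu_r = np.sum(ps_r * u_r, axis=1)
    p_left = expit(agent.temperature * (eu_l - eu_r) + agent.side_bias)
    chose_left = rng.random(n) < p_left
    return [
        ChoiceTrial(
            session_id=session_id,
            day_index=day_index,
            distribution=current.label,
            left=lefts[i],
            right=rights[i],
            chosen="left" if chose_left[i] else "right",
            sequence_tag=sequence_tag,
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class FractileConfig:
    """Knobs of the fractile elicitation sequence generator."""

    step_ml: float = 0.05  # safe-ladder increment
    repeats: int = 4  # presentations per gamble/safe pair
    min_pairs: int = 3  # distinct rungs needed for a CE fit
    ladder_margin_steps: int = 1  # rungs beyond the gamble range, each side


@dataclass
class FractileSession:
    """One generated fractile session with its simulated CE chain."""

    trials: list[ChoiceTrial] = field(default_factory=list)
    ce_by_level: dict[float, float] = field(default_factory=dict)
    degenerate: bool = False
    reason: str | None = None


def _ladder(
    gamble: RewardOption, dist: RewardDistribution, cfg: FractileConfig
) -> list[float]:
    """Safe rungs: 0.05-ml multiples (anchored at the distribution minimum)
    spanning the gamble's outcome range plus a margin, clipped to the
    distribution."""
    lo = min(m for m, _ in gamble.outcomes)
    hi = max(m for m, _ in gamble.outcomes)
    margin = cfg.ladder_margin_steps * cfg.step_ml
    n_steps = int(round(dist.range_ml / cfg.step_ml))
    rungs = [dist.min_ml + k * cfg.step_ml for k in range(n_steps + 1)]
    kept = [r for r in rungs if lo - margin - 1e-9 <= r <= hi + margin + 1e-9]
    return [round(r, 9) for r in kept]


def _elicit_ce(
    agent: AgentConfig,
    gamble: RewardOption,
    dist: RewardDistribution,
    cfg: FractileConfig,
    rng: np.random.Generator,
    session_id: str,
    day_index: int,
    tag: str,
) -> tuple[list[ChoiceTrial], float | None, str | None]:
    """Simulate one gamble's ladder block and read its CE off the fitted
    psychometric inflection (continuous, not snapped to the 0.05-ml grid)."""
    rungs = _ladder(gamble, dist, cfg)
    if len(rungs) < cfg.min_pairs:
        return [], None, f"ladder has {len(rungs)} rungs (< {cfg.min_pairs})"
    pairs = [(gamble, RewardOption.safe(r)) for r in rungs for _ in range(cfg.repeats)]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    trials = simulate_choices(agent, pairs, dist, rng, session_id, day_index, tag)
    try:
        fit = fit_psychometric(
            choice_ratios(trials, gamble),
            min_points=cfg.min_pairs,
            min_repeats=min(cfg.repeats, 4),
        )
    except PsychometricError as err:
        return trials, None, str(err)
    ce = fit.x0
    half = cfg.step_ml / 2.0
    if ce < dist.min_ml + half or ce > dist.max_ml - half:
        return trials, None, f"CE {ce:.3f} ml within half a step of a bound"
    return trials, ce, None


def generate_fractile_session(
    agent: AgentConfig,
    dist: RewardDistribution,
    day_index: int = 0,
    config: FractileConfig | None = None,
    session_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> FractileSession:
    """Generate one three-step fractile session.

    Step 1 pairs the (min, max) equiprobable gamble against the safe ladder;
    the simulated CE (utility 0.5) seeds step 2's gambles (min, CE) and
    (CE, max), whose trials are interwoven in a single sequence; step 3
    chains once more to utilities 0.125 and 0.875.  A simulated CE landing
    within half a ladder step of a distribution bound marks the session
    degenerate and stops the chain.
    """
    cfg = config or FractileConfig()
    rng = rng if rng is not None else day_rng(agent.seed, day_index)
    sid = session_id or f"sim-{dist.label}-d{day_index}"
    session = FractileSession()

    g1 = RewardOption.gamble(dist.min_ml, dist.max_ml)
    trials, ce_mid, reason = _elicit_ce(
        agent, g1, dist, cfg, rng, sid, day_index, "fractile_step1"
    )
    session.trials.extend(trials)
    if ce_mid is None:
        session.degenerate, session.reason = True, f"step 1: {reason}"
        return session
    session.ce_by_level[0.5] = ce_mid

    # step 2: both gambles interwoven in one sequence
    g_lo = RewardOption.gamble(dist.min_ml, round(ce_mid, 9))
    g_hi = RewardOption.gamble(round(ce_mid, 9), dist.max_ml)
    step2: dict[float, float] = {}
    block: list[tuple[RewardOption, RewardOption]] = []
    for g in (g_lo, g_hi):
        rungs = _ladder(g, dist, cfg)
        block += [(g, RewardOption.safe(r)) for r in rungs for _ in range(cfg.repeats)]
    order = rng.permutation(len(block))
    block = [block[i] for i in order]
    trials2 = simulate_choices(
        agent, block, dist, rng, sid, day_index, "fractile_step2"
    )
    session.trials.extend(trials2)
    for g, level in ((g_lo, 0.25), (g_hi, 0.75)):
        try:
            fit = fit_psychometric(
                choice_ratios(trials2, g),
                min_points=cfg.min_pairs,
                min_repeats=min(cfg.repeats, 4),
            )
        except PsychometricError as err:
            session.degenerate, session.reason = True, f"step 2 ({level}): {err}"
            continue
        half = cfg.step_ml / 2.0
        if fit.x0 < dist.min_ml + half or fit.x0 > dist.max_ml - half:
            session.degenerate = True
            session.reason = f"step 2 ({level}): CE near a distribution bound"
            continue
        step2[level] = fit.x0
        session.ce_by_level[level] = fit.x0

    # step 3: chained from the step-2 CEs
    step3_gambles = []
    if 0.25 in step2:
        step3_gambles.append(
            (RewardOption.gamble(dist.min_ml, round(step2[0.25], 9)), 0.125)
        )
    if 0.75 in step2:
        step3_gambles.append(
            (RewardOption.gamble(round(step2[0.75], 9), dist.max_ml), 0.875)
        )
    block = []
    for g, _level in step3_gambles:
        rungs = _ladder(g, dist, cfg)
        block += [(g, RewardOption.safe(r)) for r in rungs for _ in range(cfg.repeats)]
    if block:
        order = rng.permutation(len(block))
        block = [block[i] for i in order]
        trials3 = simulate_choices(
            agent, block, dist, rng, sid, day_index, "fractile_step3"
        )
        session.trials.extend(trials3)
        for g, level in step3_gambles:
            try:
                fit = fit_psychometric(
                    choice_ratios(trials3, g),
                    min_points=cfg.min_pairs,
                    min_repeats=min(cfg.repeats, 4),
                )
            except PsychometricError:
                continue
            if dist.contains(fit.x0):
                session.ce_by_level[level] = fit.x0
    return session


def generate_validation_session(
    agent: AgentConfig,
    dist: RewardDistribution,
    day_index: int = 0,
    config: FractileConfig | None = None,
    session_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[ChoiceTrial]:
    """Generate a validation sequence: each of the four equivariant gambles
    paired against its safe ladder, all interwoven."""
    cfg = config or FractileConfig()
    rng = rng if rng is not None else day_rng(agent.seed, day_index)
    sid = session_id or f"sim-{dist.label}-val-d{day_index}"
    block = []
    for g in design_gambles(dist):
        rungs = _ladder(g, dist, cfg)
        block += [(g, RewardOption.safe(r)) for r in rungs for _ in range(cfg.repeats)]
    order = rng.permutation(len(block))
    block = [block[i] for i in order]
    return simulate_choices(agent, block, dist, rng, sid, day_index, "validation")


def random_gamble_safe_pairs(
    dist: RewardDistribution, n: int, rng: np.random.Generator
) -> list[tuple[RewardOption, RewardOption]]:
    """Random equiprobable gambles vs. random safes spanning the range.

    A generic trial template for parameter-recovery studies: outcomes drawn
    uniformly in the distribution, which identifies the utility curve over
    its whole domain.
    """
    lo, hi = dist.min_ml, dist.max_ml
    out = []
    for _ in range(n):
        a, b = np.sort(rng.uniform(lo, hi, size=2))
        safe = rng.uniform(lo, hi)
        out.append((RewardOption.gamble(float(a), float(b)), RewardOption.safe(float(safe))))
    return out
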