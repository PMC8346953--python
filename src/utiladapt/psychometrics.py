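"""Certainty-equivalent estimation and fractile bookkeeping.

The certainty equivalent (CE) of a gamble is the safe magnitude chosen with
probability 0.5 against it.  It is read off a logistic psychometric function
fitted to the proportion of safe choices at each tested safe magnitude:

    P(choose safe) = 1 / (1 + exp(-(safe_ml - x0) / sigma))

with inflection x0 (the CE) and temperature sigma.  The default objective is
binomial maximum likelihood on the per-safe counts, which weights unequally
sampled rungs correctly; an unweighted least-squares mode on the raw ratios
is available via ``method="ls"``.

The fractile (bisection) procedure chains CEs into a utility ladder: the CE
of the (min, max) gamble carries utility 0.5; gambles built between min and
that CE, and between the CE and max, yield CEs at utilities 0.25 and 0.75;
one further step yields 0.125 and 0.875.  Sessions in which fewer than three
utility levels can be reliably estimated are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .distributions import RewardDistribution, RewardOption
from .trials import ChoiceTrial

__all__ = [
    "PsychometricFit",
    "CEPoint",
    "PsychometricError",
    "InsufficientDataError",
    "DegenerateFitError",
    "choice_ratios",
    "fit_psychometric",
    "run_fractile",
    "normalize_ce",
    "STEP_LEVELS",
]

# utility levels produced by each fractile step
STEP_LEVELS = {1: (0.5,), 2: (0.25, 0.75), 3: (0.125, 0.875)}


class PsychometricError(RuntimeError):
    """Base class for psychometric-fit failures."""


class InsufficientDataError(PsychometricError):
    """Fewer distinct/repeated safe rungs than the elicitation filter allows."""


class DegenerateFitError(PsychometricError):
    """Flat choice ratios (sigma at its upper bound); no CE can be read off."""


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic psychometric curve for one gamble."""

    x0: float
    sigma: float
    n_points: int
    deviance: float

    def prob_safe(self, safe_ml):
        z = (np.asarray(safe_ml, dtype=float) - self.x0) / self.sigma
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CEPoint:
    """A certainty equivalent tied to a gamble and an assigned utility level."""

    gamble: RewardOption
    ce_ml: float
    utility_level: float
    step: int
    day_index: int
    session_id: str
    distribution: str
    x0: float
    sigma: float


def choice_ratios(
    trials: list[ChoiceTrial], gamble: RewardOption
) -> list[tuple[float, float, int]]:
    """Aggregate safe-choice proportions per distinct safe magnitude.

    Returns rows ``(safe_ml, proportion_safe, n)`` sorted by safe magnitude,
    over trials that pair `gamble` against a safe option.
    """
    counts: dict[float, list[int]] = {}
    for t in trials:
        if t.left.is_safe == t.right.is_safe:
            continue
        safe, risky = (t.left, t.right) if t.left.is_safe else (t.right, t.left)
        if risky != gamble:
            continue
        chose_safe = (t.chosen == "left") == t.left.is_safe
        m = round(safe.outcomes[0][0], 9)
        n_safe, n_tot = counts.setdefault(m, [0, 0])
        counts[m][0] = n_safe + int(chose_safe)
        counts[m][1] = n_tot + 1
    if not counts:
        raise PsychometricError("no trials pair the given gamble against safe options")
    return [(m, counts[m][0] / counts[m][1], counts[m][1]) for m in sorted(counts)]


def _nll(params, safes, k, n):
    x0, log_sigma = params
    sigma = math.exp(log_sigma)
    z = (safes - x0) / sigma
    # log(1+e^-z) and log(1+e^z), stable
    log_p = -np.logaddexp(0.0, -z)
    log_q = -np.logaddexp(0.0, z)
    return -float(np.sum(k * log_p + (n - k) * log_q))


def fit_psychometric(
    ratios: list[tuple[float, float, int]],
    method: str = "ml",
    min_points: int = 3,
    min_repeats: int = 4,
) -> PsychometricFit:
    """Fit the two-parameter logistic psychometric curve to choice ratios.

    Parameters
    ----------
    ratios
        Rows ``(safe_ml, proportion_safe, n)`` from :func:`choice_ratios`.
    method
        ``"ml"`` (binomial maximum likelihood, default) or ``"ls"``
        (unweighted least squares on the proportions).
    min_points, min_repeats
        Elicitation filter: at least `min_points` distinct safe magnitudes,
        each presented at least `min_repeats` times.
    """
    rows = [r for r in ratios if r[2] >= min_repeats]
    if len(rows) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} safe magnitudes repeated >= {min_repeats} times, "
            f"have {len(rows)}"
        )
    safes = np.array([r[0] for r in rows])
    props = np.array([r[1] for r in rows])
    n = np.array([r[2] for r in rows], dtype=float)
    k = props * n

    span = float(safes.max() - safes.min())
    if span <= 0:
        raise InsufficientDataError("all safe magnitudes identical")
    sigma_hi = 10.0 * span
    bounds = [
        (safes.min() - span, safes.max() + span),
        (math.log(1e-4), math.log(sigma_hi)),
    ]

    # init: x0 at the empirical 50% crossing, sigma at a quarter of the range
    crossing = np.interp(0.5, props, safes) if props[-1] > props[0] else float(
        np.median(safes)
    )
    x0_init = float(np.clip(crossing, *bounds[0]))
    starts = [(x0_init, math.log(span / 4.0))]
    rng = np.random.default_rng(0)
    starts += [
        (
            float(np.clip(x0_init + rng.normal(0, span / 4), *bounds[0])),
            float(np.clip(math.log(span / 4) + rng.normal(0, 1), *bounds[1])),
        )
        for _ in range(3)
    ]

    if method == "ml":
        objective = lambda p: _nll(p, safes, k, n)
    elif method == "ls":
        def objective(p):
            x0, log_sigma = p
            pred = 1.0 / (1.0 + np.exp(-(safes - x0) / math.exp(log_sigma)))
            return float(np.sum((pred - props) ** 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    best = None
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and best.fun == res.fun:
            continue
    if best is None or not np.isfinite(best.fun):
        raise PsychometricError("psychometric fit failed to converge")

    x0, sigma = float(best.x[0]), float(math.exp(best.x[1]))
    if sigma >= 0.99 * sigma_hi:
        raise DegenerateFitError(
            f"sigma hit its upper bound ({sigma:.3g} ml); choice ratios are flat"
        )
    return PsychometricFit(x0=x0, sigma=sigma, n_points=len(rows),
                           deviance=float(best.fun))


def normalize_ce(ce_ml: float, distribution: RewardDistribution) -> float:
    """Normalize a CE relative to the distribution's min/max anchors."""
    return distribution.normalize(ce_ml)


def _fit_gamble_ce(trials, gamble, ladder_step, distribution,
                   min_points, min_repeats, method):
    ratios = choice_ratios(trials, gamble)
    fit = fit_psychometric(ratios, method=method, min_points=min_points,
                           min_repeats=min_repeats)
    safes = [r[0] for r in ratios]
    # CE clamping rule: an inflection more than one ladder step outside the
    # tested rungs cannot be trusted for chaining.
    if fit.x0 < min(safes) - ladder_step or fit.x0 > max(safes) + ladder_step:
        raise DegenerateFitError(
            f"fitted x0={fit.x0:.3f} ml falls outside the tested ladder"
        )
    if not distribution.contains(fit.x0):
        raise DegenerateFitError(f"fitted x0={fit.x0:.3f} ml outside the distribution")
    return fit


def run_fractile(
    trials: list[ChoiceTrial],
    distribution: RewardDistribution,
    ladder_step: float = 0.05,
    min_points: int = 3,
    min_repeats: int = 4,
    min_levels: int = 3,
    method: str = "ml",
) -> list[CEPoint]:
    """Run fractile bookkeeping on one session's tagged trials.

    Trials must carry ``sequence_tag`` in {fractile_step1, fractile_step2,
    fractile_step3}.  Gambles are identified by their outcome tuples; each
    step's gambles are fitted separately and CEs are assigned utility levels
    by the gamble's position in the chain (below/above the previous CE).

    Returns one :class:`CEPoint` per reliably estimated level, or raises
    :class:`PsychometricError` if fewer than `min_levels` levels survive.
    """
    if not trials:
        raise PsychometricError("empty trial list")
    by_step: dict[int, dict[RewardOption, list[ChoiceTrial]]] = {1: {}, 2: {}, 3: {}}
    for t in trials:
        if not t.sequence_tag.startswith("fractile_step"):
            continue
        step = int(t.sequence_tag[-1])
        risky = t.right if t.left.is_safe else t.left
        by_step[step].setdefault(risky, []).append(t)

    if not by_step[1]:
        raise PsychometricError("no step-1 trials; fractile chain cannot start")

    meta = dict(day_index=trials[0].day_index, session_id=trials[0].session_id,
                distribution=trials[0].distribution)
    points: list[CEPoint] = []

    def try_fit(step_trials, gamble, level, step):
        try:
            fit = _fit_gamble_ce(step_trials, gamble, ladder_step, distribution,
                                 min_points, min_repeats, method)
        except PsychometricError:
            return None
        points.append(CEPoint(gamble=gamble, ce_ml=fit.x0, utility_level=level,
                              step=step, x0=fit.x0, sigma=fit.sigma, **meta))
        return fit.x0

    (g1, t1), = by_step[1].items()
    ce_mid = try_fit(t1, g1, 0.5, 1)
    if ce_mid is None:
        raise PsychometricError("step-1 CE could not be estimated")

    # step 2: gamble between min and the step-1 CE -> 0.25; CE..max -> 0.75
    ce_by_level = {0.5: ce_mid}
    for gamble, g_trials in by_step[2].items():
        lo, hi = gamble.outcomes[0][0], gamble.outcomes[1][0]
        level = 0.25 if hi <= ce_mid + 1e-9 else 0.75
        ce = try_fit(g_trials, gamble, level, 2)
        if ce is not None:
            ce_by_level[level] = ce

    # step 3: gambles built from the step-2 CEs
    for gamble, g_trials in by_step[3].items():
        hi = gamble.outcomes[1][0]
        level = 0.125 if hi <= ce_mid + 1e-9 else 0.875
        try_fit(g_trials, gamble, level, 3)

    if len(points) < min_levels:
        raise PsychometricError(
            f"only {len(points)} utility levels reliably estimated "
            f"(< {min_levels}); session discarded"
        )
    return sorted(points, key=lambda p: p.utility_level)
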