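"""Quantifying utility adaptation across reward distributions.

Two coefficients summarize how a decision-maker's utility function responds
when the available reward range changes:

SAC (sequential adaptation coefficient)
    Relative change in the area under consecutive normalized utilities,
    SAC = (CR_n - CR_{n-1}) / CR_{n-1}.  Zero when the normalized shape is
    unchanged (full adaptation); negative when the new utility is more
    convex (more risk-seeking), positive when more concave.

GAC (general adaptation coefficient)
    Places a narrow-range utility between two constructions on the full
    range: the full-range utility itself (no adaptation: the narrow utility
    is just a segment of one absolute curve, GAC = 0) and a rescaled copy of
    the full-range utility squeezed into the narrow domain and image (full
    adaptation, GAC = 1),

        GAC = (int U_partial - int U_full) / (int U_adapt - int U_full),

    integrals over the narrow sub-interval of the normalized full domain.
    The narrow utility's image slots are anchored to the full curve:
    mapping [a, b] (the narrow range in normalized full space) onto image
    [U_full(a), U_full(b)] — for the lower half-range this is
    [0, U_full(b)], for the upper half [U_full(a), 1], exactly the anchoring
    the half-range task design prescribes.

A Monte-Carlo procedure checks that the whole estimation chain (fractile
simulation -> daily DCM fits -> median parameters -> GAC) returns GAC near 0
for a non-adapting ground-truth agent and near 1 for a fully adapting one.

Inflection points are compared across ranges by preserving their relative
position (affine rescaling), clipping into the target range when the mapped
value would leave it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .agent import AgentConfig, FractileConfig, day_rng, generate_fractile_session
from .dcm import DCMFit, FitError, fit_dcm
from .distributions import RewardDistribution
from .models import PARAM_NAMES, UtilityCurve, curvature_ratio

__all__ = [
    "AdaptationReport",
    "UndefinedGACError",
    "median_curve",
    "rescale_inflection",
    "sac",
    "build_adapted_template",
    "gac",
    "monte_carlo_no_adaptation",
    "MonteCarloResult",
]

_QUAD_POINTS = 10_001


class UndefinedGACError(RuntimeError):
    """The full curve is self-similar on the segment (zero denominator)."""


def median_curve(fits: list[DCMFit]) -> UtilityCurve:
    """Parameter-wise median of daily estimates (not a pointwise median)."""
    fits = [f for f in fits if f.excluded_reason is None]
    if not fits:
        raise ValueError("no non-excluded fits")
    families = {f.family for f in fits}
    if len(families) > 1:
        raise ValueError(f"mixed families: {sorted(families)}")
    family = fits[0].family
    stacked = np.array([f.params.utility.params for f in fits])
    return UtilityCurve(family, tuple(float(v) for v in np.median(stacked, axis=0)))


def rescale_inflection(
    inflection_ml: float,
    from_dist: RewardDistribution,
    to_dist: RewardDistribution,
) -> tuple[float, bool]:
    """Map an inflection to another range preserving its relative position.

    Returns ``(value_ml, clipped)``; values landing outside the target range
    are set to the nearer bound with ``clipped=True``.
    """
    rel = (inflection_ml - from_dist.min_ml) / from_dist.range_ml
    value = to_dist.min_ml + rel * to_dist.range_ml
    clipped = value < to_dist.min_ml or value > to_dist.max_ml
    return float(np.clip(value, to_dist.min_ml, to_dist.max_ml)), bool(clipped)


def sac(curve_n: Callable, curve_prev: Callable) -> float:
    """Sequential adaptation coefficient: relative change in curvature ratio
    between consecutive normalized utilities."""
    cr_prev = curvature_ratio(curve_prev, n_grid=_QUAD_POINTS)
    cr_n = curvature_ratio(curve_n, n_grid=_QUAD_POINTS)
    if cr_prev <= 0:
        raise ValueError("previous curve has non-positive area")
    return (cr_n - cr_prev) / cr_prev


def _segment(
    narrow_dist: RewardDistribution, full_dist: RewardDistribution
) -> tuple[float, float]:
    if not (
        full_dist.min_ml - 1e-9 <= narrow_dist.min_ml
        and narrow_dist.max_ml <= full_dist.max_ml + 1e-9
    ):
        raise ValueError(
            f"narrow range [{narrow_dist.min_ml}, {narrow_dist.max_ml}] not inside "
            f"full range [{full_dist.min_ml}, {full_dist.max_ml}]"
        )
    a = full_dist.normalize(narrow_dist.min_ml)
    b = full_dist.normalize(narrow_dist.max_ml)
    return a, b


def build_adapted_template(
    full_curve: Callable,
    narrow_dist: RewardDistribution,
    full_dist: RewardDistribution,
) -> Callable:
    """Rescale the full-range utility into the narrow domain and image.

    On the narrow sub-interval [a, b] of normalized full space,
    U_adapt(x) = c + (d - c) * U_full((x - a)/(b - a)) with image slots
    [c, d] = [U_full(a), U_full(b)].
    """
    a, b = _segment(narrow_dist, full_dist)
    c = float(full_curve(a))
    d = float(full_curve(b))

    def u_adapt(x):
        u = np.clip((np.asarray(x, dtype=float) - a) / (b - a), 0.0, 1.0)
        out = c + (d - c) * np.asarray(full_curve(u), dtype=float)
        return float(out) if np.isscalar(x) else out

    return u_adapt


def _embed_narrow(
    narrow_curve: Callable, a: float, b: float, c: float, d: float
) -> Callable:
    # narrow utility mapped into full space with the template's image slots
    def u_partial(x):
        u = np.clip((np.asarray(x, dtype=float) - a) / (b - a), 0.0, 1.0)
        out = c + (d - c) * np.asarray(narrow_curve(u), dtype=float)
        return float(out) if np.isscalar(x) else out

    return u_partial


def gac(
    narrow_curve: Callable,
    full_curve: Callable,
    narrow_dist: RewardDistribution,
    full_dist: RewardDistribution,
) -> float:
    """General adaptation coefficient of a narrow-range utility.

    0 when the narrow utility coincides with the full curve's segment,
    1 when it is the fully rescaled template; raises
    :class:`UndefinedGACError` when the full curve is affinely self-similar
    on the segment (e.g. linear), which makes the denominator vanish.
    """
    a, b = _segment(narrow_dist, full_dist)
    c = float(full_curve(a))
    d = float(full_curve(b))
    xs = np.linspace(a, b, _QUAD_POINTS)

    u_partial = _embed_narrow(narrow_curve, a, b, c, d)
    u_adapt = build_adapted_template(full_curve, narrow_dist, full_dist)

    int_full = np.trapezoid(np.asarray(full_curve(xs), dtype=float), xs)
    int_adapt = np.trapezoid(u_adapt(xs), xs)
    int_partial = np.trapezoid(u_partial(xs), xs)

    denom = int_adapt - int_full
    if abs(denom) < 1e-9:
        raise UndefinedGACError(
            "full curve is self-similar on the narrow segment; GAC is undefined"
        )
    return float((int_partial - int_full) / denom)


@dataclass(frozen=True)
class AdaptationReport:
    """Per-distribution shape metrics and adaptation coefficients."""

    median_curves: dict[str, UtilityCurve]
    inflection_ml: dict[str, float | None]
    curvature_ratio: dict[str, float]
    sac: dict[str, float]  # keyed "prev->next"
    gac: dict[str, float | None]  # keyed by narrow label; None = undefined
    predicted_inflections: dict[str, tuple[float, bool]]  # rescaled, clip flag


@dataclass
class MonteCarloResult:
    """Rep-level GAC/SAC draws from the simulated estimation chain."""

    gac_by_dist: dict[str, np.ndarray]
    sac_by_dist: dict[str, np.ndarray]
    refit_failures: int = 0
    n_reps: int = 0
    params_by_dist: dict[str, list] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for label, vals in self.gac_by_dist.items():
            out[label] = {
                "gac_median": float(np.median(vals)),
                "gac_p2.5": float(np.percentile(vals, 2.5)),
                "gac_p97.5": float(np.percentile(vals, 97.5)),
                "sac_median": float(np.median(self.sac_by_dist[label])),
            }
        return out


def monte_carlo_no_adaptation(
    full_curve: UtilityCurve,
    narrow_dists: list[RewardDistribution],
    full_dist: RewardDistribution,
    n_reps: int = 1000,
    days_per_dist: int = 5,
    seed: int = 0,
    temperature: float = 10.0,
    side_bias: float = 0.0,
    adaptation_mode: str = "none",
    fit_family: str = "prelec2",
    fractile_config: FractileConfig | None = None,
    n_starts: int = 3,
) -> MonteCarloResult:
    """Simulate the whole estimation chain under a known adaptation regime.

    For each rep and each narrow distribution: simulate `days_per_dist`
    fractile sessions of an agent whose ground-truth utility is the
    full-range `full_curve` (non-adapting by default; set
    ``adaptation_mode="full"`` for the fully adapting control), fit the DCM
    per day, take the parameter-wise median, and compute GAC/SAC against the
    full curve.  Returns the rep-level coefficient draws.
    """
    cfg = fractile_config or FractileConfig()
    gac_by = {d.label: [] for d in narrow_dists}
    sac_by = {d.label: [] for d in narrow_dists}
    failures = 0
    root = np.random.SeedSequence([seed, 777])
    rep_seeds = root.generate_state(n_reps * 2)[: n_reps]

    for rep in range(n_reps):
        rep_seed = int(rep_seeds[rep]) % (2**31 - 1)
        agent = AgentConfig(
            utility=full_curve,
            temperature=temperature,
            side_bias=side_bias,
            adaptation_mode=adaptation_mode,
            reference=full_dist,
            seed=rep_seed,
        )
        for dist in narrow_dists:
            daily = []
            for day in range(days_per_dist):
                rng = day_rng(rep_seed, day)
                sess = generate_fractile_session(
                    agent, dist, day_index=day, config=cfg, rng=rng
                )
                if not sess.trials:
                    continue
                try:
                    fit = fit_dcm(
                        sess.trials,
                        fit_family,
                        dist,
                        n_starts=n_starts,
                        seed=rep_seed + day,
                    )
                except FitError:
                    failures += 1
                    continue
                daily.append(fit)
            if not daily:
                failures += 1
                continue
            narrow = median_curve(daily)
            try:
                g = gac(narrow, full_curve, dist, full_dist)
            except UndefinedGACError:
                g = np.nan
            gac_by[dist.label].append(g)
            sac_by[dist.label].append(sac(narrow, full_curve))

    result = MonteCarloResult(
        gac_by_dist={k: np.array(v) for k, v in gac_by.items()},
        sac_by_dist={k: np.array(v) for k, v in sac_by.items()},
        refit_failures=failures,
        n_reps=n_reps,
    )
    expected = n_reps * len(narrow_dists) * days_per_dist
    if expected and failures > 0.2 * expected:
        import warnings

        warnings.warn(
            f"{failures} refit failures out of {expected} day-fits",
            RuntimeWarning,
            stacklevel=2,
        )
    return result
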