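"""Parametric utility families on the normalized reward domain [0, 1].

Five families are provided, all mapping normalized magnitude m in [0, 1] to
utility in [0, 1] and anchored at U(0) = 0, U(1) = 1:

``power1``
    U(m) = m**alpha.  Purely convex (alpha < 1, risk-seeking) or concave
    (alpha > 1, risk-averse); no interior inflection.
``tversky1``
    U(m) = m**g / (m**g + (1-m)**g)**(1/g), the classic one-parameter
    inverse-S form transplanted from probability weighting to magnitude.
    This family's exact published form is not written out in the source
    literature; the implementation here is a reconstruction of the standard
    form.  gamma < 1 gives an inverse-S, gamma > 1 an S-shape.
``prelec2``
    U(m) = exp(-beta * (-ln m)**alpha).  Monotone; behaves as the power law
    m**beta when alpha = 1, S-shaped when alpha > 1, inverse-S when
    alpha < 1.  Defined at m = 0 by its limit, U(0) = 0.
``scdf2``
    CDF of the two-sided power distribution with knot beta and curvature
    alpha:  U(m) = beta*(m/beta)**alpha for m <= beta, else
    1 - (1-beta)*((1-m)/(1-beta))**alpha.  alpha > 1 is S-shaped with the
    inflection exactly at the knot.
``power3``
    Two-branch power function around a reference point gamma,
    raw(m) = (m-gamma)**alpha for m >= gamma, -beta*(gamma-m)**alpha below,
    affinely rescaled so that U(0) = 0 and U(1) = 1 (the raw form is not
    intrinsically anchored).  beta is a loss-aversion weight; it defaults to
    1 when fitting gains-only data.

The module also computes the two shape metrics used to compare utilities
across reward distributions: the interior inflection point (where curvature
reverses and the first derivative peaks) and the curvature ratio (CR), the
area under the curve on the normalized unit square.  CR > 0.5 means net
concavity (risk aversion), CR < 0.5 net convexity (risk seeking); a linear
utility has CR = 0.5 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .distributions import RewardDistribution

__all__ = [
    "UtilityCurve",
    "ShapeMetrics",
    "FAMILIES",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "curvature_ratio",
    "to_ml",
]

# m is clamped here before taking logs; U(0) is defined by limit.
_EPS_M = 1e-12

# Parameter names and bounds, per family.  Bounds keep every curve monotone,
# finite and identifiable.
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "power1": ("alpha",),
    "tversky1": ("gamma",),
    "prelec2": ("alpha", "beta"),
    "scdf2": ("alpha", "beta"),
    "power3": ("alpha", "beta", "gamma"),
}

PARAM_BOUNDS: dict[str, tuple[tuple[float, float], ...]] = {
    "power1": ((0.05, 20.0),),
    # below gamma ~ 0.28 the Tversky form loses monotonicity
    "tversky1": ((0.3, 5.0),),
    "prelec2": ((0.05, 20.0), (0.05, 20.0)),
    "scdf2": ((0.05, 20.0), (0.01, 0.99)),
    "power3": ((0.05, 20.0), (0.0, 10.0), (0.0, 1.0)),
}

FAMILIES = tuple(PARAM_NAMES)


def _eval_power1(m: np.ndarray, alpha: float) -> np.ndarray:
    return m**alpha


def _eval_tversky1(m: np.ndarray, gamma: float) -> np.ndarray:
    num = m**gamma
    den = (num + (1.0 - m) ** gamma) ** (1.0 / gamma)
    return num / den


def _eval_prelec2(m: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    mc = np.clip(m, _EPS_M, 1.0)
    out = np.exp(-beta * (-np.log(mc)) ** alpha)
    # anchor the singular endpoint by its limit
    return np.where(m <= 0.0, 0.0, out)


def _eval_scdf2(m: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    lower = beta * (np.minimum(m, beta) / beta) ** alpha
    upper = 1.0 - (1.0 - beta) * ((1.0 - np.maximum(m, beta)) / (1.0 - beta)) ** alpha
    return np.where(m <= beta, lower, upper)


def _eval_power3(m: np.ndarray, alpha: float, beta: float, gamma: float) -> np.ndarray:
    def raw(x: np.ndarray) -> np.ndarray:
        above = np.maximum(x - gamma, 0.0) ** alpha
        below = -beta * np.maximum(gamma - x, 0.0) ** alpha
        return np.where(x >= gamma, above, below)

    lo, hi = raw(np.asarray(0.0)), raw(np.asarray(1.0))
    # beta=0 with gamma=1 makes the raw form identically zero; the clamp
    # turns it into a (terrible-fitting) flat curve instead of NaNs
    denom = max(float(hi - lo), 1e-12)
    return (raw(m) - lo) / denom


_EVALUATORS: dict[str, Callable[..., np.ndarray]] = {
    "power1": _eval_power1,
    "tversky1": _eval_tversky1,
    "prelec2": _eval_prelec2,
    "scdf2": _eval_scdf2,
    "power3": _eval_power3,
}


@dataclass(frozen=True)
class ShapeMetrics:
    """Inflection location (normalized and in ml) and curvature ratio."""

    inflection_norm: float | None
    inflection_ml: float | None
    curvature_ratio: float


@dataclass(frozen=True)
class UtilityCurve:
    """A parametric utility family with parameter values, on [0, 1]."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _EVALUATORS:
            raise ValueError(f"unknown utility family {self.family!r}")
        names = PARAM_NAMES[self.family]
        if len(self.params) != len(names):
            raise ValueError(
                f"{self.family} takes {len(names)} parameters {names}, "
                f"got {len(self.params)}"
            )
        for name, value, (lo, hi) in zip(names, self.params, PARAM_BOUNDS[self.family]):
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{self.family} parameter {name}={value} outside bounds [{lo}, {hi}]"
                )

    def __call__(self, m):
        """Evaluate utility at normalized magnitude(s) m in [0, 1]."""
        arr = np.asarray(m, dtype=float)
        if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError("magnitude outside the normalized domain [0, 1]")
        arr = np.clip(arr, 0.0, 1.0)
        out = _EVALUATORS[self.family](arr, *self.params)
        return float(out) if np.isscalar(m) else out

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def inflection(self) -> float | None:
        """Interior point where curvature reverses, or None if it never does."""
        return _inflection(self)

    def curvature_ratio(self, n_grid: int = 10_001) -> float:
        return curvature_ratio(self, n_grid=n_grid)

    def shape_metrics(
        self, distribution: RewardDistribution | None = None
    ) -> ShapeMetrics:
        infl = self.inflection()
        infl_ml = (
            to_ml(infl, distribution)
            if (infl is not None and distribution is not None)
            else None
        )
        return ShapeMetrics(infl, infl_ml, self.curvature_ratio())


def curvature_ratio(curve: Callable[[np.ndarray], np.ndarray], n_grid: int = 10_001) -> float:
    """Normalized area under a utility curve on [0, 1] (composite trapezoid).

    The total area of the normalized square is 1, so the integral itself is
    the curvature ratio.  Accepts any callable on [0, 1], not only
    :class:`UtilityCurve`.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    return float(np.trapezoid(np.asarray(curve(grid), dtype=float), grid))


def to_ml(value_norm: float, distribution: RewardDistribution) -> float:
    """Map a normalized metric back to ml within a reward distribution."""
    return distribution.denormalize(value_norm)


# ---------------------------------------------------------------------------
# Inflection finding


def _prelec2_inflection(alpha: float, beta: float) -> float | None:
    # With t = -ln m, sign(U'') = -sign(g(t)) where
    # g(t) = beta*alpha*t**alpha - t - (alpha - 1); the interior inflection is
    # the unique positive root of g (none when alpha = 1: power law).
    if abs(alpha - 1.0) < 1e-12:
        return None

    def g(t: float) -> float:
        return beta * alpha * t**alpha - t - (alpha - 1.0)

    t_max = -np.log(_EPS_M)
    ts = np.geomspace(1e-9, t_max, 20_001)
    vals = g(ts)
    signs = np.sign(vals)
    idx = np.nonzero(np.diff(signs) != 0)[0]
    if len(idx) == 0:
        return None
    if len(idx) > 1:
        raise RuntimeError(
            f"prelec2({alpha}, {beta}): multiple curvature sign changes found"
        )
    root = brentq(g, ts[idx[0]], ts[idx[0] + 1], xtol=1e-12)
    m = float(np.exp(-root))
    return m if 0.0 < m < 1.0 else None


def _numeric_inflection(
    curve: Callable, n_scan: int = 4001, h: float = 1e-4
) -> float | None:
    # Sign-change scan of central second differences, refined by brentq.
    xs = np.linspace(2 * h, 1.0 - 2 * h, n_scan)
    d2 = np.asarray(curve(xs - h)) - 2.0 * np.asarray(curve(xs)) + np.asarray(
        curve(xs + h)
    )
    signs = np.sign(d2)
    signs[np.abs(d2) < 1e-13] = 0  # float noise near the crossing
    nzi = np.nonzero(signs)[0]
    if len(nzi) == 0:
        return None
    changes = np.nonzero(np.diff(signs[nzi]) != 0)[0]
    if len(changes) == 0:
        return None
    if len(changes) > 1:
        raise RuntimeError("multiple curvature sign changes found")
    a = xs[nzi[changes[0]]]
    b = xs[nzi[changes[0] + 1]]

    def d2_at(x: float) -> float:
        return float(curve(x - h) - 2.0 * curve(x) + curve(x + h))

    return float(brentq(d2_at, a, b, xtol=1e-7))


def _inflection(curve: UtilityCurve) -> float | None:
    family, params = curve.family, curve.params
    if family == "power1":
        return None
    if family == "prelec2":
        return _prelec2_inflection(*params)
    if family == "scdf2":
        alpha, beta = params
        if abs(alpha - 1.0) < 1e-12:
            return None  # linear
        return beta if 0.0 < beta < 1.0 else None
    if family == "power3":
        alpha, _beta, gamma = params
        if abs(alpha - 1.0) < 1e-12:
            return None
        return gamma if 0.0 < gamma < 1.0 else None
    # tversky1: no closed form used; numeric scan
    return _numeric_inflection(curve)
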