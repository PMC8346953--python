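"""Out-of-sample risk-attitude validation.

Four equivariant, equiprobable gambles per reward distribution — each
spanning 30% of the range, centered at 25/45/65/85% of the range — are used
to measure certainty equivalents outside the fractile sequences.  The signed
difference CE − EV indicates risk attitude (positive: risk-seeking;
negative: risk-averse), and a linear regression

    CE − EV = beta0 + beta1 * (EV − inflection)

anchored at the fitted utility's inflection point validates the predicted
risk-attitude reversal: beta1 < 0 for S-shaped utilities (risk-seeking below
the inflection, risk-averse above), with beta0 the residual risk attitude at
the inflection itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .distributions import RewardDistribution, RewardOption

__all__ = [
    "ValidationPoint",
    "RegressionFit",
    "design_gambles",
    "risk_attitude",
    "fit_risk_regression",
    "CENTER_FRACTIONS",
    "SPREAD_FRACTION",
]

CENTER_FRACTIONS = (0.25, 0.45, 0.65, 0.85)
SPREAD_FRACTION = 0.30


@dataclass(frozen=True)
class ValidationPoint:
    """One out-of-sample gamble with its measured CE and risk attitude."""

    gamble: RewardOption
    ev_ml: float
    ce_ml: float
    risk_attitude: float  # ce - ev, ml
    ev_minus_inflection: float  # ml


@dataclass(frozen=True)
class RegressionFit:
    beta0: float
    beta1: float
    r_squared: float
    n_points: int


def design_gambles(
    distribution: RewardDistribution,
    centers: tuple[float, ...] = CENTER_FRACTIONS,
    spread_fraction: float = SPREAD_FRACTION,
) -> list[RewardOption]:
    """Design the equivariant validation gambles for a distribution.

    Each gamble is equiprobable two-outcome with outcome spread equal to
    `spread_fraction` of the range and center at each of `centers` (as
    fractions of the range).  Configurations whose outcomes would leave the
    distribution are refused.
    """
    rng_ml = distribution.range_ml
    spread = spread_fraction * rng_ml
    gambles = []
    for c in centers:
        center = distribution.min_ml + c * rng_ml
        lo, hi = center - spread / 2.0, center + spread / 2.0
        if lo < distribution.min_ml - 1e-9 or hi > distribution.max_ml + 1e-9:
            raise ValueError(
                f"gamble centered at {c:.0%} of the range with spread "
                f"{spread_fraction:.0%} leaves the distribution"
            )
        gambles.append(RewardOption.gamble(round(lo, 9), round(hi, 9)))
    return gambles


def risk_attitude(ce_ml: float, gamble: RewardOption) -> float:
    """Signed CE − EV in ml; positive means risk-seeking."""
    return ce_ml - gamble.ev_ml


def fit_risk_regression(
    points: list[ValidationPoint], inflection_ml: float
) -> RegressionFit:
    """OLS of CE − EV on EV − inflection (both in ml), pooled over points."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 validation points, have {len(points)}")
    x = np.array([p.ev_ml - inflection_ml for p in points])
    y = np.array([p.risk_attitude for p in points])
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate regression: all EVs coincide")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        r_squared=float(model.rsquared),
        n_points=len(points),
    )
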