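"""Reward distributions and reward options.

A *reward distribution* is the range of juice magnitudes (in ml) available in a
block of experimental sessions.  It supplies the normalization anchors used
throughout the pipeline: the minimum maps to utility 0 and the maximum to
utility 1.  A *reward option* is either a safe (guaranteed) magnitude or an
equiprobable two-outcome gamble.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RewardDistribution",
    "RewardOption",
    "LOW",
    "HIGH",
    "FULL",
    "FULL_ALT",
    "PRESETS",
]


@dataclass(frozen=True)
class RewardDistribution:
    """A named reward range in ml, defining the normalization anchors."""

    label: str
    min_ml: float
    max_ml: float

    def __post_init__(self) -> None:
        if not self.min_ml < self.max_ml:
            raise ValueError(
                f"min_ml must be < max_ml, got ({self.min_ml}, {self.max_ml})"
            )
        if self.min_ml < 0:
            raise ValueError(f"min_ml must be non-negative, got {self.min_ml}")

    @property
    def range_ml(self) -> float:
        return self.max_ml - self.min_ml

    def contains(self, m_ml: float, tol: float = 1e-9) -> bool:
        return self.min_ml - tol <= m_ml <= self.max_ml + tol

    def normalize(self, m_ml: float) -> float:
        """Affine map of a magnitude onto [0, 1] (min -> 0, max -> 1)."""
        if not self.contains(m_ml):
            raise ValueError(
                f"{m_ml} ml outside distribution [{self.min_ml}, {self.max_ml}]"
            )
        return (m_ml - self.min_ml) / self.range_ml

    def denormalize(self, x: float) -> float:
        """Inverse of :meth:`normalize`: [0, 1] -> ml."""
        return self.min_ml + x * self.range_ml


# Canonical presets used in the study design.
LOW = RewardDistribution("low", 0.0, 0.5)
HIGH = RewardDistribution("high", 0.5, 1.0)
FULL = RewardDistribution("full", 0.0, 1.0)
FULL_ALT = RewardDistribution("full", 0.1, 1.3)

PRESETS = {"low": LOW, "high": HIGH, "full": FULL}


@dataclass(frozen=True)
class RewardOption:
    """One choice option: a tuple of (magnitude_ml, probability) outcomes.

    Safe options have a single outcome at p = 1; gambles in this task are
    equiprobable two-outcome (each p = 0.5).
    """

    outcomes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        total_p = sum(p for _, p in self.outcomes)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities must sum to 1, got {total_p}")
        if any(p < 0 for _, p in self.outcomes):
            raise ValueError("outcome probabilities must be non-negative")

    @classmethod
    def safe(cls, m_ml: float) -> "RewardOption":
        return cls(((m_ml, 1.0),))

    @classmethod
    def gamble(cls, low_ml: float, high_ml: float, p_low: float = 0.5) -> "RewardOption":
        return cls(((low_ml, p_low), (high_ml, 1.0 - p_low)))

    @property
    def is_safe(self) -> bool:
        return len(self.outcomes) == 1

    @property
    def ev_ml(self) -> float:
        """Expected value in ml (probability-weighted mean of outcomes)."""
        return sum(m * p for m, p in self.outcomes)

    def within(self, dist: RewardDistribution, tol: float = 1e-9) -> bool:
        return all(dist.contains(m, tol) for m, _ in self.outcomes)
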