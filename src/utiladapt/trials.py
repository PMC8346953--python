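"""Trial records and their array representation.

A :class:`ChoiceTrial` is one binary decision between a left and a right
reward option, with the recorded choice.  :func:`trials_to_arrays` packs a
trial list into flat numpy arrays (normalized magnitudes, probabilities and
a chose-left indicator) for fast likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import RewardDistribution, RewardOption

__all__ = ["ChoiceTrial", "TrialArrays", "trials_to_arrays"]

SEQUENCE_TAGS = (
    "fractile_step1",
    "fractile_step2",
    "fractile_step3",
    "validation",
)


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary choice between two reward options."""

    session_id: str
    day_index: int
    distribution: str
    left: RewardOption
    right: RewardOption
    chosen: str  # "left" | "right"
    sequence_tag: str

    def __post_init__(self) -> None:
        if self.chosen not in ("left", "right"):
            raise ValueError(f"chosen must be 'left' or 'right', got {self.chosen!r}")
        if self.sequence_tag not in SEQUENCE_TAGS:
            raise ValueError(f"unknown sequence_tag {self.sequence_tag!r}")


@dataclass(frozen=True)
class TrialArrays:
    """Flat per-trial arrays, magnitudes normalized to [0, 1]."""

    m_left: np.ndarray  # (n, 2) normalized magnitudes (2nd col 0 for safes)
    p_left: np.ndarray  # (n, 2) probabilities (2nd col 0 for safes)
    m_right: np.ndarray
    p_right: np.ndarray
    chose_left: np.ndarray  # (n,) bool

    @property
    def n(self) -> int:
        return len(self.chose_left)


def _pack(option: RewardOption, dist: RewardDistribution) -> tuple[list, list]:
    ms = [dist.normalize(m) for m, _ in option.outcomes]
    ps = [p for _, p in option.outcomes]
    while len(ms) < 2:
        ms.append(0.0)
        ps.append(0.0)
    return ms, ps


def trials_to_arrays(
    trials: list[ChoiceTrial], distribution: RewardDistribution
) -> TrialArrays:
    """Pack trials into arrays, normalizing magnitudes by `distribution`."""
    if not trials:
        raise ValueError("empty trial list")
    ml, pl, mr, pr, cl = [], [], [], [], []
    for t in trials:
        ms, ps = _pack(t.left, distribution)
        ml.append(ms)
        pl.append(ps)
        ms, ps = _pack(t.right, distribution)
        mr.append(ms)
        pr.append(ps)
        cl.append(t.chosen == "left")
    return TrialArrays(
        m_left=np.array(ml),
        p_left=np.array(pl),
        m_right=np.array(mr),
        p_right=np.array(pr),
        chose_left=np.array(cl, dtype=bool),
    )
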