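"""Discrete-choice model (DCM) fitting, model selection and outlier rules.

The DCM is a logit over expected-utility differences,

    P(choose left) = 1 / (1 + exp(-lambda * (EU_left - EU_right) - theta)),

with EU = sum_i p_i * U(m_i) on magnitudes normalized by the session's
reward distribution.  For each utility family the free parameters (utility
parameters plus temperature lambda and side bias theta) are estimated by
maximum likelihood on individual trials: bounded L-BFGS-B from
Latin-hypercube multi-starts, best start retained.

Model selection uses BIC = k*ln(n) - 2*LL and seeded 10-fold
cross-validation (held-out negative log-likelihood).  Daily fits whose
ln-transformed utility parameters fall outside pooled mean +/- 3 SD (pool =
all days, all subjects, per parameter) are excluded as parametric outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import qmc
from sklearn.model_selection import KFold, StratifiedKFold

from .distributions import RewardDistribution, RewardOption
from .models import PARAM_BOUNDS, PARAM_NAMES, UtilityCurve, _EVALUATORS
from .trials import ChoiceTrial, TrialArrays, trials_to_arrays

__all__ = [
    "DCMParams",
    "DCMFit",
    "FitError",
    "expected_utility",
    "neg_log_likelihood",
    "fit_dcm",
    "bic",
    "crossvalidate",
    "flag_outliers",
]

_LAMBDA_BOUNDS = (0.0, 1000.0)
_THETA_BOUNDS = (-10.0, 10.0)
_P_CLAMP = 1e-12  # keeps the log finite


class FitError(RuntimeError):
    """Raised when every optimization start fails."""


@dataclass(frozen=True)
class DCMParams:
    utility: UtilityCurve
    temperature: float
    side_bias: float

    def __post_init__(self) -> None:
        if not _LAMBDA_BOUNDS[0] <= self.temperature <= _LAMBDA_BOUNDS[1]:
            raise ValueError(f"lambda outside {_LAMBDA_BOUNDS}")
        if not _THETA_BOUNDS[0] <= self.side_bias <= _THETA_BOUNDS[1]:
            raise ValueError(f"theta outside {_THETA_BOUNDS}")


@dataclass(frozen=True)
class DCMFit:
    """A fitted DCM with its likelihood and model-selection scores."""

    params: DCMParams
    neg_ll: float
    n_trials: int
    k: int
    bic: float
    cv_negll: float | None
    converged: bool
    excluded_reason: str | None = None

    @property
    def family(self) -> str:
        return self.params.utility.family


def expected_utility(
    option: RewardOption, curve: UtilityCurve, distribution: RewardDistribution
) -> float:
    """EU = sum of p * U(normalized m) over the option's outcomes."""
    return float(sum(p * curve(distribution.normalize(m)) for m, p in option.outcomes))


def _p_left(theta_vec: np.ndarray, family: str, arrays: TrialArrays) -> np.ndarray:
    *u_params, lam, th = theta_vec
    evaluator = _EVALUATORS[family]
    u_l = evaluator(arrays.m_left, *u_params)
    u_r = evaluator(arrays.m_right, *u_params)
    eu_l = np.sum(arrays.p_left * u_l, axis=1)
    eu_r = np.sum(arrays.p_right * u_r, axis=1)
    return expit(lam * (eu_l - eu_r) + th)


def _nll_arrays(theta_vec, family, arrays) -> float:
    p = np.clip(_p_left(theta_vec, family, arrays), _P_CLAMP, 1.0 - _P_CLAMP)
    ll = np.where(arrays.chose_left, np.log(p), np.log1p(-p))
    return -float(np.sum(ll))


def neg_log_likelihood(
    trials: list[ChoiceTrial], params: DCMParams, distribution: RewardDistribution
) -> float:
    """Cumulative negative log-likelihood of the recorded choices."""
    arrays = trials_to_arrays(trials, distribution)
    vec = np.array(
        [*params.utility.params, params.temperature, params.side_bias]
    )
    return _nll_arrays(vec, params.utility.family, arrays)


def bic(fit: DCMFit) -> float:
    """BIC = k*ln(n) - 2*LL, with LL = -neg_ll."""
    return fit.k * np.log(fit.n_trials) + 2.0 * fit.neg_ll


def _bounds(family: str) -> list[tuple[float, float]]:
    return list(PARAM_BOUNDS[family]) + [_LAMBDA_BOUNDS, _THETA_BOUNDS]


def _starts(family: str, n_starts: int, seed: int) -> np.ndarray:
    bounds = np.array(_bounds(family))
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    unit = sampler.random(n_starts)
    # sample lambda on a compressed scale: huge temperatures are rarely
    # useful starting points
    lo = bounds[:, 0].copy()
    hi = bounds[:, 1].copy()
    hi[-2] = min(hi[-2], 50.0)
    return lo + unit * (hi - lo)


def fit_dcm(
    trials: list[ChoiceTrial],
    family: str,
    distribution: RewardDistribution,
    n_starts: int = 10,
    seed: int = 0,
    include_choice_params_in_k: bool = True,
    warm_start: np.ndarray | None = None,
) -> DCMFit:
    """Maximum-likelihood DCM fit for one utility family on one session.

    `k` (the BIC parameter count) includes lambda and theta by default.
    An optional `warm_start` parameter vector is prepended to the
    Latin-hypercube starts (used by cross-validation refits).
    """
    if family not in PARAM_NAMES:
        raise ValueError(f"unknown family {family!r}")
    n_u = len(PARAM_NAMES[family])
    if len(trials) < n_u + 2 + 10:
        raise FitError(
            f"too few trials ({len(trials)}) to fit {family} ({n_u + 2} params)"
        )
    arrays = trials_to_arrays(trials, distribution)
    bounds = _bounds(family)

    starts = _starts(family, n_starts, seed)
    if warm_start is not None:
        starts = np.vstack([np.asarray(warm_start), starts[: max(0, n_starts - 1)]])
    best = None  # best successfully converged start
    best_any = None  # best finite-objective start (line-search hiccups etc.)
    diagnostics = []
    for start in starts:
        res = minimize(
            _nll_arrays,
            start,
            args=(family, arrays),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-8 / max(1.0, len(trials)), "maxiter": 500},
        )
        diagnostics.append((start, res.success, res.fun))
        if np.isfinite(res.fun) and (best_any is None or res.fun < best_any.fun):
            best_any = res
        if res.success and (best is None or res.fun < best.fun):
            best = res
    converged = best is not None and (best_any is None or best.fun <= best_any.fun)
    best = best if converged else best_any
    if best is None:
        raise FitError(f"all {n_starts} starts failed: {diagnostics}")

    vec = best.x
    params = DCMParams(
        utility=UtilityCurve(family, tuple(float(v) for v in vec[:n_u])),
        temperature=float(vec[n_u]),
        side_bias=float(vec[n_u + 1]),
    )
    k = n_u + (2 if include_choice_params_in_k else 0)
    fit = DCMFit(
        params=params,
        neg_ll=float(best.fun),
        n_trials=len(trials),
        k=k,
        bic=0.0,
        cv_negll=None,
        converged=converged,
    )
    return replace(fit, bic=bic(fit))


def crossvalidate(
    trials: list[ChoiceTrial],
    family: str,
    distribution: RewardDistribution,
    k_folds: int = 10,
    seed: int = 0,
    n_starts: int = 10,
) -> float:
    """Mean held-out negative log-likelihood over seeded k-fold CV.

    Folds are stratified by sequence tag, so each fold sees every gamble
    type.  Each fold's refit warm-starts from the full-session optimum
    (plus Latin-hypercube starts, as in :func:`fit_dcm`).
    """
    if len(trials) < 2 * k_folds:
        raise ValueError(f"need >= {2 * k_folds} trials for {k_folds}-fold CV")
    full_fit = fit_dcm(trials, family, distribution, n_starts=n_starts, seed=seed)
    warm = np.array(
        [
            *full_fit.params.utility.params,
            full_fit.params.temperature,
            full_fit.params.side_bias,
        ]
    )
    tags = np.array([t.sequence_tag for t in trials])
    idx = np.arange(len(trials))
    _, counts = np.unique(tags, return_counts=True)
    if len(counts) > 1 and counts.min() >= k_folds:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = splitter.split(idx, tags)
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = splitter.split(idx)

    arrays_all = trials_to_arrays(trials, distribution)
    held_out = []
    for fold_i, (train, test) in enumerate(folds):
        if len(test) < 1:
            raise ValueError("empty CV fold")
        fit = fit_dcm(
            [trials[i] for i in train],
            family,
            distribution,
            n_starts=1,
            seed=seed + 1000 * (fold_i + 1),
            warm_start=warm,
        )
        vec = np.array(
            [*fit.params.utility.params, fit.params.temperature, fit.params.side_bias]
        )
        test_arrays = TrialArrays(
            m_left=arrays_all.m_left[test],
            p_left=arrays_all.p_left[test],
            m_right=arrays_all.m_right[test],
            p_right=arrays_all.p_right[test],
            chose_left=arrays_all.chose_left[test],
        )
        held_out.append(_nll_arrays(vec, family, test_arrays))
    return float(np.mean(held_out))


def flag_outliers(fits: list[DCMFit], n_sd: float = 3.0) -> tuple[list[DCMFit], list[DCMFit]]:
    """Partition fits into (kept, excluded) by the ln-parameter rule.

    A fit is excluded when any ln-transformed utility parameter lies outside
    the pooled mean +/- `n_sd` * SD for that parameter (pool = all supplied
    fits, e.g. all days and subjects).  Non-positive parameter values have no
    logarithm and are excluded outright.  A zero-SD pool excludes nothing.
    """
    if len(fits) < 3:
        raise ValueError(f"need >= 3 fits to pool, have {len(fits)}")
    families = {f.family for f in fits}
    if len(families) > 1:
        raise ValueError(f"mixed families in pool: {sorted(families)}")
    n_u = len(PARAM_NAMES[fits[0].family])

    values = np.full((len(fits), n_u), np.nan)
    bad_log = [False] * len(fits)
    for i, f in enumerate(fits):
        for j, v in enumerate(f.params.utility.params):
            if v <= 0:
                bad_log[i] = True
            else:
                values[i, j] = np.log(v)

    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)
    kept, excluded = [], []
    for i, f in enumerate(fits):
        if bad_log[i]:
            excluded.append(replace(f, excluded_reason="non-positive parameter"))
            continue
        out_of_band = [
            j
            for j in range(n_u)
            if sd[j] > 0 and abs(values[i, j] - mean[j]) > n_sd * sd[j]
        ]
        if out_of_band:
            names = [PARAM_NAMES[f.family][j] for j in out_of_band]
            excluded.append(
                replace(f, excluded_reason=f"ln-parameter outlier: {names}")
            )
        else:
            kept.append(f)
    return kept, excluded
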