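"""Model scoring and choice of the number of latent classes.

Provides the relative-entropy classification-certainty statistic, AIC/BIC,
and a parametric bootstrap likelihood-ratio test of k classes against k − 1
(McLachlan-style): the observed statistic 2(ℓ_k − ℓ_{k−1}) is referred to its
null distribution obtained by simulating from the fitted (k − 1)-class model
and refitting both orders on each replicate.  This bootstrap test replaces
the analytic Vuong–Lo–Mendell–Rubin approximations often reported for latent
class models; it addresses the same k vs k − 1 hypothesis with a fully
specified, reproducible procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .lca import LCAFit, LCAModel, NonConvergenceError, RHO_EPS, fit

__all__ = [
    "FitStatistics",
    "LRTResult",
    "ClassCountDecision",
    "relative_entropy",
    "n_parameters",
    "information_criteria",
    "split_largest_class",
    "bootstrap_lrt",
    "select_k",
]


@dataclass(frozen=True)
class FitStatistics:
    """Summary statistics of one fitted K-class model."""

    K: int
    loglik: float
    n_params: int
    aic: float
    bic: float
    relative_entropy: float


@dataclass(frozen=True)
class LRTResult:
    """One k vs (k−1) parametric bootstrap likelihood-ratio test."""

    k: int
    statistic: float
    p_value: float
    B: int
    B_effective: int
    null_statistics: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ClassCountDecision:
    """Outcome of sequential k vs (k−1) testing from k = 2 upward."""

    tested_k: tuple
    tests: tuple          # LRTResult per tested k
    selected_K: int
    alpha: float


def relative_entropy(posteriors, K: int | None = None) -> float:
    """Classification certainty E = 1 − Σ_i Σ_k (−p_ik ln p_ik) / (n ln K).

    1 means every posterior is degenerate (perfect certainty); 0 means all
    posteriors are uniform.  By convention K = 1 returns 1.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2:
        raise ValueError("posteriors must be an n×K matrix")
    if K is None:
        K = P.shape[1]
    if K != P.shape[1]:
        raise ValueError("K does not match posterior columns")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("posterior rows must be probabilities summing to 1")
    if K == 1:
        return 1.0
    n = P.shape[0]
    ent = -xlogy(P, P).sum()          # 0·ln 0 handled as 0
    return float(1.0 - ent / (n * math.log(K)))


def n_parameters(K: int, J: int) -> int:
    """Free parameters of a K-class model for J binary indicators."""
    return (K - 1) + K * J


def information_criteria(fit_result: LCAFit, n: int) -> FitStatistics:
    """AIC, BIC and relative entropy for one converged fit."""
    K = fit_result.model.n_classes
    J = fit_result.model.n_indicators
    p = n_parameters(K, J)
    ll = fit_result.loglik
    return FitStatistics(
        K=K,
        loglik=ll,
        n_params=p,
        aic=-2.0 * ll + 2.0 * p,
        bic=-2.0 * ll + p * math.log(n),
        relative_entropy=relative_entropy(fit_result.posteriors, K),
    )


def split_largest_class(model: LCAModel, delta: float = 0.05) -> LCAModel:
    """(k−1)-class model → k-class starting point by splitting the largest class.

    The split halves that class's weight and perturbs its profile by ±delta,
    giving the k-class EM a start at least as good as the (k−1) solution and
    guaranteeing a non-negative likelihood-ratio statistic in practice.
    """
    j = int(np.argmax(model.pi))
    pi = np.concatenate([model.pi, [model.pi[j] / 2.0]])
    pi[j] /= 2.0
    rho = np.vstack([model.rho, model.rho[j] + delta])
    rho[j] -= delta
    return LCAModel.from_probabilities(pi, np.clip(rho, RHO_EPS, 1 - RHO_EPS))


def _fit_pair(X, k, seed, n_starts, tol, max_iter):
    """Fit k−1 and k classes; the k fit is seeded with the split (k−1) model."""
    fit_km1 = fit(X, K=k - 1, n_starts=n_starts, seed=seed, tol=tol, max_iter=max_iter)
    fit_k = fit(
        X, K=k, n_starts=n_starts, seed=seed + 1, tol=tol, max_iter=max_iter,
        init_models=[split_largest_class(fit_km1.model)],
    )
    return fit_km1, fit_k


def bootstrap_lrt(
    X,
    k: int,
    B: int = 99,
    seed: int | None = None,
    n_starts: int = 50,
    replicate_starts: int = 10,
    tol: float = 1e-8,
    replicate_tol: float = 1e-6,
    max_iter: int = 2000,
) -> LRTResult:
    """Parametric bootstrap LRT of k classes against k − 1.

    The p-value is (1 + #{LRT_b ≥ LRT_obs}) / (B_effective + 1); replicates
    whose refits fail to converge are dropped with a warning.  Replicate
    refits use ``replicate_starts`` random starts and the looser
    ``replicate_tol`` (the null distribution needs the statistic's spread,
    not the last decimals of each replicate's optimum); the observed-data
    fits use the full ``n_starts`` and ``tol``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(0, 2**30))

    fit_km1, fit_k = _fit_pair(X, k, base_seed, n_starts, tol, max_iter)
    lrt_obs = 2.0 * (fit_k.loglik - fit_km1.loglik)

    null_stats = []
    for b in range(B):
        Xb, _ = fit_km1.model.sample(n, np.random.default_rng(base_seed + 7919 * (b + 1)))
        try:
            f0, f1 = _fit_pair(
                Xb, k, base_seed + 104729 * (b + 1), replicate_starts,
                replicate_tol, max_iter
            )
        except NonConvergenceError:
            warnings.warn(f"bootstrap replicate {b} dropped (non-convergence)")
            continue
        null_stats.append(2.0 * (f1.loglik - f0.loglik))
    null_stats = np.asarray(null_stats)
    b_eff = len(null_stats)
    if b_eff == 0:
        raise NonConvergenceError("all bootstrap replicates failed")
    p = (1.0 + np.sum(null_stats >= lrt_obs)) / (b_eff + 1.0)
    return LRTResult(k=k, statistic=float(lrt_obs), p_value=float(p),
                     B=B, B_effective=b_eff, null_statistics=null_stats)


def select_k(
    X,
    k_max: int = 4,
    alpha: float = 0.05,
    B: int = 99,
    seed: int | None = None,
    n_starts: int = 50,
    replicate_starts: int = 10,
    tol: float = 1e-8,
    replicate_tol: float = 1e-6,
    max_iter: int = 2000,
) -> ClassCountDecision:
    """Sequential k vs (k−1) testing: k = 2, 3, … up to ``k_max``.

    Stops at the first non-significant test; the selected K is the last k
    whose test rejected (1 if even the 2-vs-1 test fails).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rng = np.random.default_rng(seed)
    tested, tests = [], []
    selected = 1
    for k in range(2, k_max + 1):
        res = bootstrap_lrt(
            X, k, B=B, seed=int(rng.integers(0, 2**30)),
            n_starts=n_starts, replicate_starts=replicate_starts,
            tol=tol, replicate_tol=replicate_tol, max_iter=max_iter,
        )
        tested.append(k)
        tests.append(res)
        if res.p_value < alpha:
            selected = k
        else:
            break
    return ClassCountDecision(
        tested_k=tuple(tested), tests=tuple(tests), selected_K=selected, alpha=alpha
    )
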