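"""Latent class analysis for binary indicators: a Bernoulli mixture fit by EM.

The model: each subject belongs to one of K unobserved classes; class k has
prior probability π_k, and given class membership the J binary indicators are
independent Bernoullis with class-conditional probabilities ρ_kj.  The
marginal likelihood of an indicator vector y is

    P(y) = Σ_k π_k Π_j ρ_kj^{y_j} (1 − ρ_kj)^{1 − y_j}

Maximum likelihood is found by EM with multiple seeded random starts; the
best converged start wins.  ρ is clamped to [eps, 1 − eps] so that degenerate
(perfectly separating) indicators keep the log-likelihood finite.

Data are collapsed to unique response patterns with counts before EM, so each
iteration costs O(#patterns × K × J) regardless of n (with J = 6 there are at
most 64 patterns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.special import logsumexp

__all__ = [
    "LCAModel",
    "LCAFit",
    "DegenerateFitWarning",
    "NonConvergenceError",
    "loglik",
    "em_step",
    "posterior",
    "fit",
    "LatentClassAnalysis",
    "save_model",
    "load_model",
]

RHO_EPS = 1e-6


class DegenerateFitWarning(UserWarning):
    """An EM start collapsed a class to (numerically) zero membership."""


class NonConvergenceError(RuntimeError):
    """No EM start converged; carries the best partial fit."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class LCAModel:
    """Mixing proportions ``pi`` (K,) and Bernoulli profiles ``rho`` (K, J)."""

    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "rho", rho)
        if pi.ndim != 1 or rho.shape[0] != pi.shape[0]:
            raise ValueError("pi must be length K and rho K×J")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi entries must be > 0 and sum to 1")
        if np.any(rho < RHO_EPS - 1e-15) or np.any(rho > 1 - RHO_EPS + 1e-15):
            raise ValueError(f"rho entries must lie in [{RHO_EPS}, {1 - RHO_EPS}]")

    @property
    def n_classes(self) -> int:
        return self.pi.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.rho.shape[1]

    def permute(self, order) -> "LCAModel":
        """Relabel classes; the likelihood is invariant under this."""
        order = np.asarray(order)
        return LCAModel(self.pi[order], self.rho[order])

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n indicator vectors; returns (X, class_labels)."""
        labels = rng.choice(self.n_classes, size=n, p=self.pi)
        X = (rng.random((n, self.n_indicators)) < self.rho[labels]).astype(np.int8)
        return X, labels

    def to_dict(self) -> dict:
        return {
            "K": int(self.n_classes),
            "J": int(self.n_indicators),
            "pi": self.pi.tolist(),
            "rho": self.rho.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAModel":
        return cls(np.asarray(d["pi"]), np.asarray(d["rho"]))

    @classmethod
    def from_probabilities(cls, pi, rho) -> "LCAModel":
        """Build a model, clamping rho into the open unit interval."""
        pi = np.asarray(pi, dtype=float)
        return cls(pi / pi.sum(), np.clip(rho, RHO_EPS, 1 - RHO_EPS))


@dataclass
class LCAFit:
    """A fitted model plus everything needed to reproduce and inspect it."""

    model: LCAModel
    loglik: float
    posteriors: np.ndarray          # n × K
    modal_class: np.ndarray         # length n, argmax of posteriors
    n_iter: int
    converged: bool
    start_seed: int | None = None


def _validate_binary(X) -> np.ndarray:
    X = np.asarray(X)
    if X.dtype == object or not np.isin(np.unique(X), (0, 1)).all():
        raise TypeError("data must be a binary (0/1) matrix")
    return np.ascontiguousarray(X.astype(np.int8))


def _pattern_log_components(patterns: np.ndarray, model: LCAModel) -> np.ndarray:
    """log[π_k · Π_j ρ_kj^{y_j}(1−ρ_kj)^{1−y_j}] for each pattern × class."""
    log_rho = np.log(model.rho)          # K × J
    log_1m = np.log1p(-model.rho)
    # patterns: P × J;  result P × K
    return np.log(model.pi)[None, :] + patterns @ log_rho.T + (1 - patterns) @ log_1m.T


def loglik(X, model: LCAModel) -> float:
    """Observed-data log-likelihood Σ_i log Σ_k π_k Π_j ρ^{y}(1−ρ)^{1−y}."""
    X = _validate_binary(X)
    patterns, counts = np.unique(X, axis=0, return_counts=True)
    lc = _pattern_log_components(patterns.astype(float), model)
    return float(counts @ logsumexp(lc, axis=1))


def posterior(model: LCAModel, y) -> np.ndarray:
    """P(class | y) by Bayes rule; accepts one vector or an n×J matrix."""
    y = np.asarray(y)
    single = y.ndim == 1
    Y = _validate_binary(np.atleast_2d(y)).astype(float)
    lc = _pattern_log_components(Y, model)
    post = np.exp(lc - logsumexp(lc, axis=1, keepdims=True))
    return post[0] if single else post


def em_step(X, model: LCAModel, _counts=None, _patterns=None):
    """One EM update; returns (new_model, loglik_of_input_model).

    E-step: posterior responsibilities under ``model``.  M-step: π from mean
    responsibility, ρ from responsibility-weighted indicator means, clamped to
    [eps, 1−eps].  Warns :class:`DegenerateFitWarning` if a class's total
    responsibility falls below 1e-12.
    """
    if _patterns is None:
        X = _validate_binary(X)
        _patterns, _counts = np.unique(X, axis=0, return_counts=True)
        _patterns = _patterns.astype(float)
    lc = _pattern_log_components(_patterns, model)
    norm = logsumexp(lc, axis=1, keepdims=True)
    ll = float(_counts @ norm[:, 0])
    resp = np.exp(lc - norm) * _counts[:, None]       # P × K, weighted
    class_mass = resp.sum(axis=0)                      # K
    if np.any(class_mass < 1e-12):
        warnings.warn("EM produced an empty class", DegenerateFitWarning)
        class_mass = np.maximum(class_mass, 1e-300)
    n = _counts.sum()
    pi = class_mass / n
    rho = (resp.T @ _patterns) / class_mass[:, None]
    return LCAModel(pi / pi.sum(), np.clip(rho, RHO_EPS, 1 - RHO_EPS)), ll


def _run_em(patterns, counts, model, tol, max_iter):
    """EM to convergence on a pattern table. Returns (model, ll, n_iter, conv, empty)."""
    prev_ll = -np.inf
    converged = False
    went_degenerate = False
    n_iter = 0
    log_pi = np.log(model.pi)
    log_rho = np.log(model.rho)
    log_1m = np.log1p(-model.rho)
    one_m = 1.0 - patterns
    n = counts.sum()
    for n_iter in range(1, max_iter + 1):
        lc = log_pi[None, :] + patterns @ log_rho.T + one_m @ log_1m.T
        norm = logsumexp(lc, axis=1, keepdims=True)
        ll = float(counts @ norm[:, 0])
        resp = np.exp(lc - norm) * counts[:, None]
        class_mass = resp.sum(axis=0)
        if np.any(class_mass < 1e-12):
            went_degenerate = True
            break
        pi = class_mass / n
        rho = np.clip((resp.T @ patterns) / class_mass[:, None], RHO_EPS, 1 - RHO_EPS)
        log_pi = np.log(pi)
        log_rho = np.log(rho)
        log_1m = np.log1p(-rho)
        if ll - prev_ll < tol * max(abs(ll), 1.0) and n_iter > 1:
            converged = True
            break
        prev_ll = ll
    model = LCAModel(np.exp(log_pi) / np.exp(log_pi).sum(), np.exp(log_rho))
    if not went_degenerate:
        # report the log-likelihood of the parameters actually returned
        lc = log_pi[None, :] + patterns @ log_rho.T + one_m @ log_1m.T
        ll = float(counts @ logsumexp(lc, axis=1))
    return model, ll, n_iter, converged, went_degenerate


def _random_start(K, J, rng) -> LCAModel:
    pi = rng.dirichlet(np.ones(K))
    rho = rng.uniform(0.2, 0.8, size=(K, J))
    return LCAModel.from_probabilities(pi, rho)


def fit(
    X,
    K: int,
    n_starts: int = 50,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init_models: list[LCAModel] | None = None,
    short_iter: int = 80,
    n_final: int | None = None,
) -> LCAFit:
    """Maximum-likelihood K-class fit, best of ``n_starts`` seeded EM runs.

    Random starts draw π ~ Dirichlet(1,…,1) and ρ ~ Uniform(0.2, 0.8).
    Starts follow the usual two-stage scheme: every start runs a short EM
    burst (``short_iter`` iterations); the ``n_final`` most promising (by
    log-likelihood; default n_starts/10, minimum 2) continue to full
    convergence.  ``init_models`` are additional deterministic starting
    points (used e.g. to guarantee a nested k-class fit dominates the
    (k−1)-class solution); they are always promoted to the full run.
    Starts that collapse a class are discarded with a warning rather than
    redrawn, so results are reproducible under one seed stream.
    """
    X = _validate_binary(X)
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError("need at least K observations")
    patterns_i, counts = np.unique(X, axis=0, return_counts=True)
    patterns = patterns_i.astype(float)

    if K == 1:
        # closed form: pi = 1, rho_j = column mean
        rho = np.clip((counts @ patterns) / n, RHO_EPS, 1 - RHO_EPS)
        model = LCAModel(np.ones(1), rho[None, :])
        ll = loglik(X, model)
        post = np.ones((n, 1))
        return LCAFit(model, ll, post, np.zeros(n, dtype=int), 1, True, seed)

    rng = np.random.default_rng(seed)
    if n_final is None:
        n_final = max(2, n_starts // 10)
    best = None
    best_partial = None
    n_degenerate = 0
    starts: list[tuple[LCAModel, int | None, bool]] = [
        (m, None, True) for m in (init_models or [])
    ]
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    starts += [
        (_random_start(K, J, np.random.default_rng(int(s))), int(s), False)
        for s in start_seeds
    ]

    # stage 1: short burst for every start
    burst = min(short_iter, max_iter)
    stage1 = []
    for model0, sseed, pinned in starts:
        model, ll, n_iter, converged, degenerate = _run_em(
            patterns, counts, model0, tol, burst
        )
        if degenerate:
            n_degenerate += 1
            continue
        stage1.append([ll, model, n_iter, converged, sseed, pinned])
    # stage 2: continue the most promising (and all pinned) starts
    stage1.sort(key=lambda r: r[0], reverse=True)
    promoted = 0
    leftovers = []
    for rec in stage1:
        ll, model, n_iter, converged, sseed, pinned = rec
        if not converged and (pinned or promoted < n_final):
            promoted += 0 if pinned else 1
            model, ll, n_iter2, converged, degenerate = _run_em(
                patterns, counts, model, tol, max_iter - burst
            )
            if degenerate:
                n_degenerate += 1
                continue
            n_iter += n_iter2
        elif not converged:
            leftovers.append(rec)
            continue
        record = (ll, model, n_iter, converged, sseed)
        if converged:
            if best is None or ll > best[0]:
                best = record
        elif best_partial is None or ll > best_partial[0]:
            best_partial = record
    if best is None:
        # no promoted start converged: fall back to the remaining starts
        for ll, model, n_iter, converged, sseed, pinned in leftovers:
            model, ll, n_iter2, converged, degenerate = _run_em(
                patterns, counts, model, tol, max_iter - burst
            )
            if degenerate:
                n_degenerate += 1
                continue
            record = (ll, model, n_iter + n_iter2, converged, sseed)
            if converged:
                if best is None or ll > best[0]:
                    best = record
            elif best_partial is None or ll > best_partial[0]:
                best_partial = record
    else:
        for rec in leftovers:
            if best_partial is None or rec[0] > best_partial[0]:
                best_partial = (rec[0], rec[1], rec[2], rec[3], rec[4])
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} EM start(s) discarded (empty class)", DegenerateFitWarning
        )
    if best is None:
        partial = None
        if best_partial is not None:
            ll, model, n_iter, converged, sseed = best_partial
            post = posterior(model, X)
            partial = LCAFit(model, ll, post, post.argmax(axis=1), n_iter, False, sseed)
        raise NonConvergenceError("no EM start converged", best_fit=partial)
    ll, model, n_iter, converged, sseed = best
    post = posterior(model, X)
    return LCAFit(model, ll, post, post.argmax(axis=1), n_iter, True, sseed)


class LatentClassAnalysis:
    """scikit-learn style estimator for the binary-indicator latent class model.

    Parameters
    ----------
    n_classes : number of latent classes K.
    n_starts : random EM initializations; the best converged one is kept.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap per start.
    random_state : seed for the start stream (fits are bit-reproducible).

    Attributes (after ``fit``)
    --------------------------
    weights_ : (K,) mixing proportions π.
    profiles_ : (K, J) class-conditional indicator probabilities ρ.
    loglik_ : maximized log-likelihood.
    posteriors_ : (n, K) training-set posterior memberships.
    labels_ : modal class assignment of the training data.
    n_iter_, converged_, start_seed_ : diagnostics of the winning start.
    """

    def __init__(
        self,
        n_classes: int = 3,
        n_starts: int = 50,
        tol: float = 1e-8,
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_classes": self.n_classes,
            "n_starts": self.n_starts,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- estimation ---------------------------------------------------------
    def fit(self, X, y=None, init_models=None):
        X = np.asarray(X)
        result = fit(
            X,
            K=self.n_classes,
            n_starts=self.n_starts,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
            init_models=init_models,
        )
        self.model_ = result.model
        self.weights_ = result.model.pi
        self.profiles_ = result.model.rho
        self.loglik_ = result.loglik
        self.posteriors_ = result.posteriors
        self.labels_ = result.modal_class
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.start_seed_ = result.start_seed
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return posterior(self.model_, np.asarray(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood."""
        self._check_fitted()
        return loglik(X, self.model_) / len(X)

    def sample(self, n: int, random_state: int | None = None):
        self._check_fitted()
        return self.model_.sample(n, np.random.default_rng(random_state))

    @property
    def fit_result_(self) -> LCAFit:
        self._check_fitted()
        return LCAFit(
            self.model_, self.loglik_, self.posteriors_, self.labels_,
            self.n_iter_, self.converged_, self.start_seed_,
        )


# -- serialization ----------------------------------------------------------

SCHEMA_VERSION = 1


def save_model(fit_or_model, path, settings: dict | None = None) -> None:
    """Serialize a model (or fit) to a versioned YAML document."""
    if isinstance(fit_or_model, LCAFit):
        doc = fit_or_model.model.to_dict()
        doc["loglik"] = float(fit_or_model.loglik)
        doc["converged"] = bool(fit_or_model.converged)
        doc["start_seed"] = fit_or_model.start_seed
    else:
        doc = fit_or_model.to_dict()
    doc["schema_version"] = SCHEMA_VERSION
    if settings:
        doc["settings"] = settings
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> LCAModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported model document version")
    return LCAModel.from_dict(doc)
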