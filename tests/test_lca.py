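"""Latent class core: likelihood, EM, multi-start fitting, serialization."""

import itertools
import warnings

import numpy as np
import pytest

from diabetes_typology.lca import (
    RHO_EPS,
    DegenerateFitWarning,
    LatentClassAnalysis,
    LCAModel,
    NonConvergenceError,
    em_step,
    fit,
    load_model,
    loglik,
    posterior,
    save_model,
)


def random_model(K, J, rng) -> LCAModel:
    return LCAModel.from_probabilities(
        rng.dirichlet(np.ones(K)), rng.uniform(0.1, 0.9, (K, J))
    )


def brute_force_loglik(X, model) -> float:
    """Independent oracle: enumerate all 2^J patterns and sum count·log P."""
    X = np.asarray(X)
    J = X.shape[1]
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=J):
        count = np.sum((X == pattern).all(axis=1))
        if count == 0:
            continue
        p = sum(
            model.pi[k]
            * np.prod(
                [model.rho[k, j] if pattern[j] else 1 - model.rho[k, j] for j in range(J)]
            )
            for k in range(model.n_classes)
        )
        total += count * np.log(p)
    return total


class TestLoglik:
    def test_single_class_single_record(self):
        model = LCAModel(np.ones(1), np.array([[0.5, 0.5]]))
        assert loglik(np.array([[1, 0]]), model) == pytest.approx(np.log(0.25))

    def test_two_point_mixture(self):
        model = LCAModel.from_probabilities([0.5, 0.5], [[0.0], [1.0]])
        X = np.array([[0], [1]])
        assert loglik(X, model) == pytest.approx(2 * np.log(0.5), abs=1e-5)

    @pytest.mark.parametrize("K,J,n,seed", [(2, 4, 60, 0), (3, 6, 120, 1), (1, 3, 30, 2)])
    def test_matches_pattern_enumeration_oracle(self, K, J, n, seed):
        rng = np.random.default_rng(seed)
        model = random_model(K, J, rng)
        X, _ = model.sample(n, rng)
        assert loglik(X, model) == pytest.approx(brute_force_loglik(X, model), rel=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        model = random_model(3, 5, rng)
        X, _ = model.sample(80, rng)
        assert loglik(X, model) == pytest.approx(loglik(X, model.permute([2, 0, 1])))

    def test_rejects_non_binary_data(self):
        model = random_model(2, 2, np.random.default_rng(0))
        with pytest.raises(TypeError):
            loglik(np.array([[0, 2]]), model)


class TestEMStep:
    def test_identical_rows_fixed_point(self):
        X = np.tile([1, 0, 1], (20, 1))
        model = LCAModel.from_probabilities([1.0], [[0.4, 0.4, 0.4]])
        new, _ = em_step(X, model)
        np.testing.assert_allclose(new.rho[0], [1 - RHO_EPS, RHO_EPS, 1 - RHO_EPS])
        new2, _ = em_step(X, new)
        np.testing.assert_allclose(new2.rho, new.rho, atol=1e-12)

    def test_loglik_monotone_over_random_pairs(self):
        """EM never decreases the observed-data log-likelihood."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            K = rng.integers(1, 4)
            J = rng.integers(2, 7)
            model = random_model(K, J, rng)
            X, _ = random_model(K, J, rng).sample(int(rng.integers(20, 100)), rng)
            new, _ = em_step(X, model)
            assert loglik(X, new) >= loglik(X, model) - 1e-10

    def test_separated_data_converges_to_clamped_profiles(self):
        X = np.vstack([np.zeros((30, 4)), np.ones((10, 4))]).astype(int)
        model = LCAModel.from_probabilities([0.5, 0.5], [[0.3] * 4, [0.7] * 4])
        for _ in range(200):
            model, _ = em_step(X, model)
        order = np.argsort(model.pi)[::-1]
        np.testing.assert_allclose(model.pi[order], [0.75, 0.25], atol=1e-6)
        np.testing.assert_allclose(model.rho[order[0]], [RHO_EPS] * 4)
        np.testing.assert_allclose(model.rho[order[1]], [1 - RHO_EPS] * 4)

    def test_empty_class_warns(self):
        X = np.ones((5, 2), dtype=int)
        model = LCAModel(np.array([1 - 1e-13, 1e-13]), np.full((2, 2), 0.5))
        with pytest.warns(DegenerateFitWarning):
            em_step(X, model)


class TestPosterior:
    def test_identical_profiles_return_prior(self):
        model = LCAModel.from_probabilities([0.3, 0.7], [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(posterior(model, [1, 0]), [0.3, 0.7])

    def test_bayes_arithmetic(self):
        model = LCAModel.from_probabilities([0.5, 0.5], [[0.9], [0.1]])
        np.testing.assert_allclose(posterior(model, [1]), [0.9, 0.1], atol=1e-9)

    def test_rows_normalize(self):
        rng = np.random.default_rng(5)
        model = random_model(3, 6, rng)
        X, _ = model.sample(50, rng)
        np.testing.assert_allclose(posterior(model, X).sum(axis=1), 1.0, atol=1e-10)


class TestFit:
    def test_single_class_closed_form(self):
        rng = np.random.default_rng(8)
        X = (rng.random((200, 6)) < 0.35).astype(int)
        res = fit(X, K=1, seed=0)
        np.testing.assert_allclose(res.model.pi, [1.0])
        np.testing.assert_allclose(res.model.rho[0], X.mean(axis=0), atol=1e-10)
        assert res.converged

    def test_parameter_recovery_well_separated(self):
        truth = LCAModel.from_probabilities([0.5, 0.5], [[0.9] * 6, [0.1] * 6])
        X, _ = truth.sample(500, np.random.default_rng(1))
        res = fit(X, K=2, n_starts=20, seed=2)
        order = np.argsort(res.model.rho[:, 0])[::-1]
        np.testing.assert_allclose(res.model.pi[order], truth.pi, atol=0.05)
        np.testing.assert_allclose(res.model.rho[order], truth.rho, atol=0.05)

    def test_best_of_starts_dominates_each_start(self):
        rng = np.random.default_rng(9)
        model = random_model(3, 5, rng)
        X, _ = model.sample(150, rng)
        # with every start fully run, the winner must dominate each single run
        res = fit(X, K=3, n_starts=12, seed=4, n_final=12)
        # per-start log-likelihoods are recovered by refitting from the same
        # seeded start stream one at a time
        singles = []
        for s in np.random.default_rng(4).integers(0, 2**31 - 1, size=12):
            try:
                singles.append(
                    fit(X, K=3, n_starts=0, seed=0, n_final=1,
                        init_models=[_start_from_seed(3, 5, int(s))]).loglik
                )
            except NonConvergenceError:
                continue
        assert singles and res.loglik >= max(singles) - 1e-7

    def test_determinism(self):
        rng = np.random.default_rng(10)
        model = random_model(3, 6, rng)
        X, _ = model.sample(300, rng)
        r1 = fit(X, K=3, n_starts=15, seed=123)
        r2 = fit(X, K=3, n_starts=15, seed=123)
        assert r1.loglik == r2.loglik
        np.testing.assert_array_equal(r1.model.pi, r2.model.pi)
        np.testing.assert_array_equal(r1.model.rho, r2.model.rho)
        np.testing.assert_array_equal(r1.posteriors, r2.posteriors)
        np.testing.assert_array_equal(r1.modal_class, r2.modal_class)

    def test_modal_class_consistent_with_posteriors(self):
        rng = np.random.default_rng(12)
        model = random_model(2, 4, rng)
        X, _ = model.sample(100, rng)
        res = fit(X, K=2, n_starts=5, seed=0)
        np.testing.assert_array_equal(res.modal_class, res.posteriors.argmax(axis=1))
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_non_convergence_reports_best_partial(self):
        rng = np.random.default_rng(13)
        model = random_model(3, 6, rng)
        X, _ = model.sample(400, rng)
        with pytest.raises(NonConvergenceError) as exc:
            fit(X, K=3, n_starts=5, seed=1, max_iter=2)
        assert exc.value.best_fit is not None
        assert not exc.value.best_fit.converged

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            fit(np.zeros((2, 3), dtype=int), K=3)


def _start_from_seed(K, J, s):
    r = np.random.default_rng(s)
    return LCAModel.from_probabilities(r.dirichlet(np.ones(K)), r.uniform(0.2, 0.8, (K, J)))


class TestEstimator:
    def test_fit_predict_roundtrip(self):
        truth = LCAModel.from_probabilities([0.4, 0.6], [[0.85] * 5, [0.15] * 5])
        X, labels = truth.sample(400, np.random.default_rng(3))
        est = LatentClassAnalysis(n_classes=2, n_starts=10, random_state=0).fit(X)
        assert est.converged_
        pred = est.predict(X)
        np.testing.assert_array_equal(pred, est.labels_)
        # predictions separate the generating classes (up to label swap)
        agree = max((pred == labels).mean(), (pred != labels).mean())
        assert agree > 0.9
        assert est.score(X) == pytest.approx(est.loglik_ / len(X))

    def test_get_set_params(self):
        est = LatentClassAnalysis(n_classes=4)
        assert est.get_params()["n_classes"] == 4
        est.set_params(n_classes=2, random_state=7)
        assert est.n_classes == 2 and est.random_state == 7
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


def test_model_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    model = random_model(3, 6, rng)
    X, _ = model.sample(100, rng)
    res = fit(X, K=3, n_starts=5, seed=9)
    path = tmp_path / "model.yaml"
    save_model(res, path, settings={"n_starts": 5, "seed": 9})
    loaded = load_model(path)
    np.testing.assert_allclose(loaded.pi, res.model.pi)
    np.testing.assert_allclose(loaded.rho, res.model.rho)
    assert loglik(X, loaded) == pytest.approx(res.loglik)
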