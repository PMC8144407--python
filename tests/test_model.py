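import numpy as np
import pytest
from scipy.special import logsumexp

import hidgenome as hg
from hidgenome.model import (HidGenomeModel, ablate, fit, lambda_max,
                             load_model, pairwise_proba, penalized_objective,
                             predict_proba, save_model, kkt_residual)


def random_instance(rng, n=60, m=4, K=3):
    Z = rng.standard_normal((n, m))
    true = rng.standard_normal((m, K)) * 1.5
    S = Z @ true
    P = np.exp(S - logsumexp(S, axis=1, keepdims=True))
    y = np.array([rng.choice(K, p=p) for p in P])
    labels = [f"c{k}" for k in y]
    while len(set(labels)) < K or min(labels.count(c) for c in set(labels)) < 2:
        y = np.array([rng.choice(K, p=p) for p in P])
        labels = [f"c{k}" for k in y]
    return Z, labels


def standardized(Z):
    return (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)


def ista_oracle(Zs, labels, lam, n_iter=6000):
    """Independent plain proximal-gradient solver of the penalized objective."""
    classes = sorted(set(labels))
    K = len(classes)
    y = np.array([classes.index(l) for l in labels])
    n, m = Zs.shape
    Y = np.zeros((n, K)); Y[np.arange(n), y] = 1.0
    A = np.hstack([np.ones((n, 1)), Zs])
    step = 1.0 / (0.5 * np.linalg.norm(A, 2) ** 2)
    alpha, G = np.zeros(K), np.zeros((m, K))
    for _ in range(n_iter):
        S = alpha + Zs @ G
        P = np.exp(S - logsumexp(S, axis=1, keepdims=True))
        R = P - Y
        alpha = alpha - step * R.sum(axis=0)
        G = G - step * (Zs.T @ R)
        norms = np.sqrt((G ** 2).sum(axis=1))
        shrink = np.maximum(0.0, 1.0 - step * lam / np.maximum(norms, 1e-300))
        G = G * shrink[:, None]
    S = alpha + Zs @ G
    nll = logsumexp(S, axis=1).sum() - (S * Y).sum()
    return nll + lam * np.sqrt((G ** 2).sum(axis=1)).sum()


class TestNullModel:
    def test_lambda_at_least_lambda_max_gives_prevalence_model(self):
        rng = np.random.default_rng(0)
        Z, labels = random_instance(rng)
        Zs = standardized(Z)
        y = np.array([sorted(set(labels)).index(l) for l in labels])
        Y = np.zeros((len(y), 3)); Y[np.arange(len(y)), y] = 1.0
        lam_max = lambda_max(Zs, Y)
        model = fit(Z, labels, lambda_grid=[lam_max * 1.05], tol=1e-10,
                    max_iter=5000)
        assert not model.active_groups.any()
        probs = predict_proba(model, Z)
        props = Y.mean(axis=0)
        np.testing.assert_allclose(probs, np.tile(props, (len(y), 1)), atol=1e-8)


class TestSolverCorrectness:
    def test_unpenalized_fit_matches_generic_optimizer(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(1)
        Z, labels = random_instance(rng, n=60, m=4, K=3)
        model = fit(Z, labels, lambda_grid=[0.0], tol=1e-12, max_iter=30000,
                    kkt_tol=1e-8)
        probs = predict_proba(model, Z)

        classes = sorted(set(labels))
        y = np.array([classes.index(l) for l in labels])
        A = np.hstack([np.ones((len(y), 1)), standardized(Z)])

        def nll(theta):  # reference-class parametrization, class K-1 = 0
            B = np.hstack([theta.reshape(A.shape[1], 2), np.zeros((A.shape[1], 1))])
            S = A @ B
            return logsumexp(S, axis=1).sum() - S[np.arange(len(y)), y].sum()

        res = minimize(nll, np.zeros(A.shape[1] * 2), method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 2000})
        B = np.hstack([res.x.reshape(A.shape[1], 2), np.zeros((A.shape[1], 1))])
        S = A @ B
        oracle_probs = np.exp(S - logsumexp(S, axis=1, keepdims=True))
        np.testing.assert_allclose(probs, oracle_probs, atol=1e-4)

    def test_objective_not_worse_than_ista_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(30, 81))
            m = int(rng.integers(2, 7))
            Z, labels = random_instance(rng, n=n, m=m, K=3)
            Zs = standardized(Z)
            y = np.array([sorted(set(labels)).index(l) for l in labels])
            Y = np.zeros((n, 3)); Y[np.arange(n), y] = 1.0
            lam = float(rng.uniform(0.05, 0.6)) * lambda_max(Zs, Y)
            model = fit(Z, labels, lambda_grid=[lam], tol=1e-10,
                        max_iter=20000, kkt_tol=1e-7)
            obj = penalized_objective(model, Z, labels)
            oracle = ista_oracle(Zs, labels, lam)
            assert obj <= oracle + 1e-6 * abs(oracle)
            assert kkt_residual(model, Z, labels) <= 1e-4 * (1.0 + lam)

    def test_group_sparsity_pattern(self, tiny_fit):
        _, _, _, _, model = tiny_fit
        for row in model.Gamma:
            assert np.all(row == 0) or np.all(row != 0)

    def test_predictions_invariant_to_column_scaling(self):
        rng = np.random.default_rng(3)
        Z, labels = random_instance(rng, n=50, m=5, K=3)
        m1 = fit(Z, labels, n_lambda=8, lambda_min_ratio=0.05, cv_folds=3,
                 seed=0, tol=1e-9, max_iter=5000)
        Z2 = Z.copy(); Z2[:, 2] *= 1000.0
        m2 = fit(Z2, labels, n_lambda=8, lambda_min_ratio=0.05, cv_folds=3,
                 seed=0, tol=1e-9, max_iter=5000)
        np.testing.assert_allclose(predict_proba(m1, Z), predict_proba(m2, Z2),
                                   atol=1e-6)


class TestPredict:
    def test_rows_sum_to_one(self, tiny_fit):
        _, _, _, design, model = tiny_fit
        probs = predict_proba(model, design)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_two_class_softmax_reduces_to_logistic(self):
        g = 0.7
        model = HidGenomeModel(
            classes=["A", "B"], columns=["z"], families=["region"],
            alpha=np.array([0.2, -0.2]), Gamma=np.array([[g, -g]]),
            lambda_=1.0, lambda_grid=np.array([1.0]), cv_deviance=None,
            col_means=np.zeros(1), col_sds=np.ones(1),
        )
        z = np.linspace(-2, 2, 9).reshape(-1, 1)
        probs = predict_proba(model, z)
        expected = 1.0 / (1.0 + np.exp(-(0.4 + 2 * g * z[:, 0])))
        np.testing.assert_allclose(probs[:, 0], expected, atol=1e-12)

    def test_column_mismatch_errors(self, tiny_fit):
        _, _, _, _, model = tiny_fit
        with pytest.raises(ValueError, match="columns"):
            predict_proba(model, np.zeros((3, 2)))


class TestPairwiseProba:
    def test_stated_formula(self):
        out = pairwise_proba(np.array([0.6, 0.2, 0.2]), 0, 1)
        np.testing.assert_allclose(out, [0.75, 0.25], atol=1e-12)

    def test_equal_probabilities_split_evenly(self):
        out = pairwise_proba(np.array([0.3, 0.3, 0.4]), 0, 1)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)

    def test_zero_competitor(self):
        out = pairwise_proba(np.array([0.5, 0.0, 0.5]), 0, 1)
        np.testing.assert_allclose(out, [1.0, 0.0], atol=1e-12)

    def test_degenerate_pair_is_nan(self):
        out = pairwise_proba(np.array([[0.0, 0.0, 1.0]]), 0, 1)
        assert np.isnan(out[0]).all()


class TestAblate:
    def test_marginal_and_cumulative_structure(self, tiny_fit):
        _, _, _, design, _ = tiny_fit
        catalog = tiny_fit[0]
        kwargs = dict(n_lambda=5, lambda_min_ratio=0.1, cv_folds=2, seed=0,
                      tol=1e-6, max_iter=400)
        marg = ablate(design, catalog.labels, families=("gene", "sbs96"),
                      mode="marginal", **kwargs)
        assert set(marg) == {"baseline", "baseline+gene", "baseline+sbs96"}
        assert set(marg["baseline"].families) <= {"variant", "intercept-mf"}
        cum = ablate(design, catalog.labels, families=("gene", "sbs96"),
                     mode="cumulative", **kwargs)
        names = list(cum)
        assert names[0] == "baseline"
        fam_sets = [set(m.families) for m in cum.values()]
        for a, b in zip(fam_sets, fam_sets[1:]):
            assert a <= b

    def test_unknown_family_errors(self, tiny_fit):
        catalog, _, _, design, _ = tiny_fit
        with pytest.raises(ValueError, match="unknown family"):
            ablate(design, catalog.labels, families=("nonesuch",))


class TestValidationAndIO:
    def test_non_finite_design_errors(self):
        Z = np.zeros((10, 2)); Z[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(Z, ["A"] * 5 + ["B"] * 5, lambda_grid=[1.0])

    def test_tiny_class_errors_with_name(self):
        Z = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError, match="rare"):
            fit(Z, ["A", "A", "B", "B", "rare"], lambda_grid=[1.0])

    def test_empty_lambda_grid_errors(self):
        Z = np.random.default_rng(0).standard_normal((8, 2))
        with pytest.raises(ValueError, match="empty"):
            fit(Z, ["A"] * 4 + ["B"] * 4, lambda_grid=[])

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        _, _, _, design, model = tiny_fit
        p = tmp_path / "model.npz"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_array_equal(model.Gamma, loaded.Gamma)
        np.testing.assert_array_equal(model.alpha, loaded.alpha)
        assert model.classes == loaded.classes
        assert model.lambda_ == loaded.lambda_
        np.testing.assert_allclose(
            predict_proba(model, design), predict_proba(loaded, design), atol=0
        )
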