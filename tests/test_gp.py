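"""GP regression: kernel algebra, likelihood, posterior, penalised fitting."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal

from povgp.gp import (
    FitConfig,
    GPHyperParams,
    GPModelState,
    TrainingSet,
    _objective_and_grad,
    feature_importance,
    fit,
    kernel,
    kernel_matrix,
    marginal_log_likelihood,
    penalized_objective,
    predict,
)


def make_train(n=10, d=3, seed=0, ell_s_scale=100.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    S = rng.uniform(0, ell_s_scale, (n, 2))
    y = rng.standard_normal(n)
    return TrainingSet(
        X=X, S=S, y=y,
        feature_names=[f"x{j}" for j in range(d)],
        x_mean=np.zeros(d), x_sd=np.ones(d),
    )


def random_params(rng, d):
    return GPHyperParams(
        beta=rng.standard_normal(d),
        ell=rng.uniform(0.5, 3.0),
        ell_s=rng.uniform(10.0, 100.0),
        sigma_f2=rng.uniform(0.1, 2.0),
        sigma_n2=rng.uniform(0.05, 0.5),
    )


def oracle_posterior(train, params, xs, ss):
    """Brute-force joint-Gaussian conditioning for a single test point."""
    K = kernel_matrix(train.X, train.S, train.X, train.S, params)
    C = K + params.sigma_n2 * np.eye(train.n)
    k = kernel_matrix(train.X, train.S, xs[None], ss[None], params).ravel()
    b = train.X @ params.beta
    mean = xs @ params.beta + k @ np.linalg.solve(C, train.y - b)
    var = params.sigma_f2 - k @ np.linalg.solve(C, k) + params.sigma_n2
    return mean, var


class TestKernel:
    def test_self_covariance_is_signal_variance(self):
        p = GPHyperParams(beta=np.zeros(2), ell=1.0, ell_s=10.0, sigma_f2=1.7, sigma_n2=0.1)
        x, s = np.array([0.3, -1.2]), np.array([5.0, 5.0])
        assert kernel(x, s, x, s, p) == pytest.approx(1.7)

    def test_worked_example(self):
        # sigma_f2 = 2, ||dx||^2 = 2 ell^2, ds = 0 -> 2/e
        p = GPHyperParams(beta=np.zeros(1), ell=1.5, ell_s=10.0, sigma_f2=2.0, sigma_n2=0.0)
        x1 = np.array([0.0])
        x2 = np.array([math.sqrt(2.0) * 1.5])
        s = np.array([1.0, 1.0])
        assert kernel(x1, s, x2, s, p) == pytest.approx(2.0 * math.exp(-1.0), abs=1e-12)

    def test_vanishes_at_large_feature_distance(self):
        p = GPHyperParams(beta=np.zeros(1), ell=1.0, ell_s=10.0, sigma_f2=1.0, sigma_n2=0.0)
        s = np.zeros(2)
        assert kernel(np.array([0.0]), s, np.array([100.0]), s, p) < 1e-300

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, 3)
        x1, x2 = rng.standard_normal(3), rng.standard_normal(3)
        s1, s2 = rng.uniform(0, 50, 2), rng.uniform(0, 50, 2)
        k12 = kernel(x1, s1, x2, s2, p)
        assert k12 == pytest.approx(kernel(x2, s2, x1, s1, p))
        assert 0.0 < k12 <= p.sigma_f2

    def test_nonfinite_inputs_rejected(self):
        p = GPHyperParams(beta=np.zeros(1), ell=1.0, ell_s=1.0, sigma_f2=1.0, sigma_n2=0.0)
        with pytest.raises(ValueError):
            kernel(np.array([np.nan]), np.zeros(2), np.array([0.0]), np.zeros(2), p)


class TestMarginalLikelihood:
    def test_scalar_case_closed_form(self):
        train = TrainingSet(
            X=np.array([[2.0]]), S=np.array([[0.0, 0.0]]), y=np.array([1.3]),
            feature_names=["x0"], x_mean=np.zeros(1), x_sd=np.ones(1),
        )
        p = GPHyperParams(beta=np.array([0.4]), ell=1.0, ell_s=1.0, sigma_f2=0.7, sigma_n2=0.2)
        r = 1.3 - 0.4 * 2.0
        v = 0.7 + 0.2
        expected = -r**2 / (2 * v) - 0.5 * math.log(v) - 0.5 * math.log(2 * math.pi)
        assert marginal_log_likelihood(train, p) == pytest.approx(expected, abs=1e-12)

    def test_matches_multivariate_normal_density(self):
        train = make_train(n=3, seed=2)
        p = random_params(np.random.default_rng(3), 3)
        K = kernel_matrix(train.X, train.S, train.X, train.S, p)
        C = K + p.sigma_n2 * np.eye(3)
        expected = multivariate_normal(train.X @ p.beta, C).logpdf(train.y)
        assert marginal_log_likelihood(train, p) == pytest.approx(expected, abs=1e-8)

    def test_zero_residual_quadratic_term(self):
        train = make_train(n=6, seed=4)
        p = random_params(np.random.default_rng(5), 3)
        train.y = train.X @ p.beta  # exact linear fit
        K = kernel_matrix(train.X, train.S, train.X, train.S, p)
        C = K + p.sigma_n2 * np.eye(6)
        logdet_part = -0.5 * np.linalg.slogdet(C)[1] - 3 * math.log(2 * math.pi)
        assert marginal_log_likelihood(train, p) == pytest.approx(logdet_part, abs=1e-8)


class TestPenalizedObjective:
    def test_zero_lambda_equals_likelihood(self):
        train = make_train()
        p = random_params(np.random.default_rng(6), 3)
        p.lam = 0.0
        assert penalized_objective(train, p) == marginal_log_likelihood(train, p)

    def test_zero_beta_zero_penalty(self):
        train = make_train()
        p = random_params(np.random.default_rng(7), 3)
        p.beta = np.zeros(3)
        p.lam = 5.0
        assert penalized_objective(train, p) == pytest.approx(
            marginal_log_likelihood(train, p), abs=1e-12
        )

    def test_ridge_only_worked_example(self):
        train = make_train(d=2, seed=8)
        p = GPHyperParams(
            beta=np.array([1.0, -2.0]), ell=1.0, ell_s=50.0,
            sigma_f2=0.5, sigma_n2=0.3, alpha=1.0, lam=2.0,
        )
        assert penalized_objective(train, p) == pytest.approx(
            marginal_log_likelihood(train, p) - 10.0, abs=1e-10
        )

    def test_gradient_matches_finite_differences(self):
        train = make_train(n=9, d=3, seed=9)
        rng = np.random.default_rng(10)
        theta = np.concatenate(
            [rng.standard_normal(3), rng.uniform(-0.5, 0.5, 4)]
        )
        Dx = cdist(train.X, train.X, "sqeuclidean")
        Ds = cdist(train.S, train.S, "sqeuclidean")
        _, g = _objective_and_grad(theta, train, Dx, Ds, 0.5, 0.3)
        num = np.zeros_like(theta)
        for j in range(len(theta)):
            e = np.zeros_like(theta)
            e[j] = 1e-6
            fp, _ = _objective_and_grad(theta + e, train, Dx, Ds, 0.5, 0.3)
            fm, _ = _objective_and_grad(theta - e, train, Dx, Ds, 0.5, 0.3)
            num[j] = (fp - fm) / 2e-6
        np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-7)


class TestPosterior:
    def test_matches_conditioning_oracle_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 21))
            d = int(rng.integers(1, 6))
            train = make_train(n=n, d=d, seed=int(rng.integers(1 << 30)))
            params = random_params(rng, d)
            state = GPModelState(params=params, train=train)
            xs = rng.standard_normal(d)
            ss = rng.uniform(0, 100, 2)
            pred = predict(state, xs[None], ss[None]).iloc[0]
            m_o, v_o = oracle_posterior(train, params, xs, ss)
            assert pred["mean"] == pytest.approx(m_o, abs=1e-8)
            assert pred["variance"] == pytest.approx(v_o, abs=1e-8)

    def test_noise_free_interpolation(self):
        train = make_train(n=8, seed=12)
        params = GPHyperParams(
            beta=np.zeros(3), ell=1.0, ell_s=50.0, sigma_f2=1.0, sigma_n2=1e-10,
        )
        state = GPModelState(params=params, train=train)
        pred = predict(state, train.X, train.S)
        np.testing.assert_allclose(pred["mean"], train.y, atol=1e-6)
        assert (pred["variance"] < 1e-5).all()

    def test_prior_reversion_far_away(self):
        train = make_train(n=8, seed=13)
        params = random_params(np.random.default_rng(14), 3)
        state = GPModelState(params=params, train=train)
        far_x = np.full(3, 1e4)
        far_s = np.full(2, 1e6)
        pred = predict(state, far_x[None], far_s[None]).iloc[0]
        assert pred["mean"] == pytest.approx(far_x @ params.beta, abs=1e-8)
        assert pred["variance"] == pytest.approx(
            params.sigma_f2 + params.sigma_n2, abs=1e-8
        )

    def test_variance_at_least_noise_floor(self):
        rng = np.random.default_rng(15)
        train = make_train(n=15, seed=16)
        params = random_params(rng, 3)
        state = GPModelState(params=params, train=train)
        pred = predict(state, rng.standard_normal((30, 3)), rng.uniform(0, 100, (30, 2)))
        assert (pred["variance"] >= params.sigma_n2 - 1e-10).all()

    def test_variance_ignores_observed_targets(self):
        train_a = make_train(n=12, seed=17)
        train_b = TrainingSet(
            X=train_a.X, S=train_a.S, y=train_a.y + 100.0,
            feature_names=train_a.feature_names,
            x_mean=train_a.x_mean, x_sd=train_a.x_sd,
        )
        params = random_params(np.random.default_rng(18), 3)
        rng = np.random.default_rng(19)
        xs, ss = rng.standard_normal((5, 3)), rng.uniform(0, 100, (5, 2))
        va = predict(GPModelState(params=params, train=train_a), xs, ss)["variance"]
        vb = predict(GPModelState(params=params, train=train_b), xs, ss)["variance"]
        np.testing.assert_allclose(va, vb, atol=1e-12)

    def test_extra_training_point_never_inflates_variance(self):
        rng = np.random.default_rng(20)
        train = make_train(n=10, seed=21)
        params = random_params(rng, 3)
        bigger = TrainingSet(
            X=np.vstack([train.X, rng.standard_normal(3)]),
            S=np.vstack([train.S, rng.uniform(0, 100, 2)]),
            y=np.append(train.y, 0.0),
            feature_names=train.feature_names,
            x_mean=train.x_mean, x_sd=train.x_sd,
        )
        xs, ss = rng.standard_normal((10, 3)), rng.uniform(0, 100, (10, 2))
        v_small = predict(GPModelState(params=params, train=train), xs, ss)["variance"]
        v_big = predict(GPModelState(params=params, train=bigger), xs, ss)["variance"]
        assert (v_big <= v_small + 1e-9).all()

    def test_feature_count_mismatch_raises(self):
        train = make_train()
        state = GPModelState(params=random_params(np.random.default_rng(22), 3), train=train)
        with pytest.raises(ValueError):
            predict(state, np.zeros((2, 5)), np.zeros((2, 2)))


class TestFit:
    def test_pure_linear_data_recovers_penalized_ls(self):
        """With sigma_f2 = 0 in the generator, the GP fit should agree with
        a direct elastic-net-style penalised least-squares solve."""
        rng = np.random.default_rng(23)
        n, d = 200, 4
        X = rng.standard_normal((n, d))
        beta_true = np.array([1.5, -1.0, 0.5, 0.0])
        y = X @ beta_true + 0.1 * rng.standard_normal(n)
        S = rng.uniform(0, 100, (n, 2))
        train = TrainingSet.from_raw(X, S, y, None)
        cfg = FitConfig(alpha=1.0, lam=0.5, n_restarts=2, seed=1)
        model = fit(train, cfg)

        # oracle: ridge with the penalty scaled to the Gaussian likelihood,
        # solved at the fitted noise level
        sn2 = model.params.sigma_n2
        lam_eff = 2.0 * cfg.lam * sn2  # J ~ -RSS/(2 sn2) - lam ||b||^2
        Xs = train.X
        beta_ls = np.linalg.solve(Xs.T @ Xs + lam_eff * np.eye(d), Xs.T @ train.y)
        np.testing.assert_allclose(model.params.beta, beta_ls, rtol=0.1, atol=0.02)

    def test_spatial_scale_recovered_within_factor_two(self):
        import povgp

        cfg = povgp.SyntheticConfig(
            n_communes=300, n_urban=60, n_regions=10, map_extent_km=500.0, seed=11
        )
        m = povgp.generate_commune_map(cfg)
        lf = povgp.generate_latent_field(m, cfg, source="cdr")
        train = TrainingSet.from_raw(lf.X, m.centroids, lf.y, lf.feature_names)
        model = fit(train, FitConfig(lam=0.1, seed=3))
        truth = cfg.source("cdr").ell_s
        assert truth / 2.0 <= model.params.ell_s <= truth * 2.0

    def test_objective_not_below_initialisation(self):
        train = make_train(n=40, d=3, seed=24)
        model = fit(train, FitConfig(n_restarts=2, max_iter=5, seed=0))
        assert np.isfinite(model.objective)

    def test_duplicating_points_does_not_inflate_noise(self):
        rng = np.random.default_rng(25)
        n, d = 60, 2
        X = rng.standard_normal((n, d))
        S = rng.uniform(0, 100, (n, 2))
        y = X @ np.array([1.0, -0.5]) + 0.3 * rng.standard_normal(n)
        t1 = TrainingSet.from_raw(X, S, y, None)
        t2 = TrainingSet.from_raw(
            np.vstack([X, X]), np.vstack([S, S]), np.concatenate([y, y]), None
        )
        m1 = fit(t1, FitConfig(lam=0.1, n_restarts=2, seed=2))
        m2 = fit(t2, FitConfig(lam=0.1, n_restarts=2, seed=2))
        assert m2.params.sigma_n2 <= m1.params.sigma_n2 * 1.5

    def test_large_lambda_shrinks_beta_monotonically(self):
        rng = np.random.default_rng(26)
        n, d = 80, 3
        X = rng.standard_normal((n, d))
        S = rng.uniform(0, 100, (n, 2))
        y = X @ np.array([1.0, -1.0, 0.5]) + 0.2 * rng.standard_normal(n)
        train = TrainingSet.from_raw(X, S, y, None)
        norms = []
        for lam in (0.0, 1.0, 10.0, 100.0, 1000.0):
            m = fit(train, FitConfig(lam=lam, n_restarts=1, seed=5))
            norms.append(np.linalg.norm(m.params.beta))
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05 * norms[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit(make_train(n=5), FitConfig())


class TestFeatureImportance:
    def _state(self, beta, names=None):
        d = len(beta)
        train = make_train(n=12, d=d)
        train.feature_names = names or [f"x{j}" for j in range(d)]
        params = GPHyperParams(
            beta=np.asarray(beta, dtype=float), ell=1.0, ell_s=10.0,
            sigma_f2=1.0, sigma_n2=0.1,
        )
        return GPModelState(params=params, train=train)

    def test_all_zero_all_pruned(self):
        fi = feature_importance(self._state([0.0, 0.0, 0.0]))
        assert fi["pruned"].all()

    def test_ranking_by_magnitude(self):
        fi = feature_importance(self._state([0.2, -1.5, 0.0]))
        assert fi["feature"].tolist()[:2] == ["x1", "x0"]
        assert fi.loc[fi["feature"] == "x2", "pruned"].item()
        assert fi.loc[0, "beta"] == -1.5

    def test_invariant_to_column_order(self):
        a = feature_importance(self._state([0.2, -1.5, 0.7], ["u", "v", "w"]))
        b = feature_importance(self._state([0.7, -1.5, 0.2], ["w", "v", "u"]))
        assert a["feature"].tolist() == b["feature"].tolist()
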