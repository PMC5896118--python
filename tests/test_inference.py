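"""Variational update correctness, ELBO bound, and fit behavior."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from nbgrn.distributions import NBParams, nb2_log_pmf
from nbgrn.inference import (
    FitConfig,
    RegressionProblem,
    _ncvmp_step,
    elbo,
    fit,
    initialize_state,
    neg_linear_predictor_expectation,
    update_beta,
    update_horseshoe,
    update_lambda,
    update_omega,
)

from conftest import make_problem


def _state_for(problem, config=None, mu=None, Sigma=None):
    config = config or FitConfig()
    state = initialize_state(problem, config)
    if mu is not None:
        state.mu = np.asarray(mu, dtype=float)
    if Sigma is not None:
        state.Sigma = np.asarray(Sigma, dtype=float)
    return state, config


class TestUpdateLambda:
    def test_substitution_zero_count(self):
        # y=0, E[omega]=1, E[exp(-X beta)]=1 -> Gamma(1, 2), mean 0.5
        y = np.array([0, 0])
        X = np.array([[1.0], [1.0]])
        problem = RegressionProblem(y, X)
        state, config = _state_for(problem, mu=np.array([0.0]), Sigma=np.array([[0.0]]))
        state.omega_grid = np.array([1.0])
        state.omega_weights = np.array([1.0])
        update_lambda(state, problem, config)
        assert state.lam_shape[0] == pytest.approx(1.0)
        assert state.lam_rate[0] == pytest.approx(2.0)
        assert state.e_lambda[0] == pytest.approx(0.5)

    def test_substitution_general(self):
        # y=5, E[omega]=2, E[exp(-eta)]=0.5 -> Gamma(7, 2)
        y = np.array([5, 5])
        X = np.array([[1.0], [1.0]])
        problem = RegressionProblem(y, X)
        mu = np.array([np.log(2.0)])  # exp(-mu) = 0.5 with Sigma = 0
        state, config = _state_for(problem, mu=mu, Sigma=np.array([[0.0]]))
        state.omega_grid = np.array([2.0])
        state.omega_weights = np.array([1.0])
        update_lambda(state, problem, config)
        assert state.lam_shape[0] == pytest.approx(7.0)
        assert state.lam_rate[0] == pytest.approx(2.0)

    def test_matches_conjugate_posterior_at_degenerate_beta(self):
        # with q(beta) a point mass and omega fixed, the exact posterior of
        # each latent rate is the conjugate Gamma(y + omega, 1 + omega e^-eta)
        y = np.array([4, 9])
        X = np.array([[0.5, 1.0], [-0.3, 1.0]])
        problem = RegressionProblem(y, X)
        beta = np.array([0.7, 1.2])
        omega = 50.0
        state, config = _state_for(problem, mu=beta, Sigma=np.zeros((2, 2)))
        state.omega_grid = np.array([omega])
        state.omega_weights = np.array([1.0])
        update_lambda(state, problem, config)
        eta = X @ beta
        np.testing.assert_allclose(state.lam_shape, y + omega)
        np.testing.assert_allclose(state.lam_rate, 1.0 + omega * np.exp(-eta))
        # large omega pins lambda near the model mean exp(eta)
        np.testing.assert_allclose(state.e_lambda, np.exp(eta), rtol=0.15)


class TestNegLinearPredictorExpectation:
    def test_zero_mean_zero_cov(self):
        problem = make_problem(seed=2, n=10, w=2)
        state, config = _state_for(problem, mu=np.zeros(3), Sigma=np.zeros((3, 3)))
        np.testing.assert_allclose(
            neg_linear_predictor_expectation(state, problem), np.ones(10)
        )

    def test_scalar_substitution(self):
        # X=1, mu=1, Sigma=[[2]] -> exp(-1 + 1) = 1
        y = np.array([1, 1])
        X = np.array([[1.0], [1.0]])
        problem = RegressionProblem(y, X)
        state, _ = _state_for(problem, mu=np.array([1.0]), Sigma=np.array([[2.0]]))
        np.testing.assert_allclose(
            neg_linear_predictor_expectation(state, problem), np.ones(2)
        )

    def test_against_monte_carlo_lognormal_mean(self):
        rng = np.random.default_rng(12)
        n, w = 4, 3
        X = np.column_stack([rng.normal(size=(n, w)), np.ones(n)])
        problem = RegressionProblem(np.ones(n, dtype=int), X, offset=rng.normal(size=n) * 0.1)
        A = rng.normal(size=(w + 1, w + 1)) * 0.2
        Sigma = A @ A.T + 0.05 * np.eye(w + 1)
        mu = rng.normal(size=w + 1) * 0.3
        state, _ = _state_for(problem, mu=mu, Sigma=Sigma)
        exact = neg_linear_predictor_expectation(state, problem)
        draws = rng.multivariate_normal(mu, Sigma, size=10**6)
        vals = np.exp(-(problem.X @ draws.T) - problem.offset[:, None])
        mc = vals.mean(axis=1)
        se = vals.std(axis=1) / np.sqrt(10**6)
        assert np.all(np.abs(exact - mc) < 3 * se)


class TestUpdateBeta:
    def test_complete_shrinkage_limit(self):
        problem = make_problem(seed=3)
        config = FitConfig()
        state = initialize_state(problem, config)
        update_lambda(state, problem, config)
        state.zeta2_scale = np.full(problem.n_predictors, 1e-12)  # E[1/zeta2] huge
        update_beta(state, problem, config)
        assert np.all(np.abs(state.mu[:-1]) < 1e-4)

    def test_fixed_point_of_inner_iteration(self):
        # iterate the raw NCVMP map with the other factors frozen; at its
        # fixed point the residual vanishes and the update leaves mu in place
        problem = make_problem(seed=4, n=40, w=2)
        config = FitConfig()
        state = initialize_state(problem, config)
        update_lambda(state, problem, config)
        for _ in range(400):
            state.mu, state.Sigma = _ncvmp_step(state, problem, config)
        mu_before = state.mu.copy()
        state.mu, state.Sigma = _ncvmp_step(state, problem, config)
        np.testing.assert_allclose(state.mu, mu_before, atol=1e-9)

    def test_posterior_mean_matches_grid_integration(self):
        # W=1 toy with fixed omega and fixed slope prior variance: the exact
        # posterior is a 2-d integral over (slope, intercept)
        rng = np.random.default_rng(5)
        n = 12
        x = rng.normal(size=n)
        X = np.column_stack([x, np.ones(n)])
        omega, b_true = 5.0, np.array([0.6, 1.5])
        mu_true = np.exp(X @ b_true)
        y = rng.negative_binomial(omega, omega / (omega + mu_true))
        problem = RegressionProblem(y, X)
        config = FitConfig(fixed_omega=omega, fixed_zeta2=1.0, tol=1e-10, max_iter=2000)
        state = fit(problem, config)

        slopes = np.linspace(-2.5, 2.5, 401)
        intercepts = np.linspace(-2.0, 4.0, 401)
        S, C = np.meshgrid(slopes, intercepts, indexing="ij")
        logp = (
            stats.norm.logpdf(S, scale=1.0)
            + stats.norm.logpdf(C, scale=np.sqrt(config.intercept_var))
        )
        for yi, xi in zip(y, x):
            mu_grid = np.exp(xi * S + C)
            logp += stats.nbinom.logpmf(yi, omega, omega / (omega + mu_grid))
        w = np.exp(logp - logsumexp(logp))
        slope_mean = float(np.sum(w * S))
        assert abs(state.mu[0] - slope_mean) < 0.05


class TestUpdateOmega:
    def test_weights_normalized(self, fitted_small):
        _, state = fitted_small
        assert state.omega_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(state.omega_weights >= 0)

    def test_dispersion_recovery(self):
        # intercept-only data generated at omega=2: posterior mean lands near it
        rng = np.random.default_rng(6)
        n, omega = 500, 2.0
        mu = np.exp(2.0)
        y = rng.negative_binomial(omega, omega / (omega + mu), size=n)
        problem = RegressionProblem(y, np.ones((n, 1)))
        state = fit(problem, FitConfig())
        assert 1.5 <= state.e_omega <= 2.7

    def test_initial_weights_are_prior_on_grid(self):
        # before any data pass, q(omega) is the gamma prior restricted to the grid
        problem = make_problem(seed=7, n=5, w=1)
        config = FitConfig()
        state = initialize_state(problem, config)
        grid = state.omega_grid
        logp = stats.gamma.logpdf(grid, config.omega_prior_shape, scale=1.0 / config.omega_prior_rate)
        expected = np.exp(logp - logsumexp(logp))
        np.testing.assert_allclose(state.omega_weights, expected, atol=1e-12)


class TestUpdateHorseshoe:
    def test_substitution_local_scale(self):
        # E[beta_w^2] = 1 and reciprocal-auxiliary expectation 0.5 -> IG(1, 1)
        problem = make_problem(seed=8, n=10, w=1)
        config = FitConfig()
        state = initialize_state(problem, config)
        state.mu = np.array([1.0, 0.0])
        state.Sigma = np.zeros((2, 2))
        state.a_shape, state.a_scale = 1.0, np.array([2.0])  # E[1/a] = 0.5
        state.tau2_scale = np.inf  # freeze downstream contributions for the check
        update_horseshoe(state, problem, config)
        assert state.zeta2_shape == pytest.approx(1.0)
        assert state.zeta2_scale[0] == pytest.approx(1.0)
        assert state.e_inv_zeta2[0] == pytest.approx(1.0)

    def test_closed_form_shapes(self):
        problem = make_problem(seed=9, n=20, w=3)
        config = FitConfig()
        state = initialize_state(problem, config)
        update_lambda(state, problem, config)
        update_beta(state, problem, config)
        update_horseshoe(state, problem, config)
        assert state.zeta2_shape == 1.0
        assert state.a_shape == 1.0
        assert state.tau2_shape == pytest.approx(0.5 + 3 / 2.0)  # (1 + W)/2
        assert state.b_shape == 1.0
        assert state.sigma2_shape == 0.5

    def test_active_coefficient_shrinks_less(self):
        # across seeds, the local-scale factor of the truly active predictor
        # is wider (larger IG scale) than that of a null predictor
        diffs = []
        for seed in range(20):
            problem = make_problem(seed=100 + seed)
            state = fit(problem, FitConfig())
            diffs.append(state.zeta2_scale[0] - state.zeta2_scale[1])
        assert np.median(diffs) > 0


def _toy_fixed_problem(seed=10, n=8):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = np.column_stack([x, np.ones(n)])
    omega = 3.0
    mu = np.exp(0.5 * x + 1.0)
    y = rng.negative_binomial(omega, omega / (omega + mu))
    return RegressionProblem(y, X), omega


def _log_evidence_2d(problem, omega, zeta2, intercept_var):
    slopes = np.linspace(-4.0, 4.0, 501)
    intercepts = np.linspace(-4.0, 6.0, 501)
    S, C = np.meshgrid(slopes, intercepts, indexing="ij")
    logp = stats.norm.logpdf(S, scale=np.sqrt(zeta2)) + stats.norm.logpdf(
        C, scale=np.sqrt(intercept_var)
    )
    for yi, xrow, off in zip(problem.y, problem.X, problem.offset):
        mu_grid = np.exp(xrow[0] * S + C + off)
        logp += stats.nbinom.logpmf(int(yi), omega, omega / (omega + mu_grid))
    cell = (slopes[1] - slopes[0]) * (intercepts[1] - intercepts[0])
    return float(logsumexp(logp) + np.log(cell))


class TestElbo:
    def test_elbo_bounded_by_evidence(self):
        problem, omega = _toy_fixed_problem()
        config = FitConfig(fixed_omega=omega, fixed_zeta2=1.0, tol=1e-10, max_iter=2000)
        state = fit(problem, config)
        log_z = _log_evidence_2d(problem, omega, 1.0, config.intercept_var)
        final = elbo(state, problem, config)
        assert final < log_z

    def test_permutation_invariance(self):
        problem = make_problem(seed=11, n=30, w=4)
        perm = [2, 0, 3, 1]
        X2 = np.column_stack([problem.X[:, perm], np.ones(problem.n_obs)])
        problem2 = RegressionProblem(problem.y, X2)
        s1 = fit(problem, FitConfig())
        s2 = fit(problem2, FitConfig())
        assert s1.elbo_trace[-1] == pytest.approx(s2.elbo_trace[-1], rel=1e-8)

    def test_elbo_stable_at_convergence(self, fitted_small):
        _, state = fitted_small
        assert state.converged
        trace = state.elbo_trace
        assert abs(trace[-1] - trace[-2]) < 1e-6 * abs(trace[-1])

    def test_damping_keeps_elbo_near_running_maximum(self, fitted_small):
        _, state = fitted_small
        trace = np.asarray(state.elbo_trace)
        assert trace[-1] >= trace.max() - 1e-6 * abs(trace.max())


class TestFit:
    def test_recovers_active_coefficient(self):
        hits_active, hits_null = [], []
        for seed in range(20):
            problem = make_problem(seed=200 + seed)
            state = fit(problem, FitConfig())
            sd = np.sqrt(np.diag(state.Sigma))
            lo = state.mu - 1.959964 * sd
            hi = state.mu + 1.959964 * sd
            hits_active.append(lo[0] > 0 or hi[0] < 0)  # CI excludes 0
            hits_null.append(np.all((lo[1:-1] <= 0) & (hi[1:-1] >= 0)))
        assert sum(hits_active) > 10
        assert sum(hits_null) > 10

    def test_null_data_selects_nothing(self):
        # constant counts equal to exp(intercept): all slope CIs contain 0
        rng = np.random.default_rng(13)
        n, w = 40, 4
        X = np.column_stack([rng.normal(size=(n, w)), np.ones(n)])
        y = np.full(n, 20)
        state = fit(RegressionProblem(y, X), FitConfig())
        sd = np.sqrt(np.diag(state.Sigma))[:-1]
        assert np.all(np.abs(state.mu[:-1]) < 1.959964 * sd)

    def test_offset_equivariance(self):
        problem = make_problem(seed=14)
        doubled = RegressionProblem(
            problem.y, problem.X, offset=problem.offset + np.log(2.0)
        )
        s1 = fit(problem, FitConfig())
        s2 = fit(doubled, FitConfig())
        assert s2.mu[-1] - s1.mu[-1] == pytest.approx(-np.log(2.0), abs=0.1)
        sd = np.sqrt(np.diag(s1.Sigma))[:-1] + np.sqrt(np.diag(s2.Sigma))[:-1]
        assert np.all(np.abs(s1.mu[:-1] - s2.mu[:-1]) < 2 * sd)

    def test_deterministic_traces(self):
        problem = make_problem(seed=15)
        t1 = fit(problem, FitConfig()).elbo_trace
        t2 = fit(problem, FitConfig()).elbo_trace
        assert t1 == t2

    def test_shrinkage_monotone_in_signal_strength(self):
        # scaling all true coefficients up does not reduce the number of
        # active coefficients whose CI excludes zero (median over seeds)
        def n_called(scale, seed):
            beta = np.zeros(6)
            beta[0], beta[1], beta[-1] = 0.4 * scale, -0.4 * scale, 2.0
            problem = make_problem(seed=seed, beta=beta)
            state = fit(problem, FitConfig())
            sd = np.sqrt(np.diag(state.Sigma))
            return int(np.sum(np.abs(state.mu[:2]) > 1.959964 * sd[:2]))

        weak = [n_called(1.0, 300 + s) for s in range(9)]
        strong = [n_called(2.0, 300 + s) for s in range(9)]
        assert np.median(strong) >= np.median(weak)

    def test_nonconvergence_warns_not_raises(self):
        problem = make_problem(seed=16)
        with pytest.warns(RuntimeWarning):
            state = fit(problem, FitConfig(max_iter=2))
        assert not state.converged


class TestConfig:
    def test_roundtrip_through_file(self, tmp_path):
        config = FitConfig(max_iter=123, tol=1e-5, seed=9, fixed_omega=2.0)
        path = tmp_path / "config.txt"
        config.to_file(path)
        loaded = FitConfig.from_file(path)
        assert loaded.max_iter == 123
        assert loaded.tol == pytest.approx(1e-5)
        assert loaded.fixed_omega == pytest.approx(2.0)
        assert loaded.fixed_zeta2 is None
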