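"""Variational inference for sparse negative-binomial regression.

One gene's counts ``y`` at times 2..L are regressed on all other genes'
(transformed) values at times 1..L-1 under an NB2 observation model with a
horseshoe prior on the slopes.  Inference uses a mean-field approximation

    q = prod_t q(lambda_t) . q(beta) . q(omega) . prod_w q(zeta2_w) q(a_w)
        . q(tau2) q(b) q(sigma2)

over the Poisson-Gamma augmented model.  All factors except ``q(beta)`` and
``q(omega)`` have closed-form conjugate updates; ``q(beta)`` is Gaussian and
updated by a non-conjugate variational message passing (NCVMP) step, and
``q(omega)`` is handled by quadrature on a fixed log-spaced grid.  Coordinate
sweeps run until the evidence lower bound (ELBO) stabilizes.

Because the NCVMP step does not guarantee a monotone ELBO, the beta update is
damped: when the bound drops, the step is halved (convex combination with the
previous Gaussian) up to a fixed number of times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionProblem",
    "FitConfig",
    "VariationalState",
    "update_lambda",
    "neg_linear_predictor_expectation",
    "update_beta",
    "update_omega",
    "update_horseshoe",
    "elbo",
    "initialize_state",
    "fit",
]


class RegressionProblem:
    """One gene's regression: response counts, lagged design matrix, offsets.

    Parameters
    ----------
    y : array of non-negative integers, length N
        Counts of the target gene at times 2..L across replicates.
    X : array, N x (W+1)
        Predictor values at times 1..L-1 aligned row-wise with ``y``; the
        final column must be exactly 1 (intercept).  Transitions never cross
        replicate boundaries.
    offset : array, length N, optional
        Log size factor of each response sample; zeros when omitted.
    predictor_names : sequence of str, optional
        Labels for the W non-intercept columns.
    """

    def __init__(self, y, X, offset=None, predictor_names=None):
        y = np.asarray(y)
        yf = np.asarray(y, dtype=float)
        if yf.ndim != 1:
            raise ValueError("y must be a 1-d array of counts")
        if not np.allclose(yf, np.round(yf)) or np.any(yf < 0):
            raise ValueError("y must contain non-negative integer counts")
        self.y = np.round(yf).astype(np.int64)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != self.y.size:
            raise ValueError("X must be 2-d with one row per element of y")
        if self.y.size < 2:
            raise ValueError("need at least 2 transition rows")
        if not np.all(X[:, -1] == 1.0):
            raise ValueError("last column of X must be the all-ones intercept")
        self.X = X
        if offset is None:
            offset = np.zeros(self.y.size)
        self.offset = np.asarray(offset, dtype=float)
        if self.offset.shape != self.y.shape:
            raise ValueError("offset must match y in length")
        W = X.shape[1] - 1
        if predictor_names is None:
            predictor_names = [f"x{w}" for w in range(W)]
        if len(predictor_names) != W:
            raise ValueError("need one name per non-intercept predictor")
        self.predictor_names = list(predictor_names)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1] - 1


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the variational optimizer.

    ``omega_grid_*`` set the quadrature grid for the dispersion (log-uniform).
    ``fixed_omega`` / ``fixed_zeta2`` freeze the dispersion or replace the
    horseshoe with a fixed slope prior variance; both exist for validation
    against brute-force posteriors on tiny problems.
    """

    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    omega_grid_size: int = 200
    omega_grid_min: float = 1e-2
    omega_grid_max: float = 1e3
    damping_max_halvings: int = 8
    damping_tol: float = 1e-8
    exp_clip: float = 50.0
    intercept_var: float = 100.0
    omega_prior_shape: float = 0.01
    omega_prior_rate: float = 0.01
    init_sigma_diag: float = 0.1
    fixed_omega: float | None = None
    fixed_zeta2: float | None = None

    def omega_grid(self) -> np.ndarray:
        if self.fixed_omega is not None:
            return np.array([self.fixed_omega])
        return np.exp(
            np.linspace(
                np.log(self.omega_grid_min),
                np.log(self.omega_grid_max),
                self.omega_grid_size,
            )
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in self.__dict__.items():
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {key!r}")
                if val == "None":
                    kwargs[key] = None
                elif types[key].startswith("int"):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class VariationalState:
    """All approximating-distribution parameters for one gene's fit.

    Gamma factors are (shape, rate); inverse-gamma factors are (shape, scale).
    ``omega_weights`` are normalized quadrature weights on ``omega_grid``.
    """

    lam_shape: np.ndarray
    lam_rate: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    omega_grid: np.ndarray
    omega_weights: np.ndarray
    zeta2_shape: float
    zeta2_scale: np.ndarray
    a_shape: float
    a_scale: np.ndarray
    tau2_shape: float
    tau2_scale: float
    b_shape: float
    b_scale: float
    sigma2_shape: float
    sigma2_scale: float
    n_iter: int = 0
    converged: bool = False
    n_clip_events: int = 0
    elbo_trace: list = field(default_factory=list)

    # -- expectations -----------------------------------------------------
    @property
    def e_omega(self) -> float:
        return float(np.dot(self.omega_weights, self.omega_grid))

    @property
    def e_lambda(self) -> np.ndarray:
        return self.lam_shape / self.lam_rate

    @property
    def e_log_lambda(self) -> np.ndarray:
        return digamma(self.lam_shape) - np.log(self.lam_rate)

    @property
    def e_inv_zeta2(self) -> np.ndarray:
        return self.zeta2_shape / self.zeta2_scale

    @property
    def e_inv_a(self) -> np.ndarray:
        return self.a_shape / self.a_scale

    @property
    def e_inv_tau2(self) -> float:
        return self.tau2_shape / self.tau2_scale

    @property
    def e_inv_b(self) -> float:
        return self.b_shape / self.b_scale

    @property
    def e_inv_sigma2(self) -> float:
        return self.sigma2_shape / self.sigma2_scale

    @property
    def e_beta2(self) -> np.ndarray:
        return self.mu**2 + np.diag(self.Sigma)


def initialize_state(problem: RegressionProblem, config: FitConfig) -> VariationalState:
    """Deterministic starting point: zero slopes, intercept at the log mean rate."""
    W = problem.n_predictors
    mu = np.zeros(W + 1)
    s = np.exp(problem.offset)
    mu[-1] = np.log(np.mean(problem.y / s) + 1e-8)
    Sigma = config.init_sigma_diag * np.eye(W + 1)
    grid = config.omega_grid()
    if config.fixed_omega is not None:
        weights = np.array([1.0])
    else:
        logw = (config.omega_prior_shape - 1.0) * np.log(grid) - config.omega_prior_rate * grid
        weights = np.exp(logw - logsumexp(logw))
    state = VariationalState(
        lam_shape=np.maximum(problem.y.astype(float), 1e-8) + 1.0,
        lam_rate=np.ones(problem.n_obs),
        mu=mu,
        Sigma=Sigma,
        omega_grid=grid,
        omega_weights=weights,
        zeta2_shape=1.0,
        zeta2_scale=np.ones(W),
        a_shape=1.0,
        a_scale=np.ones(W),
        tau2_shape=0.5 + W / 2.0,
        tau2_scale=1.0,
        b_shape=1.0,
        b_scale=1.0,
        sigma2_shape=0.5,
        sigma2_scale=1.0,
    )
    return state


def neg_linear_predictor_expectation(
    state: VariationalState, problem: RegressionProblem, clip: float = 50.0
) -> np.ndarray:
    """E_q[exp(-(X_t beta + offset_t))] per row, by the log-normal mean identity.

    Equals ``exp(-X_t mu - offset_t + 0.5 X_t Sigma X_t^T)``.  The exponent is
    clipped at ``±clip`` to guard overflow; clip events are counted on the
    state and logged.
    """
    quad = np.einsum("ij,jk,ik->i", problem.X, state.Sigma, problem.X)
    expo = -problem.X @ state.mu - problem.offset + 0.5 * quad
    n_clip = int(np.sum(np.abs(expo) > clip))
    if n_clip:
        state.n_clip_events += n_clip
        logger.warning("clipped %d exponent(s) at ±%g in E[exp(-X beta)]", n_clip, clip)
    return np.exp(np.clip(expo, -clip, clip))


def update_lambda(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> None:
    """Conjugate update of every q(lambda_t) to Gamma(y_t + E[omega], 1 + E[omega] E[exp(-eta_t)])."""
    e_om = state.e_omega
    negexp = neg_linear_predictor_expectation(state, problem, clip=config.exp_clip)
    state.lam_shape = problem.y + e_om
    state.lam_rate = 1.0 + e_om * negexp


def _prior_precision(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> np.ndarray:
    W = problem.n_predictors
    if config.fixed_zeta2 is not None:
        diag = np.full(W, 1.0 / config.fixed_zeta2)
    else:
        diag = state.e_inv_zeta2
    return np.diag(np.append(diag, 1.0 / config.intercept_var))


def _ncvmp_step(state: VariationalState, problem: RegressionProblem, config: FitConfig):
    """One raw NCVMP Gaussian update for beta; returns (mu_new, Sigma_new)."""
    w = neg_linear_predictor_expectation(state, problem, clip=config.exp_clip)
    e_lam = state.e_lambda
    e_om = state.e_omega
    M = _prior_precision(state, problem, config)
    A = e_om * (problem.X.T * (e_lam * w)) @ problem.X + M
    try:
        Sigma_new = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"singular precision matrix in beta update (cond issues); "
            f"N={problem.n_obs}, W={problem.n_predictors}"
        ) from exc
    Sigma_new = 0.5 * (Sigma_new + Sigma_new.T)
    grad = e_om * problem.X.T @ (e_lam * w - 1.0) - M @ state.mu
    mu_new = state.mu + Sigma_new @ grad
    return mu_new, Sigma_new


def update_beta(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> None:
    """Damped NCVMP update of q(beta).

    NCVMP does not guarantee a monotone bound, so if the ELBO drops by more
    than ``config.damping_tol`` the step is halved (convex combination of the
    old and proposed Gaussians) up to ``config.damping_max_halvings`` times;
    if it still drops, the un-moved state is kept for this sweep.
    """
    elbo_before = elbo(state, problem, config)
    mu_old, Sigma_old = state.mu.copy(), state.Sigma.copy()
    mu_new, Sigma_new = _ncvmp_step(state, problem, config)
    frac = 1.0
    for _ in range(config.damping_max_halvings + 1):
        state.mu = (1.0 - frac) * mu_old + frac * mu_new
        state.Sigma = (1.0 - frac) * Sigma_old + frac * Sigma_new
        if elbo(state, problem, config) >= elbo_before - config.damping_tol:
            return
        frac *= 0.5
    state.mu, state.Sigma = mu_old, Sigma_old


def update_omega(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> None:
    """Quadrature update of q(omega) on the fixed grid.

    Pointwise log weight at omega: E_q[sum_t log Gamma(lambda_t; omega,
    omega exp(-eta_t))] + log p(omega), normalized by log-sum-exp.
    """
    if config.fixed_omega is not None:
        return
    grid = state.omega_grid
    eta_bar = problem.X @ state.mu + problem.offset
    negexp = neg_linear_predictor_expectation(state, problem, clip=config.exp_clip)
    e_lam = state.e_lambda
    e_log_lam = state.e_log_lambda
    N = problem.n_obs
    s1 = float(np.sum(eta_bar))
    s2 = float(np.sum(e_log_lam))
    s3 = float(np.sum(e_lam * negexp))
    logw = (
        N * grid * np.log(grid)
        - grid * s1
        - N * gammaln(grid)
        + (grid - 1.0) * s2
        - grid * s3
        + (config.omega_prior_shape - 1.0) * np.log(grid)
        - config.omega_prior_rate * grid
    )
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        raise FloatingPointError(
            "q(omega) weights underflowed to zero everywhere; widen or shift the omega grid"
        )
    state.omega_weights = np.exp(logw - norm)


def update_horseshoe(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> None:
    """Closed-form inverse-gamma updates of the horseshoe chain.

    q(zeta2_w) = IG(1, E[beta_w^2]/2 + E[1/a_w]);  q(a_w) = IG(1, E[1/zeta2_w]
    + E[1/tau2]);  q(tau2) = IG((1+W)/2, E[1/b] + sum_w E[1/a_w]);
    q(b) = IG(1, E[1/tau2] + E[1/sigma2]);  q(sigma2) = IG(1/2, E[1/b]).
    """
    if config.fixed_zeta2 is not None:
        return
    e_beta2 = state.e_beta2[:-1]
    state.zeta2_shape = 1.0
    state.zeta2_scale = 0.5 * e_beta2 + state.e_inv_a
    state.a_shape = 1.0
    state.a_scale = state.e_inv_zeta2 + state.e_inv_tau2
    W = problem.n_predictors
    state.tau2_shape = 0.5 + W / 2.0
    state.tau2_scale = state.e_inv_b + float(np.sum(state.e_inv_a))
    state.b_shape = 1.0
    state.b_scale = state.e_inv_tau2 + state.e_inv_sigma2
    state.sigma2_shape = 0.5
    state.sigma2_scale = state.e_inv_b


def _invgamma_entropy(shape, scale):
    return shape + np.log(scale) + gammaln(shape) - (1.0 + shape) * digamma(shape)


def _invgamma_e_log(shape, scale):
    return np.log(scale) - digamma(shape)


def _omega_cell_widths(grid: np.ndarray) -> np.ndarray:
    if grid.size == 1:
        return np.array([1.0])
    mids = 0.5 * (grid[1:] + grid[:-1])
    lo = np.concatenate([[grid[0] - (mids[0] - grid[0])], mids])
    hi = np.concatenate([mids, [grid[-1] + (grid[-1] - mids[-1])]])
    return hi - lo


def elbo(state: VariationalState, problem: RegressionProblem, config: FitConfig) -> float:
    """Evidence lower bound E_q[log p(y, theta)] - E_q[log q(theta)].

    The Poisson latent rates are integrated through their Gamma factors, the
    dispersion through the quadrature weights (interpreted as a piecewise-
    constant density on the grid cells), and the horseshoe chain through its
    inverse-gamma factors.  In fixed-omega / fixed-zeta2 validation modes the
    corresponding prior and entropy terms drop out so the bound is comparable
    with brute-force evidence for the reduced model.
    """
    y = problem.y.astype(float)
    e_lam = state.e_lambda
    e_log_lam = state.e_log_lambda
    negexp = neg_linear_predictor_expectation(state, problem, clip=config.exp_clip)
    eta_bar = problem.X @ state.mu + problem.offset
    grid, wts = state.omega_grid, state.omega_weights

    # E over q(omega) of functions appearing in the Gamma(lambda | ...) density
    if config.fixed_omega is not None:
        om = config.fixed_omega
        e_om, e_om_log_om, e_lgam_om = om, om * np.log(om), gammaln(om)
    else:
        e_om = float(np.dot(wts, grid))
        e_om_log_om = float(np.dot(wts, grid * np.log(grid)))
        e_lgam_om = float(np.dot(wts, gammaln(grid)))

    total = 0.0
    # E[log p(y_t | lambda_t)], Poisson
    total += float(np.sum(y * e_log_lam - e_lam - gammaln(y + 1.0)))
    # E[log p(lambda_t | X, beta, omega)], Gamma with rate omega exp(-eta)
    N = problem.n_obs
    total += (
        N * e_om_log_om
        - e_om * float(np.sum(eta_bar))
        + (e_om - 1.0) * float(np.sum(e_log_lam))
        - e_om * float(np.sum(e_lam * negexp))
        - N * e_lgam_om
    )
    # E[log p(beta)]
    e_beta2 = state.e_beta2
    if config.fixed_zeta2 is not None:
        e_log_zeta2 = np.full(problem.n_predictors, np.log(config.fixed_zeta2))
        e_inv_zeta2 = np.full(problem.n_predictors, 1.0 / config.fixed_zeta2)
    else:
        e_log_zeta2 = _invgamma_e_log(state.zeta2_shape, state.zeta2_scale)
        e_inv_zeta2 = state.e_inv_zeta2
    total += float(
        np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * e_log_zeta2 - 0.5 * e_inv_zeta2 * e_beta2[:-1])
    )
    total += -0.5 * np.log(2 * np.pi * config.intercept_var) - e_beta2[-1] / (
        2.0 * config.intercept_var
    )
    # prior on omega
    if config.fixed_omega is None:
        total += float(
            np.dot(
                wts,
                config.omega_prior_shape * np.log(config.omega_prior_rate)
                - gammaln(config.omega_prior_shape)
                + (config.omega_prior_shape - 1.0) * np.log(grid)
                - config.omega_prior_rate * grid,
            )
        )
    # horseshoe chain priors
    if config.fixed_zeta2 is None:
        e_log_a = _invgamma_e_log(state.a_shape, state.a_scale)
        e_log_tau2 = _invgamma_e_log(state.tau2_shape, state.tau2_scale)
        e_log_b = _invgamma_e_log(state.b_shape, state.b_scale)
        e_log_sigma2 = _invgamma_e_log(state.sigma2_shape, state.sigma2_scale)
        lg_half = gammaln(0.5)
        total += float(
            np.sum(-0.5 * e_log_a - lg_half - 1.5 * e_log_zeta2 - state.e_inv_a * e_inv_zeta2)
        )
        total += float(
            np.sum(
                -0.5 * e_log_tau2 - lg_half - 1.5 * e_log_a - state.e_inv_tau2 * state.e_inv_a
            )
        )
        total += -0.5 * e_log_b - lg_half - 1.5 * e_log_tau2 - state.e_inv_b * state.e_inv_tau2
        total += (
            -0.5 * e_log_sigma2 - lg_half - 1.5 * e_log_b - state.e_inv_sigma2 * state.e_inv_b
        )
        total += -e_log_sigma2  # improper p(sigma2) ∝ 1/sigma2

    # entropies
    total += float(
        np.sum(
            state.lam_shape
            - np.log(state.lam_rate)
            + gammaln(state.lam_shape)
            + (1.0 - state.lam_shape) * digamma(state.lam_shape)
        )
    )
    k = state.mu.size
    sign, logdet = np.linalg.slogdet(state.Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("q(beta) covariance is not positive definite")
    total += 0.5 * (k * (1.0 + np.log(2 * np.pi)) + logdet)
    if config.fixed_omega is None:
        widths = _omega_cell_widths(grid)
        nz = wts > 1e-300
        total += -float(np.sum(wts[nz] * (np.log(wts[nz]) - np.log(widths[nz]))))
    if config.fixed_zeta2 is None:
        total += float(np.sum(_invgamma_entropy(state.zeta2_shape, state.zeta2_scale)))
        total += float(np.sum(_invgamma_entropy(state.a_shape, state.a_scale)))
        total += float(_invgamma_entropy(state.tau2_shape, state.tau2_scale))
        total += float(_invgamma_entropy(state.b_shape, state.b_scale))
        total += float(_invgamma_entropy(state.sigma2_shape, state.sigma2_scale))
    return float(total)


def fit(problem: RegressionProblem, config: FitConfig | None = None) -> VariationalState:
    """Coordinate-ascent fit: lambda -> beta -> omega -> horseshoe per sweep.

    Stops when |ΔELBO| < tol·|ELBO| or after ``max_iter`` sweeps; in the
    latter case the state is returned with ``converged=False`` and a warning
    is emitted (never an exception).
    """
    if config is None:
        config = FitConfig()
    state = initialize_state(problem, config)
    prev = -np.inf
    for it in range(1, config.max_iter + 1):
        update_lambda(state, problem, config)
        update_beta(state, problem, config)
        update_omega(state, problem, config)
        update_horseshoe(state, problem, config)
        current = elbo(state, problem, config)
        state.elbo_trace.append(current)
        state.n_iter = it
        if np.isfinite(prev) and abs(current - prev) < config.tol * abs(current):
            state.converged = True
            break
        prev = current
    if not state.converged:
        warnings.warn(
            f"variational fit did not converge in {config.max_iter} sweeps "
            f"(last |dELBO| = {abs(current - prev):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("non-convergence after %d sweeps", config.max_iter)
    return state
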