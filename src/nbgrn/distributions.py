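"""Probability densities and distributional identities underlying the model.

The observation model is the NB2 negative binomial: a count ``y`` with mean
``mu`` and dispersion ``omega`` has variance ``mu + mu**2 / omega``.  Writing
the NB2 as a Poisson-Gamma mixture (``y ~ Pois(lam)``,
``lam ~ Gamma(omega, rate=omega/mu)``) is what makes the variational scheme
tractable, and the horseshoe prior on regression coefficients is represented
as a chain of inverse-gamma scale mixtures terminating in a half-Cauchy
marginal.  The self-check operations in this module assert those identities
numerically; the test suite leans on them as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "NBParams",
    "HorseshoeHyper",
    "nb2_log_pmf",
    "nb2_rvs",
    "poisson_gamma_mixture_check",
    "sample_horseshoe_scale_chain",
    "horseshoe_marginal_check",
    "joint_log_prob",
]


@dataclass(frozen=True)
class NBParams:
    """NB2 parameter pair: mean ``mu`` > 0 and dispersion ``omega`` > 0.

    Variance under NB2 is ``mu + mu**2 / omega``; large ``omega`` recovers
    the Poisson limit.
    """

    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and np.isfinite(self.mean)):
            raise ValueError(f"NB2 mean must be positive and finite, got {self.mean}")
        if not (self.dispersion > 0 and np.isfinite(self.dispersion)):
            raise ValueError(
                f"NB2 dispersion must be positive and finite, got {self.dispersion}"
            )

    @property
    def variance(self) -> float:
        return self.mean + self.mean**2 / self.dispersion


@dataclass
class HorseshoeHyper:
    """Hyper-parameter state of the horseshoe hierarchy for one regression.

    Per-coefficient local scales ``zeta2`` (variance of each slope), their
    inverse-gamma auxiliaries ``a``, the global scale ``tau2`` with auxiliary
    ``b``, and the top-level ``sigma2``.  ``intercept_var`` is the fixed
    normal prior variance on the constant term and (``omega_shape``,
    ``omega_rate``) parameterize the gamma prior on the dispersion.
    """

    zeta2: np.ndarray
    a: np.ndarray
    tau2: float
    b: float
    sigma2: float
    intercept_var: float = 100.0
    omega_shape: float = 0.01
    omega_rate: float = 0.01

    def __post_init__(self) -> None:
        self.zeta2 = np.asarray(self.zeta2, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.zeta2.shape != self.a.shape:
            raise ValueError("zeta2 and a must have one entry per predictor")
        for name in ("tau2", "b", "sigma2", "intercept_var", "omega_shape", "omega_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (np.all(self.zeta2 > 0) and np.all(self.a > 0)):
            raise ValueError("all local scales must be strictly positive")

    @property
    def n_predictors(self) -> int:
        return self.zeta2.size


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if not np.allclose(yf, np.round(yf)):
            raise ValueError("counts must be integers")
        y = np.round(yf).astype(np.int64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return y


def nb2_log_pmf(y, params: NBParams) -> np.ndarray | float:
    """Log pmf of the NB2 distribution at count(s) ``y``.

    Uses the size/probability form ``NB(r=omega, p=omega/(omega+mu))`` which
    has mean ``mu`` and variance ``mu + mu**2/omega``.
    """
    yv = _validate_counts(y)
    r = params.dispersion
    mu = params.mean
    # log pmf written directly for numerical stability at large r
    out = (
        gammaln(yv + r)
        - gammaln(r)
        - gammaln(yv + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + yv * (np.log(mu) - np.log(r + mu))
    )
    return out if np.ndim(y) else float(out)


def nb2_rvs(params: NBParams, size, rng: np.random.Generator) -> np.ndarray:
    """Draw NB2 variates with mean ``params.mean`` and dispersion ``params.dispersion``."""
    p = params.dispersion / (params.dispersion + params.mean)
    return rng.negative_binomial(params.dispersion, p, size=size)


def poisson_gamma_mixture_check(
    mean: float, omega: float, n_draws: int, seed: int
) -> float:
    """Max absolute deviation between the NB2 pmf and its Poisson-Gamma mixture.

    Draws ``lam ~ Gamma(omega, rate=omega/mean)`` and averages the Poisson pmf
    over the draws; the marginal of ``y`` is then NB2(mean, omega).  Returns
    ``max_y |NB2 pmf(y) - MC estimate(y)|`` over a support covering essentially
    all of the mass.  Serves as a numerical self-test of the augmentation.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10^4 for a meaningful check")
    params = NBParams(mean=mean, dispersion=omega)
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=omega, scale=mean / omega, size=n_draws)
    y_max = int(stats.nbinom.ppf(1.0 - 1e-6, omega, omega / (omega + mean))) + 5
    ys = np.arange(y_max + 1)
    # accumulate E_lam[Pois pmf(y)] in draw chunks to bound memory
    acc = np.zeros(ys.size)
    lgam = gammaln(ys + 1.0)
    for start in range(0, n_draws, 50_000):
        chunk = lam[start : start + 50_000]
        log_pmf = ys[:, None] * np.log(chunk)[None, :] - chunk[None, :] - lgam[:, None]
        acc += np.exp(log_pmf).sum(axis=1)
    mixture_pmf = acc / n_draws
    exact_pmf = np.exp(nb2_log_pmf(ys, params))
    return float(np.max(np.abs(exact_pmf - mixture_pmf)))


def sample_horseshoe_scale_chain(
    tau: float, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw local variances ``zeta2`` from the inverse-gamma chain at fixed ``tau``.

    ``a ~ InvGamma(1/2, scale=1/tau^2)`` then ``zeta2 ~ InvGamma(1/2, scale=1/a)``;
    marginally ``sqrt(zeta2) ~ halfCauchy(0, tau)``.
    """
    a = stats.invgamma.rvs(0.5, scale=1.0 / tau**2, size=n_draws, random_state=rng)
    return stats.invgamma.rvs(0.5, scale=1.0 / a, size=n_draws, random_state=rng)


def horseshoe_marginal_check(tau: float, n_draws: int, seed: int) -> float:
    """KS distance between chain draws of ``sqrt(zeta2)`` and halfCauchy(0, tau)."""
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10^4 for a meaningful check")
    rng = np.random.default_rng(seed)
    zeta = np.sqrt(sample_horseshoe_scale_chain(tau, n_draws, rng))
    res = stats.kstest(zeta, stats.halfcauchy(scale=tau).cdf)
    return float(res.statistic)


def joint_log_prob(problem, beta: np.ndarray, omega: float, hyper: HorseshoeHyper) -> float:
    """Log joint probability of counts and parameters for one gene's regression.

    Sums the NB2 likelihood of every transition row (with the size-factor
    offset folded into the mean), the normal prior on each slope given its
    local variance, the inverse-gamma chain on the scales, the normal prior on
    the intercept, and the gamma prior on the dispersion.  The top-level
    ``p(sigma2) ∝ 1/sigma2`` is improper; its unnormalized log density is used.
    """
    beta = np.asarray(beta, dtype=float)
    W = problem.n_predictors
    if beta.shape != (W + 1,):
        raise ValueError(f"beta must have length {W + 1} (slopes + intercept)")
    if hyper.n_predictors != W:
        raise ValueError("hyper-parameter dimension does not match problem")
    if not omega > 0:
        raise ValueError("omega must be positive")

    eta = problem.X @ beta + problem.offset
    mu = np.exp(eta)
    lp = 0.0
    for yi, mi in zip(problem.y, mu):
        lp += nb2_log_pmf(int(yi), NBParams(mean=float(mi), dispersion=omega))

    slopes = beta[:-1]
    lp += float(np.sum(stats.norm.logpdf(slopes, scale=np.sqrt(hyper.zeta2))))
    lp += float(stats.norm.logpdf(beta[-1], scale=np.sqrt(hyper.intercept_var)))
    lp += float(np.sum(stats.invgamma.logpdf(hyper.zeta2, 0.5, scale=1.0 / hyper.a)))
    lp += float(np.sum(stats.invgamma.logpdf(hyper.a, 0.5, scale=1.0 / hyper.tau2)))
    lp += float(stats.invgamma.logpdf(hyper.tau2, 0.5, scale=1.0 / hyper.b))
    lp += float(stats.invgamma.logpdf(hyper.b, 0.5, scale=1.0 / hyper.sigma2))
    lp += -np.log(hyper.sigma2)  # improper p(sigma2) ∝ 1/sigma2
    lp += float(stats.gamma.logpdf(omega, hyper.omega_shape, scale=1.0 / hyper.omega_rate))
    return float(lp)
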