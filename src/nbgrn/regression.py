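"""Model/Results interface over the variational NB-horseshoe regression.

``NBHorseshoeModel`` holds one gene's regression problem; ``fit()`` runs the
variational optimizer and returns an ``NBHorseshoeResults`` carrying the
Gaussian posterior over coefficients, credible intervals, edge scores and the
ELBO trace, with a ``summary()`` in the spirit of statsmodels results.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .inference import FitConfig, RegressionProblem, fit as _fit

__all__ = ["NBHorseshoeModel", "NBHorseshoeResults", "edge_score"]


def edge_score(post_mean, post_sd):
    """Posterior sign-consistency score in [0, 1).

    ``1 - 2 Phi(-|mu|/sd)``: the posterior probability that the coefficient
    shares the sign of its posterior mean, minus the opposite-tail mass.
    Exceeds 0.95 exactly when zero lies outside the central 95% credible
    interval, so the probability cutoff and the interval criterion coincide.
    """
    post_sd = np.asarray(post_sd, dtype=float)
    if np.any(post_sd <= 0):
        raise ValueError("posterior sd must be strictly positive")
    z = np.abs(np.asarray(post_mean, dtype=float)) / post_sd
    out = 1.0 - 2.0 * stats.norm.sf(z)
    return float(out) if out.ndim == 0 else out


class NBHorseshoeModel:
    """Sparse NB2 regression of counts on lagged predictors, horseshoe prior.

    Parameters
    ----------
    endog : array of non-negative integer counts
    exog : array, n x W
        Predictor columns (no intercept; one is appended internally).
    offset : array, optional
        Log size factors added to the linear predictor.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, offset=None, exog_names=None):
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != np.asarray(endog).shape[0]:
            exog = exog.T
        X = np.column_stack([exog, np.ones(exog.shape[0])])
        self.problem = RegressionProblem(
            np.asarray(endog), X, offset=offset, predictor_names=exog_names
        )
        self.endog = self.problem.y
        self.exog = exog

    @classmethod
    def from_problem(cls, problem: RegressionProblem) -> "NBHorseshoeModel":
        obj = cls.__new__(cls)
        obj.problem = problem
        obj.endog = problem.y
        obj.exog = problem.X[:, :-1]
        return obj

    @property
    def exog_names(self):
        return self.problem.predictor_names + ["const"]

    def fit(self, config: FitConfig | None = None, **kwargs) -> "NBHorseshoeResults":
        """Run variational inference; keyword arguments override config fields."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace

            config = replace(config, **kwargs)
        state = _fit(self.problem, config)
        return NBHorseshoeResults(self, state, config)


class NBHorseshoeResults:
    """Posterior summaries of a fitted NB-horseshoe regression."""

    def __init__(self, model: NBHorseshoeModel, state, config: FitConfig):
        self.model = model
        self.state = state
        self.config = config

    @property
    def params(self) -> np.ndarray:
        """Posterior mean of the coefficients (slopes then intercept)."""
        return self.state.mu

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviation of the coefficients."""
        return np.sqrt(np.diag(self.state.Sigma))

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def elbo(self) -> float:
        return self.state.elbo_trace[-1]

    @property
    def elbo_trace(self) -> np.ndarray:
        return np.asarray(self.state.elbo_trace)

    @property
    def dispersion(self) -> float:
        """Posterior mean of the NB2 dispersion omega."""
        return self.state.e_omega

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Central (1 - alpha) credible intervals, rows (lower, upper)."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def edge_scores(self) -> np.ndarray:
        """Sign-consistency score per slope (intercept excluded)."""
        return edge_score(self.params[:-1], self.bse[:-1])

    def selected(self, cutoff: float = 0.95) -> np.ndarray:
        """Boolean mask of slopes whose score exceeds ``cutoff``."""
        return self.edge_scores() > cutoff

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        lines = [
            "NB-horseshoe regression (variational)",
            f"  n obs: {self.model.problem.n_obs}   predictors: "
            f"{self.model.problem.n_predictors}",
            f"  ELBO: {self.elbo:.4f}   sweeps: {self.state.n_iter}   "
            f"converged: {self.converged}",
            f"  E[omega]: {self.dispersion:.4f}",
            "",
            f"{'term':>12} {'mean':>10} {'sd':>10} "
            f"{f'[{alpha / 2:.3f}':>10} {f'{1 - alpha / 2:.3f}]':>10} {'score':>8}",
        ]
        scores = np.append(self.edge_scores(), np.nan)
        for name, m, s, (lo, hi), sc in zip(
            self.model.exog_names, self.params, self.bse, ci, scores
        ):
            sc_str = f"{sc:8.4f}" if np.isfinite(sc) else "       -"
            lines.append(f"{name:>12} {m:10.4f} {s:10.4f} {lo:10.4f} {hi:10.4f} {sc_str}")
        return "\n".join(lines)
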