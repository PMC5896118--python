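import numpy as np
import pytest

from nbgrn.inference import FitConfig, RegressionProblem, fit
from nbgrn.network import DirectedNetwork, DynamicNetworkModel
from nbgrn.simulate import simulate_benchmark


def make_problem(seed=1, n=57, w=5, beta=None, omega=2.0, offset=None):
    """Simulate one NB regression problem with Gaussian predictors."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=(n, w)), np.ones(n)])
    if beta is None:
        beta = np.zeros(w + 1)
        beta[0], beta[-1] = 0.8, 2.0
    off = np.zeros(n) if offset is None else np.asarray(offset)
    mu = np.exp(X @ beta + off)
    y = rng.negative_binomial(omega, omega / (omega + mu))
    return RegressionProblem(y, X, offset=off)


@pytest.fixture(scope="session")
def fitted_small():
    """A converged fit on a 5-predictor problem with one active coefficient."""
    problem = make_problem(seed=1)
    return problem, fit(problem, FitConfig())


@pytest.fixture(scope="session")
def strong_network_fit():
    """10-gene network simulated with strong coefficients, fitted end to end."""
    spec, data = simulate_benchmark(n_nodes=10, seed=3, mixture_loc=0.8)
    results = DynamicNetworkModel(data).fit()
    truth = DirectedNetwork.from_edge_list(spec.nodes, spec.true_edges())
    return spec, data, results, truth
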