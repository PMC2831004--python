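"""Likelihood, priors and closed-form probabilities for the p2 model.

The undirected model places an independent Bernoulli variable on each
unordered pair {i, j}:

    logit P(X_ij = 1) = theta + alpha_i + alpha_j,
    alpha_i = gamma . x_i + a_i.

Priors are hierarchical normal-gamma: theta ~ N(0, 1/tau_theta), each
gamma_k ~ N(0, 1/tau_gamma), a_i ~ N(0, 1/tau_a), with conjugate
Gamma(a0, b0) hyperpriors (a0 = b0 = 0.001, i.e. effectively
noninformative) on all three precisions.

The directed p1 dyad probabilities (mutual / asymmetric / null cells with
a reciprocity parameter) are provided as closed-form utilities; the
sampler and the rest of the pipeline operate on undirected graphs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from p2net.network_io import CovariateTable, Network, empty_covariates

__all__ = [
    "ModelParameters",
    "Hyperparameters",
    "DirectedDyadProbs",
    "sociality",
    "edge_probability",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "dyad_probabilities_directed",
]


@dataclass
class Hyperparameters:
    """Gamma(shape a0, rate b0) hyperprior shared by all precisions."""

    a0: float = 0.001
    b0: float = 0.001

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("Gamma hyperparameters must be strictly positive")


@dataclass
class ModelParameters:
    """Current state of the p2 model.

    theta      global density (log-odds of an edge between two zero-sociality nodes)
    gamma      covariate effects, length m (possibly empty)
    a          node random effects, length n
    tau_theta, tau_gamma, tau_a   precisions (inverse variances) of the normals
    """

    theta: float
    gamma: np.ndarray
    a: np.ndarray
    tau_theta: float = 1.0
    tau_gamma: float = 1.0
    tau_a: float = 1.0

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=np.float64))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=np.float64))
        for name in ("tau_theta", "tau_gamma", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def sociality(params: ModelParameters, covariates: CovariateTable | np.ndarray, net: Network | None = None) -> np.ndarray:
    """Sociality vector alpha_i = gamma . x_i + a_i.

    ``covariates`` may be a CovariateTable (requires ``net`` for alignment)
    or an (n x m) matrix already in node order.  With m = 0 covariates the
    socialities are the random effects themselves.
    """
    a = params.a
    m = params.gamma.shape[0]
    if isinstance(covariates, CovariateTable):
        if net is None:
            raise ValueError("a Network is required to align a CovariateTable")
        X = covariates.align(net)
    else:
        X = np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(len(a), 0)
    if X.shape[0] != len(a):
        raise ValueError(f"covariate rows ({X.shape[0]}) != number of random effects ({len(a)})")
    if X.shape[1] != m:
        raise ValueError(f"covariate columns ({X.shape[1]}) != gamma length ({m})")
    return X @ params.gamma + a


def edge_probability(theta: float, alpha_i: float, alpha_j: float) -> float:
    """P(edge between i and j) = expit(theta + alpha_i + alpha_j).

    Symmetric in (alpha_i, alpha_j); saturates smoothly at extreme inputs.
    """
    # sum the socialities first so the value is exactly symmetric in (i, j)
    return float(expit(theta + (alpha_i + alpha_j)))


def _logistic_loglik(eta: np.ndarray, x: np.ndarray) -> float:
    # sum_k [ x_k * eta_k - log(1 + exp(eta_k)) ], computed stably
    return float(np.sum(x * eta - np.logaddexp(0.0, eta)))


def log_likelihood(
    net: Network,
    params: ModelParameters,
    covariates: CovariateTable | np.ndarray | None = None,
) -> float:
    """Bernoulli log-likelihood over all unordered node pairs.

    sum_{i<j} [ x_ij log p_ij + (1 - x_ij) log(1 - p_ij) ] with
    p_ij = expit(theta + alpha_i + alpha_j).
    """
    if net.directed:
        raise ValueError(
            "log_likelihood is defined for undirected networks; "
            "use dyad_probabilities_directed for directed dyads"
        )
    n = net.n_nodes
    if len(params.a) != n:
        raise ValueError(f"random-effects length ({len(params.a)}) != number of nodes ({n})")
    if covariates is None:
        covariates = empty_covariates(net)
    alpha = sociality(params, covariates, net)
    adj = net.adjacency()
    iu, ju = np.triu_indices(n, k=1)
    eta = params.theta + alpha[iu] + alpha[ju]
    return _logistic_loglik(eta, adj[iu, ju])


def _normal_logpdf(x: np.ndarray | float, tau: float) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(np.sum(0.5 * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * x**2))


def _gamma_logpdf(x: float, a0: float, b0: float) -> float:
    if x <= 0:
        return -np.inf
    return a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * np.log(x) - b0 * x


def log_prior(params: ModelParameters, hyper: Hyperparameters | None = None) -> float:
    """Log density of the hierarchical prior at the given state.

    Normal(0, tau^-1) terms for theta, each gamma_k and each a_i, plus
    Gamma(a0, b0) terms for the three precisions.
    """
    hyper = hyper or Hyperparameters()
    lp = _normal_logpdf(params.theta, params.tau_theta)
    lp += _gamma_logpdf(params.tau_theta, hyper.a0, hyper.b0)
    if params.gamma.size:
        lp += _normal_logpdf(params.gamma, params.tau_gamma)
    lp += _gamma_logpdf(params.tau_gamma, hyper.a0, hyper.b0)
    if params.a.size:
        lp += _normal_logpdf(params.a, params.tau_a)
    lp += _gamma_logpdf(params.tau_a, hyper.a0, hyper.b0)
    return lp


def log_posterior(
    net: Network,
    params: ModelParameters,
    covariates: CovariateTable | np.ndarray | None = None,
    hyper: Hyperparameters | None = None,
) -> float:
    """Unnormalized log posterior: log_likelihood + log_prior."""
    return log_likelihood(net, params, covariates) + log_prior(params, hyper)


@dataclass(frozen=True)
class DirectedDyadProbs:
    """Probabilities of the four outcomes of a directed dyad (i, j).

    m      mutual (both edges present)
    a_ij   only i -> j
    a_ji   only j -> i
    n      null (no edge)
    """

    m: float
    a_ij: float
    a_ji: float
    n: float

    def __post_init__(self) -> None:
        total = self.m + self.a_ij + self.a_ji + self.n
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"dyad probabilities must sum to 1, got {total}")


def dyad_probabilities_directed(
    theta: float,
    phi: float,
    alpha_i: float,
    beta_i: float,
    alpha_j: float,
    beta_j: float,
) -> DirectedDyadProbs:
    """Closed-form p1 dyad distribution for a directed pair (i, j).

    Unnormalized log masses: 0 for null, theta + alpha_i + beta_j for
    i -> j only, theta + alpha_j + beta_i for j -> i only, and
    2 theta + alpha_i + alpha_j + beta_i + beta_j + phi for mutual, where
    phi is the reciprocity parameter, alpha the expansiveness and beta the
    attractiveness.  The normalizer (the lambda_ij "residual") enforces
    that the four cells sum to one.
    """
    logm = np.array(
        [
            2.0 * theta + alpha_i + alpha_j + beta_i + beta_j + phi,  # mutual
            theta + alpha_i + beta_j,  # i -> j
            theta + alpha_j + beta_i,  # j -> i
            0.0,  # null
        ]
    )
    logm -= logm.max()
    p = np.exp(logm)
    p /= p.sum()
    return DirectedDyadProbs(m=float(p[0]), a_ij=float(p[1]), a_ji=float(p[2]), n=float(p[3]))
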