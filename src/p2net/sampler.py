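"""Metropolis-within-Gibbs MCMC for the p2 model posterior.

One sweep updates, in order: the density parameter theta (random-walk
Metropolis), each covariate effect gamma_k (random-walk Metropolis), each
random effect a_i sequentially (random-walk Metropolis on its full
conditional, which touches only node i's incident pairs), and finally the
three precisions by exact conjugate Gibbs draws from their gamma full
conditionals.

Proposal scales are adapted during burn-in toward a 0.44 acceptance rate
for scalar blocks (the classic optimum for one-dimensional random walks)
and frozen afterwards, so the post-burn-in kernel leaves the posterior
invariant.  All randomness flows through ``numpy.random.Generator`` seeded
from the configured seed; identical (data, config, seed) gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import logit

from p2net.model import Hyperparameters
from p2net.network_io import CovariateTable, Network, empty_covariates

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "update_precision",
    "metropolis_block",
    "run_chain",
    "run_chains",
]

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    The ``paper`` profile (50000 burn-in / 100000 draws) mirrors a full
    analysis run; the ``desk`` profile (2000 / 8000) is sized for
    interactive use and simulation studies.
    """

    burn_in: int = 50_000
    draws: int = 100_000
    thin: int = 10
    chains: int = 2
    seed: int = 0
    scale_theta: float = 0.3
    scale_gamma: float = 0.3
    scale_a: float = 1.0
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        for name in ("scale_theta", "scale_gamma", "scale_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def paper_profile(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(burn_in=50_000, draws=100_000, seed=seed, **kw)

    @classmethod
    def desk_profile(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(burn_in=2_000, draws=8_000, seed=seed, **kw)

    def chain_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.chains)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from one or more chains.

    Arrays are indexed (chain, draw) for scalars and (chain, draw, dim)
    for vectors.  ``node_ids`` fixes the column order of ``a``;
    ``covariate_names`` that of ``gamma``.
    """

    theta: np.ndarray
    gamma: np.ndarray
    a: np.ndarray
    tau_theta: np.ndarray
    tau_gamma: np.ndarray
    tau_a: np.ndarray
    node_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    acceptance: list[dict[str, float]]
    seeds: list[int]
    config: SamplerConfig

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated along axis 0."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def alpha_draws(self, X: np.ndarray | None = None) -> np.ndarray:
        """Per-draw sociality matrix alpha = X gamma + a, pooled over chains.

        ``X`` is the (n x m) covariate matrix in node order; omit it (or
        pass an m = 0 matrix) for a covariate-free fit.
        """
        a = self.pooled("a")
        if self.gamma.shape[-1] == 0 or X is None:
            return a
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return a + self.pooled("gamma") @ X.T

    def save(self, prefix: str | Path) -> None:
        """Checkpoint as <prefix>.npz (draws) + <prefix>.json (metadata)."""
        prefix = Path(prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            theta=self.theta,
            gamma=self.gamma,
            a=self.a,
            tau_theta=self.tau_theta,
            tau_gamma=self.tau_gamma,
            tau_a=self.tau_a,
        )
        meta = {
            "node_ids": list(self.node_ids),
            "covariate_names": list(self.covariate_names),
            "acceptance": self.acceptance,
            "seeds": self.seeds,
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "burn_in", "draws", "thin", "chains", "seed",
                    "scale_theta", "scale_gamma", "scale_a", "adapt",
                )
            },
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorSamples":
        prefix = Path(prefix)
        arrs = np.load(prefix.with_suffix(".npz"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            theta=arrs["theta"],
            gamma=arrs["gamma"],
            a=arrs["a"],
            tau_theta=arrs["tau_theta"],
            tau_gamma=arrs["tau_gamma"],
            tau_a=arrs["tau_a"],
            node_ids=tuple(meta["node_ids"]),
            covariate_names=tuple(meta["covariate_names"]),
            acceptance=meta["acceptance"],
            seeds=meta["seeds"],
            config=SamplerConfig(**meta["config"]),
        )


def update_precision(
    values: np.ndarray, hyper: Hyperparameters, rng: np.random.Generator
) -> float:
    """One conjugate Gibbs draw of a normal precision.

    For k values with a N(0, tau^-1) likelihood and tau ~ Gamma(a0, b0),
    the full conditional is Gamma(a0 + k/2, b0 + sum(values^2)/2).
    An empty vector returns a draw from the prior.
    """
    values = np.atleast_1d(np.asarray(values, dtype=np.float64))
    shape = hyper.a0 + 0.5 * values.size
    rate = hyper.b0 + 0.5 * float(np.sum(values**2))
    return float(rng.gamma(shape, 1.0 / rate))


def metropolis_block(
    current: float | np.ndarray,
    log_target: Callable[[float | np.ndarray], float],
    scale: float,
    rng: np.random.Generator,
) -> tuple[float | np.ndarray, bool]:
    """One symmetric random-walk Metropolis step.

    Proposes current + scale * N(0, I) and accepts with probability
    min(1, exp(log_target(proposal) - log_target(current))).
    """
    lp_cur = log_target(current)
    if not np.isfinite(lp_cur):
        raise ValueError("log_target is not finite at the current state")
    if np.isscalar(current) or np.ndim(current) == 0:
        prop = float(current) + scale * float(rng.standard_normal())
    else:
        cur = np.asarray(current, dtype=np.float64)
        prop = cur + scale * rng.standard_normal(cur.shape)
    lp_prop = log_target(prop)
    if np.log(rng.random()) < lp_prop - lp_cur:
        return prop, True
    return current, False


def _adapt_scale(log_scale: float, accepted: int, window: int) -> float:
    rate = accepted / window
    return float(np.clip(log_scale + (rate - _TARGET_ACCEPT), np.log(1e-3), np.log(50.0)))


def run_chain(
    net: Network,
    covariates: CovariateTable | np.ndarray | None,
    hyper: Hyperparameters,
    config: SamplerConfig,
    chain_seed: int | np.random.SeedSequence,
    init: dict | None = None,
) -> dict:
    """Run a single chain; returns a dict of thinned post-burn-in draws.

    ``init`` may override the default initial values (keys ``theta``,
    ``gamma``, ``a``).  Defaults: theta at the logit of the observed
    density (clipped away from the boundary), gamma = 0, a = 0, all
    precisions 1.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if net.directed:
        raise ValueError("the sampler handles undirected networks only")

    if covariates is None:
        covariates = empty_covariates(net)
    X = covariates.align(net) if isinstance(covariates, CovariateTable) else np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(n, 0)
    m = X.shape[1]

    rng = np.random.default_rng(chain_seed)
    adj = net.adjacency()
    iu, ju = np.triu_indices(n, k=1)
    x_pairs = adj[iu, ju]
    n_edges = float(x_pairs.sum())
    deg = adj.sum(axis=1)
    # per-covariate pair sums: s_k[p] = x_i,k + x_j,k for pair p
    s_pairs = [X[iu, k] + X[ju, k] for k in range(m)]
    sx = [float(np.sum(x_pairs * s_pairs[k])) for k in range(m)]

    init = init or {}
    dens = np.clip(net.density, 1.0 / (net.n_pairs + 1.0), 1.0 - 1.0 / (net.n_pairs + 1.0))
    theta = float(init.get("theta", logit(dens)))
    gamma = np.asarray(init.get("gamma", np.zeros(m)), dtype=np.float64).copy()
    a = np.asarray(init.get("a", np.zeros(n)), dtype=np.float64).copy()
    tau_theta = tau_gamma = tau_a = 1.0
    alpha = X @ gamma + a

    ls_theta = np.log(config.scale_theta)
    ls_gamma = np.full(m, np.log(config.scale_gamma))
    ls_a = np.full(n, np.log(config.scale_a))

    n_keep = config.draws // config.thin
    out = {
        "theta": np.empty(n_keep),
        "gamma": np.empty((n_keep, m)),
        "a": np.empty((n_keep, n)),
        "tau_theta": np.empty(n_keep),
        "tau_gamma": np.empty(n_keep),
        "tau_a": np.empty(n_keep),
    }

    acc_theta = acc_win_theta = 0
    acc_gamma = np.zeros(m, dtype=int)
    acc_win_gamma = np.zeros(m, dtype=int)
    acc_a = np.zeros(n, dtype=int)
    acc_win_a = np.zeros(n, dtype=int)

    total = config.burn_in + config.draws
    keep_idx = 0
    for sweep in range(total):
        in_burn = sweep < config.burn_in

        # --- theta: a shift moves every pair's linear predictor equally
        eta = theta + alpha[iu] + alpha[ju]
        delta = np.exp(ls_theta) * rng.standard_normal()
        dll = delta * n_edges - float(
            np.sum(np.logaddexp(0.0, eta + delta) - np.logaddexp(0.0, eta))
        )
        dlp = -0.5 * tau_theta * ((theta + delta) ** 2 - theta**2)
        if np.log(rng.random()) < dll + dlp:
            theta += delta
            acc_win_theta += 1
            if not in_burn:
                acc_theta += 1

        # --- gamma_k: a shift moves pair p by delta * (x_i,k + x_j,k)
        for k in range(m):
            eta = theta + alpha[iu] + alpha[ju]
            delta = np.exp(ls_gamma[k]) * rng.standard_normal()
            shift = delta * s_pairs[k]
            dll = delta * sx[k] - float(
                np.sum(np.logaddexp(0.0, eta + shift) - np.logaddexp(0.0, eta))
            )
            dlp = -0.5 * tau_gamma * ((gamma[k] + delta) ** 2 - gamma[k] ** 2)
            if np.log(rng.random()) < dll + dlp:
                gamma[k] += delta
                alpha += delta * X[:, k]
                acc_win_gamma[k] += 1
                if not in_burn:
                    acc_gamma[k] += 1

        # --- a_i sequentially; only node i's incident pairs change
        deltas = np.exp(ls_a) * rng.standard_normal(n)
        logu = np.log(rng.random(n))
        for i in range(n):
            delta = deltas[i]
            eta_i = theta + alpha[i] + alpha  # includes the phantom j = i term
            sp_all = np.logaddexp(0.0, eta_i + delta) - np.logaddexp(0.0, eta_i)
            dll = delta * deg[i] - (float(sp_all.sum()) - float(sp_all[i]))
            dlp = -0.5 * tau_a * ((a[i] + delta) ** 2 - a[i] ** 2)
            if logu[i] < dll + dlp:
                a[i] += delta
                alpha[i] += delta
                acc_win_a[i] += 1
                if not in_burn:
                    acc_a[i] += 1

        # --- conjugate precision draws
        tau_theta = update_precision(np.array([theta]), hyper, rng)
        tau_gamma = update_precision(gamma, hyper, rng)
        tau_a = update_precision(a, hyper, rng)

        if config.adapt and in_burn and (sweep + 1) % _ADAPT_WINDOW == 0:
            ls_theta = _adapt_scale(ls_theta, acc_win_theta, _ADAPT_WINDOW)
            for k in range(m):
                ls_gamma[k] = _adapt_scale(ls_gamma[k], acc_win_gamma[k], _ADAPT_WINDOW)
            for i in range(n):
                ls_a[i] = _adapt_scale(ls_a[i], acc_win_a[i], _ADAPT_WINDOW)
            acc_win_theta = 0
            acc_win_gamma[:] = 0
            acc_win_a[:] = 0

        if not in_burn:
            t = sweep - config.burn_in
            if (t + 1) % config.thin == 0:
                out["theta"][keep_idx] = theta
                out["gamma"][keep_idx] = gamma
                out["a"][keep_idx] = a
                out["tau_theta"][keep_idx] = tau_theta
                out["tau_gamma"][keep_idx] = tau_gamma
                out["tau_a"][keep_idx] = tau_a
                keep_idx += 1

    out["acceptance"] = {
        "theta": acc_theta / config.draws,
        "gamma": float(acc_gamma.mean() / config.draws) if m else float("nan"),
        "a": float(acc_a.mean() / config.draws),
    }
    return out


def run_chains(
    net: Network,
    covariates: CovariateTable | np.ndarray | None,
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Run ``config.chains`` independent chains from overdispersed starts.

    Chain c starts at theta alternating between -4 and 0, with random
    effects drawn N(0, 1) from the chain's own stream — deliberately
    spread out so Gelman-Rubin comparisons across chains are meaningful.
    """
    hyper = hyper or Hyperparameters()
    config = config or SamplerConfig()
    if covariates is None:
        covariates = empty_covariates(net)
    X = covariates.align(net) if isinstance(covariates, CovariateTable) else np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(net.n_nodes, 0)
    m = X.shape[1]
    cov_names = (
        tuple(covariates.columns) if isinstance(covariates, CovariateTable) else tuple(f"x{k}" for k in range(m))
    )

    theta_starts = [-4.0, 0.0]
    chains: list[dict] = []
    seeds_out: list[int] = []
    for c, ss in enumerate(config.chain_seeds()):
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        init = {
            "theta": theta_starts[c % len(theta_starts)],
            "a": init_rng.standard_normal(net.n_nodes),
            "gamma": np.zeros(m),
        }
        chains.append(run_chain(net, X, hyper, config, ss, init=init))
        seeds_out.append(int(ss.entropy) if isinstance(ss.entropy, int) else config.seed)

    return PosteriorSamples(
        theta=np.stack([ch["theta"] for ch in chains]),
        gamma=np.stack([ch["gamma"] for ch in chains]),
        a=np.stack([ch["a"] for ch in chains]),
        tau_theta=np.stack([ch["tau_theta"] for ch in chains]),
        tau_gamma=np.stack([ch["tau_gamma"] for ch in chains]),
        tau_a=np.stack([ch["tau_a"] for ch in chains]),
        node_ids=tuple(net.nodes),
        covariate_names=cov_names,
        acceptance=[ch["acceptance"] for ch in chains],
        seeds=seeds_out,
        config=config,
    )
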