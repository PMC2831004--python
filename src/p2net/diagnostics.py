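"""Convergence diagnostics for MCMC output.

Two classical diagnostics are provided: Geweke's two-window z-score
(compares the mean of an early window of a single chain against a late
window, with variances estimated from the spectral density at frequency
zero so autocorrelation is accounted for) and the Gelman-Rubin potential
scale reduction factor (compares between-chain and within-chain variance
across parallel chains started from overdispersed points).

Rules of thumb used for flagging: |z| > 1.96 suggests the chain mean is
still drifting; PSRF > 1.1 suggests the chains have not mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from p2net.sampler import PosteriorSamples

__all__ = ["geweke_z", "gelman_rubin", "DiagnosticReport", "diagnose"]


def spectral_variance_at_zero(x: np.ndarray) -> float:
    """Estimate S(0)/n, the large-sample variance of the sample mean.

    Bartlett lag-window estimator with truncation at floor(sqrt(n)) lags:
    S(0) = gamma_0 + 2 sum_{k=1..L} (1 - k/(L+1)) gamma_k.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    xc = x - x.mean()
    var0 = float(xc @ xc) / n
    if var0 == 0.0:
        raise ValueError("degenerate chain: zero variance window")
    L = int(np.sqrt(n))
    s = var0
    for k in range(1, L + 1):
        gamma_k = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gamma_k
    # a heavily negatively-correlated window can push the estimate below 0
    s = max(s, 1e-12 * var0)
    return s / n


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for a single chain.

    z = (mean of first ``first`` fraction - mean of last ``last`` fraction)
    normalized by spectral-density-at-zero variance estimates of the two
    windows.  Under convergence z is asymptotically standard normal.
    """
    chain = np.asarray(chain, dtype=np.float64)
    if chain.size < 100:
        raise ValueError("chain too short for Geweke diagnostic (need >= 100 draws)")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("window fractions must be in (0,1) with first + last <= 1")
    n = chain.size
    w1 = chain[: int(np.floor(first * n))]
    w2 = chain[n - int(np.floor(last * n)) :]
    v1 = spectral_variance_at_zero(w1)
    v2 = spectral_variance_at_zero(w2)
    return float((w1.mean() - w2.mean()) / np.sqrt(v1 + v2))


def gelman_rubin(chains: list[np.ndarray] | np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor (PSRF).

    With m chains of length n, W is the mean within-chain variance and
    B/n the variance of the chain means; the pooled posterior-variance
    estimate is (n-1)/n W + B/n and PSRF = sqrt(pooled / W).  Values near
    1 indicate that the chains are sampling the same distribution.
    """
    arr = np.asarray(chains, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a list of equal-length 1-D chains")
    m, n = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    if n < 10:
        raise ValueError("chains too short for Gelman-Rubin (need >= 10 draws)")
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    if W == 0.0:
        raise ValueError("degenerate chains: zero within-chain variance")
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


@dataclass
class DiagnosticReport:
    """Per-parameter Geweke z (each chain) and PSRF, with threshold flags."""

    table: pd.DataFrame

    @property
    def converged(self) -> bool:
        return not bool(self.table["geweke_flag"].any() or self.table["psrf_flag"].any())

    def max_psrf(self) -> float:
        return float(self.table["psrf"].max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def diagnose(
    samples: PosteriorSamples,
    include_a: bool = False,
    z_threshold: float = 1.96,
    psrf_threshold: float = 1.1,
) -> DiagnosticReport:
    """Diagnostics for theta, the gammas, the precisions and optionally each a_i.

    PSRF requires >= 2 chains and is reported as NaN (unflagged) for a
    single chain; Geweke is computed per chain and the worst |z| reported.
    """
    rows = []
    params: list[tuple[str, np.ndarray]] = [("theta", samples.theta)]
    for k, name in enumerate(samples.covariate_names):
        params.append((f"gamma[{name}]", samples.gamma[:, :, k]))
    params += [
        ("tau_theta", samples.tau_theta),
        ("tau_a", samples.tau_a),
    ]
    if samples.covariate_names:
        params.append(("tau_gamma", samples.tau_gamma))
    if include_a:
        for i, node in enumerate(samples.node_ids):
            params.append((f"a[{node}]", samples.a[:, :, i]))

    multi = samples.n_chains >= 2
    for name, arr in params:
        zs = [geweke_z(arr[c]) for c in range(arr.shape[0])]
        psrf = gelman_rubin(arr) if multi else float("nan")
        for c, z in enumerate(zs):
            rows.append(
                {
                    "parameter": name,
                    "chain": c,
                    "geweke_z": z,
                    "psrf": psrf,
                    "geweke_flag": abs(z) > z_threshold,
                    "psrf_flag": bool(psrf > psrf_threshold) if multi else False,
                }
            )
    return DiagnosticReport(table=pd.DataFrame(rows))
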