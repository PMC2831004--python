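"""Posterior summaries, social-node calling and covariate-effect reports.

A node is called *social* when the 2.5% posterior quantile of its
sociality alpha_i is strictly greater than zero — a stricter requirement
than merely having a positive posterior mean, and the model-based
counterpart of the descriptive notion of a hub.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from p2net.network_io import CovariateTable, Network, degree_sequence, empty_covariates
from p2net.sampler import PosteriorSamples

__all__ = ["FitSummary", "summarize", "call_social", "covariate_effect"]

_QUANTS = (0.025, 0.975)


@dataclass
class FitSummary:
    """Posterior summary of a fit.

    ``nodes``: one row per node, sorted by posterior mean sociality
    (descending): id, degree, alpha_mean, alpha_sd, q2.5, q97.5, the
    covariate columns, positive_mean and social flags.

    ``globals``: one row per global parameter (theta and each gamma) with
    mean, sd and the 2.5%/97.5% quantiles.
    """

    nodes: pd.DataFrame
    globals: pd.DataFrame

    def to_csv(self, nodes_path, globals_path=None) -> None:
        self.nodes.to_csv(nodes_path, index=False)
        if globals_path is not None:
            self.globals.to_csv(globals_path, index=False)


def _summary_row(draws: np.ndarray) -> tuple[float, float, float, float]:
    lo, hi = np.quantile(draws, _QUANTS)
    return float(draws.mean()), float(draws.std(ddof=1)), float(lo), float(hi)


def summarize(
    samples: PosteriorSamples,
    net: Network,
    covariates: CovariateTable | None = None,
) -> FitSummary:
    """Pool chains and summarize alpha per node plus the global parameters.

    Socialities are reconstructed per draw as alpha_i = gamma . x_i + a_i
    before summarizing, so quantiles are of alpha itself, not of the
    random effect alone.
    """
    if samples.n_draws == 0:
        raise ValueError("no draws to summarize")
    covariates = covariates if covariates is not None else empty_covariates(net)
    X = covariates.align(net, list(samples.covariate_names))
    alpha = samples.alpha_draws(X)  # (total draws, n)
    deg = degree_sequence(net)

    rows = []
    for i, node in enumerate(samples.node_ids):
        mean, sd, lo, hi = _summary_row(alpha[:, i])
        row = {
            "id": node,
            "degree": deg[node],
            "alpha_mean": mean,
            "alpha_sd": sd,
            "q2.5": lo,
            "q97.5": hi,
        }
        for k, cname in enumerate(samples.covariate_names):
            row[cname] = X[i, k]
        row["positive_mean"] = mean > 0
        row["social"] = lo > 0
        rows.append(row)
    nodes = pd.DataFrame(rows).sort_values(
        ["alpha_mean", "id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )

    grows = []
    mean, sd, lo, hi = _summary_row(samples.pooled("theta"))
    grows.append({"parameter": "theta", "mean": mean, "sd": sd, "q2.5": lo, "q97.5": hi})
    for k, cname in enumerate(samples.covariate_names):
        mean, sd, lo, hi = _summary_row(samples.pooled("gamma")[:, k])
        grows.append(
            {"parameter": f"gamma[{cname}]", "mean": mean, "sd": sd, "q2.5": lo, "q97.5": hi}
        )
    return FitSummary(nodes=nodes, globals=pd.DataFrame(grows))


def call_social(summary: FitSummary) -> tuple[list[str], int]:
    """Social nodes (q2.5 of alpha strictly > 0) and the positive-mean count.

    Returns the social node IDs sorted by posterior mean sociality
    (descending) together with the number of nodes whose posterior mean
    alpha is positive.
    """
    df = summary.nodes
    social = df.loc[df["q2.5"] > 0].sort_values(
        ["alpha_mean", "id"], ascending=[False, True], kind="mergesort"
    )
    n_positive = int((df["alpha_mean"] > 0).sum())
    return social["id"].tolist(), n_positive


def covariate_effect(summary: FitSummary, which: str) -> dict:
    """Posterior summary and plain-language verdict for one covariate effect.

    The verdict reads e.g. "positive effect, credible" when the entire 95%
    credible interval of gamma lies above zero, and "positive effect, not
    credible" when the mean is positive but the interval straddles zero.
    """
    name = f"gamma[{which}]"
    match = summary.globals.loc[summary.globals["parameter"] == name]
    if match.empty:
        known = [p[6:-1] for p in summary.globals["parameter"] if p.startswith("gamma[")]
        raise KeyError(f"unknown covariate {which!r}; available: {known}")
    row = match.iloc[0]
    mean, lo, hi = row["mean"], row["q2.5"], row["q97.5"]
    if mean == 0 and row["sd"] == 0:
        verdict = "no effect"
    elif lo > 0:
        verdict = "positive effect, credible"
    elif hi < 0:
        verdict = "negative effect, credible"
    elif mean > 0:
        verdict = "positive effect, not credible"
    elif mean < 0:
        verdict = "negative effect, not credible"
    else:
        verdict = "no effect"
    return {
        "covariate": which,
        "mean": float(mean),
        "sd": float(row["sd"]),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "verdict": verdict,
    }
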