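"""Cluster nodes by sociality and summarize inter-cluster interaction flows.

Nodes are clustered by agglomerative complete linkage on the Euclidean
distances between their posterior mean socialities; cutting the
dendrogram at k groups (k = 5 by default) yields structurally similar
node classes, numbered 1..k by descending mean sociality so Cluster 1 is
the most social/highest-degree group.  The flow matrix expresses, for
every ordered-free cluster pair, the share of all network edges running
between (or, on the diagonal, within) the clusters — a coarse-grained
picture of the network's organization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from p2net.network_io import Network, degree_sequence
from p2net.posterior import FitSummary

__all__ = [
    "ClusterResult",
    "sociality_distance",
    "complete_linkage",
    "cut_clusters",
    "cluster_report",
]


def sociality_distance(summary: FitSummary) -> tuple[np.ndarray, list[str]]:
    """Euclidean distance matrix between posterior mean socialities.

    For scalar summaries this is D_ij = |alpha_mean_i - alpha_mean_j|.
    Returns the symmetric zero-diagonal matrix and the node IDs in the
    summary's row order.
    """
    alpha = summary.nodes["alpha_mean"].to_numpy(dtype=np.float64)
    ids = summary.nodes["id"].tolist()
    D = np.abs(alpha[:, None] - alpha[None, :])
    np.fill_diagonal(D, 0.0)
    return D, ids


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage merge sequence (SciPy linkage matrix).

    Row t holds the two cluster indices merged at step t, the merge height
    (the maximum pairwise distance across the merged clusters) and the new
    cluster's size.  Heights are non-decreasing.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("expected a square distance matrix")
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return linkage(squareform(dist, checks=False), method="complete")


def cut_clusters(merges: np.ndarray, k: int = 5, order_by: np.ndarray | None = None) -> np.ndarray:
    """Cut a merge sequence into exactly k clusters (undo the last k-1 merges).

    Labels are 1..k.  When ``order_by`` (e.g. the per-node mean sociality)
    is given, clusters are renumbered by descending mean of that vector,
    so cluster 1 has the highest mean sociality.
    """
    n = merges.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = fcluster(merges, t=k, criterion="maxclust")
    uniq = np.unique(raw)
    if len(uniq) != k:
        # ties in merge heights can make maxclust undershoot; force exact k
        heights = merges[:, 2]
        cut = heights[-(k - 1)] if k > 1 else np.inf
        raw = fcluster(merges, t=cut - 1e-12, criterion="distance")
        uniq = np.unique(raw)
    if order_by is not None:
        means = {c: float(np.mean(order_by[raw == c])) for c in uniq}
        ranking = sorted(uniq, key=lambda c: -means[c])
    else:
        ranking = sorted(uniq, key=lambda c: float(np.min(np.where(raw == c)[0])))
    relabel = {c: i + 1 for i, c in enumerate(ranking)}
    return np.array([relabel[c] for c in raw], dtype=int)


@dataclass
class ClusterResult:
    """Clustering of nodes with structural summaries.

    ``merges``: SciPy linkage matrix; ``labels``: node ID -> cluster 1..k;
    ``summary``: per-cluster size and degree range; ``flows``: k x k
    DataFrame of edge percentages (within-cluster on the diagonal),
    summing to 100 over the upper triangle including the diagonal.
    """

    merges: np.ndarray
    labels: dict[str, int]
    summary: pd.DataFrame
    flows: pd.DataFrame

    def to_csv(self, summary_path, flows_path) -> None:
        self.summary.to_csv(summary_path, index=False)
        long = self.flows.stack().reset_index()
        long.columns = ["cluster_a", "cluster_b", "percent"]
        long = long[long.cluster_a <= long.cluster_b]
        long.to_csv(flows_path, index=False)


def cluster_report(
    labels: dict[str, int] | np.ndarray,
    net: Network,
    summary: FitSummary,
    merges: np.ndarray | None = None,
) -> ClusterResult:
    """Per-cluster sizes, degree ranges and the inter-cluster flow matrix.

    ``labels`` is either a node->cluster mapping or an array aligned with
    the rows of ``summary``.  Flow percentages are relative to the total
    edge count; each edge contributes to exactly one (unordered) cluster
    pair, so all entries of the upper triangle (with diagonal) sum to 100.
    """
    if not isinstance(labels, dict):
        ids = summary.nodes["id"].tolist()
        labels = {v: int(c) for v, c in zip(ids, np.asarray(labels))}
    missing = [v for v in net.nodes if v not in labels]
    if missing:
        raise ValueError(f"labels missing for node(s): {missing[:10]}")

    ks = sorted(set(labels.values()))
    deg = degree_sequence(net)
    rows = []
    for c in ks:
        members = [v for v in net.nodes if labels[v] == c]
        degs = [deg[v] for v in members]
        rows.append(
            {
                "cluster": c,
                "size": len(members),
                "degree_min": int(min(degs)),
                "degree_max": int(max(degs)),
            }
        )
    summary_df = pd.DataFrame(rows)

    flow = pd.DataFrame(0.0, index=ks, columns=ks)
    n_edges = net.n_edges
    for u, v in net.edges:
        cu, cv = labels[u], labels[v]
        lo, hi = min(cu, cv), max(cu, cv)
        flow.loc[lo, hi] += 1
    if n_edges:
        flow = flow / n_edges * 100.0
    # each unordered cluster pair is counted once (upper triangle +
    # diagonal), so the whole matrix sums to 100 on a non-empty graph
    return ClusterResult(
        merges=merges if merges is not None else np.empty((0, 4)),
        labels=labels,
        summary=summary_df,
        flows=flow,
    )
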