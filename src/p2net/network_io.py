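"""Network and node-attribute I/O.

Edge lists are two-column TSV files of string node identifiers (lines
starting with ``#`` are comments).  Node attribute tables are TSV with a
header whose first column is ``id``; remaining columns are numeric
covariates, either binary {0, 1} or continuous (e.g. a predicted
probability of intrinsic disorder, to be binarized at a threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "CovariateTable",
    "read_edge_list",
    "write_edge_list",
    "read_node_table",
    "binarize_disorder",
    "degree_sequence",
]


class EdgeListFormatError(ValueError):
    """Raised for malformed edge-list input (self-loops, short lines)."""


@dataclass(frozen=True)
class Network:
    """A simple graph over string node IDs.

    ``nodes`` preserves first-appearance order and is the canonical node
    indexing used everywhere downstream (adjacency matrices, sociality
    vectors).  Undirected edges are stored canonically with
    lexicographically ordered endpoints; no self-loops, no duplicates.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    directed: bool = False

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node IDs")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint {u!r}/{v!r} not in node list")
            if not self.directed and u > v:
                raise ValueError(f"undirected edge ({u!r}, {v!r}) not canonical")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_pairs(self) -> int:
        """Number of possible undirected edges, n(n-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def density(self) -> float:
        return self.n_edges / self.n_pairs if self.n_pairs else 0.0

    def node_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in node-list order (symmetric if undirected)."""
        idx = self.node_index()
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=np.float64)
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            adj[i, j] = 1.0
            if not self.directed:
                adj[j, i] = 1.0
        return adj

    def has_edge(self, u: str, v: str) -> bool:
        if self.directed:
            return (u, v) in self.edges
        return (min(u, v), max(u, v)) in self.edges


def _canonical(u: str, v: str, directed: bool) -> tuple[str, str]:
    if directed or u <= v:
        return (u, v)
    return (v, u)


def network_from_edges(
    edges: Iterable[tuple[str, str]],
    nodes: Iterable[str] | None = None,
    directed: bool = False,
) -> Network:
    """Build a :class:`Network` from edge pairs, canonicalizing and deduplicating.

    ``nodes``, when given, fixes the node order and may include isolated
    nodes; otherwise nodes appear in order of first mention in ``edges``.
    """
    seen: dict[tuple[str, str], None] = {}
    order: list[str] = list(nodes) if nodes is not None else []
    known = set(order)
    for u, v in edges:
        if u == v:
            raise EdgeListFormatError(f"self-loop on node {u!r}")
        for w in (u, v):
            if w not in known:
                if nodes is not None:
                    raise ValueError(f"edge endpoint {w!r} not in the node list")
                known.add(w)
                order.append(w)
        seen.setdefault(_canonical(u, v, directed), None)
    return Network(nodes=tuple(order), edges=frozenset(seen), directed=directed)


def read_edge_list(
    path: str | Path,
    directed: bool = False,
    strict: bool = False,
    nodes_path: str | Path | None = None,
) -> Network:
    """Read a two-column TSV edge list into a :class:`Network`.

    Duplicate edges (including reversed duplicates of an undirected pair)
    are deduplicated with a warning, or rejected when ``strict`` is true.
    A self-loop line is always an error.  ``nodes_path`` optionally names a
    one-ID-per-line file fixing the node universe (allowing isolated nodes).
    """
    path = Path(path)
    raw: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise EdgeListFormatError(f"{path}:{lineno}: empty node ID")
            if u == v:
                raise EdgeListFormatError(f"{path}:{lineno}: self-loop on node {u!r}")
            raw.append((u, v))

    canon = [_canonical(u, v, directed) for u, v in raw]
    n_dup = len(canon) - len(set(canon))
    if n_dup:
        msg = f"{path}: {n_dup} duplicate edge line(s) deduplicated"
        if strict:
            raise EdgeListFormatError(msg)
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)

    node_order = None
    if nodes_path is not None:
        with Path(nodes_path).open() as fh:
            node_order = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return network_from_edges(raw, nodes=node_order, directed=directed)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the canonical edge set as two-column TSV (sorted for stability)."""
    with Path(path).open("w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


@dataclass
class CovariateTable:
    """Node-level covariates keyed by node ID.

    ``data`` has the node ID as index; ``kinds`` maps each column to
    ``"binary"`` or ``"continuous"``.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate node ID(s) in covariate table: {dups}")
        for col, kind in self.kinds.items():
            if kind == "binary":
                vals = set(pd.unique(self.data[col].dropna()))
                if not vals <= {0, 1, 0.0, 1.0}:
                    raise ValueError(f"binary column {col!r} contains values outside {{0,1}}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def align(self, net: Network, columns: list[str] | None = None) -> np.ndarray:
        """Covariate matrix (n_nodes x m) in network node order.

        Raises if any network node is missing from the table.
        """
        cols = columns if columns is not None else self.columns
        missing = [v for v in net.nodes if v not in self.data.index]
        if missing:
            raise ValueError(f"node(s) absent from covariate table: {missing[:10]}")
        mat = self.data.loc[list(net.nodes), cols].to_numpy(dtype=np.float64)
        return mat


def empty_covariates(net: Network) -> CovariateTable:
    """A covariate table with zero columns aligned to ``net`` (m = 0)."""
    return CovariateTable(data=pd.DataFrame(index=pd.Index(list(net.nodes), name="id")))


def read_node_table(path: str | Path) -> CovariateTable:
    """Read a TSV node attribute table (header, first column = node ID).

    Every non-ID column must parse as numeric with no missing values;
    columns whose values are all in {0, 1} are classified binary, others
    continuous.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 1:
        raise ValueError(f"{path}: empty table")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index.name = "id"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate node ID(s): {dups}")
    kinds: dict[str, str] = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric value(s) in column {col!r} for IDs {bad[:10]}")
        missing = df.index[df[col].isna()].tolist()
        if missing:
            raise ValueError(f"{path}: missing value(s) in column {col!r} for IDs {missing[:10]}")
        df[col] = numeric
        kinds[col] = "binary" if set(pd.unique(numeric)) <= {0.0, 1.0} else "continuous"
    return CovariateTable(data=df, kinds=kinds)


def binarize_disorder(
    table: CovariateTable, column: str, threshold: float = 0.7, new_column: str | None = None
) -> CovariateTable:
    """Binarize a continuous probability column at ``threshold`` (inclusive).

    Values >= threshold map to 1, the rest to 0; the boundary is inclusive.
    The original column is retained and a new binary column
    ``<column>_bin`` (or ``new_column``) is appended.
    """
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    vals = table.data[column]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError(f"column {column!r} has values outside [0, 1]")
    name = new_column or f"{column}_bin"
    df = table.data.copy()
    df[name] = (vals >= threshold).astype(np.float64)
    kinds = dict(table.kinds)
    kinds[name] = "binary"
    return CovariateTable(data=df, kinds=kinds)


def degree_sequence(net: Network) -> dict[str, int]:
    """Degree of each node (total degree when directed), in node-list order."""
    deg: dict[str, int] = {v: 0 for v in net.nodes}
    for u, v in net.edges:
        deg[u] += 1
        deg[v] += 1
    return deg
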