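"""Bipartite topology metrics: per-class degree distribution, clustering,
redundancy, and Table-style whole-network summaries.

In a bipartite graph, the classic triangle-based clustering coefficient is
identically zero, so local density is measured instead by neighborhood
overlap with *second* neighbors (nodes of the same class reachable through
one opposite-class node):

    cc(u) = mean over v in N(N(u)) of |N(u) & N(v)| / |N(u) | N(v)|

with N(N(u)) excluding u itself; cc is undefined (NaN) when u has no second
neighbors.

The redundancy coefficient asks how dispensable a node is for the
connectivity of the opposite layer:

    rc(u) = #{pairs {w1, w2} of neighbors of u co-covered by some other
             node u' != u} / (k_u * (k_u - 1) / 2)

rc(u) = 1 means deleting u changes nothing in the one-mode projection of
the opposite class; rc is undefined below degree 2. Undefined values
propagate as NaN and are excluded from class means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError
from .mi_network import gene_nodes, mir_nodes

log = logging.getLogger("cdrenet")


def _require_node(G: nx.Graph, u) -> None:
    if u not in G:
        raise DomainError(f"node {u!r} not in network")


def bipartite_clustering(G: nx.Graph, u) -> float:
    """Pairwise-overlap clustering coefficient of node u; NaN if undefined."""
    _require_node(G, u)
    nu = set(G[u])
    second = set()
    for v in nu:
        second.update(G[v])
    second.discard(u)
    if not second:
        return float("nan")
    # fsum: the result is independent of set iteration order
    total = math.fsum(
        len(nu & set(G[v])) / len(nu | set(G[v])) for v in second
    )
    return total / len(second)


def redundancy(G: nx.Graph, u) -> float:
    """Fraction of neighbor pairs of u co-covered by another node; NaN if k < 2."""
    _require_node(G, u)
    nbrs = list(G[u])
    k = len(nbrs)
    if k < 2:
        return float("nan")
    # other regulators of each neighbor; pairs with an empty set cannot be covered
    others = [frozenset(G[w]) - {u} for w in nbrs]
    candidates = [s for s in others if s]
    covered = 0
    for i in range(len(candidates)):
        si = candidates[i]
        for j in range(i + 1, len(candidates)):
            if si & candidates[j]:
                covered += 1
    return covered / (k * (k - 1) / 2)


def degree_distribution(G: nx.Graph, node_class: str) -> pd.Series:
    """P(k) = n_k / n over the nodes of one class; sums to 1."""
    nodes = [n for n, d in G.nodes(data=True) if d.get("feature_class") == node_class]
    if not nodes:
        raise DomainError(f"no nodes of class {node_class!r}")
    degrees = pd.Series([G.degree(n) for n in nodes])
    dist = degrees.value_counts(normalize=True).sort_index()
    dist.index.name = "k"
    dist.name = "p"
    return dist


def node_metrics(G: nx.Graph) -> pd.DataFrame:
    """Per-node table: node_id, node_class, degree, clustering, redundancy."""
    rows = []
    for n, d in sorted(G.nodes(data=True)):
        rows.append(
            {
                "node_id": n,
                "node_class": d.get("feature_class"),
                "degree": G.degree(n),
                "clustering": bipartite_clustering(G, n),
                "redundancy": redundancy(G, n),
            }
        )
    return pd.DataFrame(
        rows, columns=["node_id", "node_class", "degree", "clustering", "redundancy"]
    )


@dataclass
class NetworkSummary:
    """Whole-network counts and per-class means (NaN where undefined)."""

    n_mir_nodes: int
    n_gene_nodes: int
    n_edges: int
    n_components: int
    mean_degree_mir: float
    mean_degree_gene: float
    mean_clustering_mir: float
    mean_clustering_gene: float
    mean_redundancy_mir: float
    mean_redundancy_gene: float

    @classmethod
    def from_counts(cls, n_mir_nodes: int, n_gene_nodes: int, n_edges: int
                    ) -> "NetworkSummary":
        """Summary determined by counts alone (mean degree = edges / nodes).

        Lets printed node/edge counts be checked for arithmetic consistency
        with printed average degrees without the underlying network.
        """
        nan = float("nan")
        return cls(
            n_mir_nodes=n_mir_nodes,
            n_gene_nodes=n_gene_nodes,
            n_edges=n_edges,
            n_components=0,
            mean_degree_mir=n_edges / n_mir_nodes if n_mir_nodes else nan,
            mean_degree_gene=n_edges / n_gene_nodes if n_gene_nodes else nan,
            mean_clustering_mir=nan,
            mean_clustering_gene=nan,
            mean_redundancy_mir=nan,
            mean_redundancy_gene=nan,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def summarize(G: nx.Graph, metrics: pd.DataFrame | None = None) -> NetworkSummary:
    """Counts, per-class mean degree/clustering/redundancy, component count.

    Means of clustering and redundancy are over nodes where the metric is
    defined. Components are counted on the bipartite graph as a whole.
    """
    if metrics is None:
        metrics = node_metrics(G)
    mirs = mir_nodes(G)
    genes = gene_nodes(G)
    by_class = {c: metrics[metrics["node_class"] == c] for c in ("mir", "gene")}
    nan = float("nan")

    def mean_of(cls: str, col: str) -> float:
        sub = by_class[cls][col].astype(float)
        sub = sub[np.isfinite(sub)]
        return float(sub.mean()) if len(sub) else nan

    return NetworkSummary(
        n_mir_nodes=len(mirs),
        n_gene_nodes=len(genes),
        n_edges=G.number_of_edges(),
        n_components=nx.number_connected_components(G),
        mean_degree_mir=mean_of("mir", "degree"),
        mean_degree_gene=mean_of("gene", "degree"),
        mean_clustering_mir=mean_of("mir", "clustering"),
        mean_clustering_gene=mean_of("gene", "clustering"),
        mean_redundancy_mir=mean_of("mir", "redundancy"),
        mean_redundancy_gene=mean_of("gene", "redundancy"),
    )


def cumulative_distribution(values) -> pd.Series:
    """Empirical cumulative frequency: sorted unique values -> F(x) in (0, 1]."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cumulative_distribution requires nonempty input")
    if not np.isfinite(arr).all():
        raise DomainError("cumulative_distribution requires finite values")
    xs, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    out = pd.Series(cum, index=xs, name="cumulative_frequency")
    out.index.name = "value"
    return out
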