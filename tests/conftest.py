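import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cdrenet import ExpressionMatrix, build_bipartite_network


@pytest.fixture
def toy_graph() -> nx.Graph:
    """The canonical 3-top/5-bottom illustration of redundancy semantics:

    A and B both regulate genes 1, 2, 3; C regulates 3, 4, 5. B is fully
    redundant (A covers all its neighbor pairs); C is fully nonredundant
    (genes 4 and 5 have no other regulator).
    """
    edges = (
        [("A", g, 1.0) for g in ("1", "2", "3")]
        + [("B", g, 1.0) for g in ("1", "2", "3")]
        + [("C", g, 1.0) for g in ("3", "4", "5")]
    )
    return build_bipartite_network(edges)


def make_matrix(values, feature_class="gene", condition="A", prefix=None):
    """Small ExpressionMatrix from a 2-D array with generated IDs."""
    values = np.asarray(values, dtype=float)
    prefix = prefix or feature_class
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(df, feature_class, condition)


def random_bipartite(rng, n_top=8, n_bottom=8, p=0.3) -> nx.Graph:
    """Random bipartite graph with miR/gene classed nodes (may be sparse)."""
    edges = []
    for i in range(n_top):
        for j in range(n_bottom):
            if rng.random() < p:
                edges.append((f"m{i}", f"g{j}", 1.0))
    return build_bipartite_network(edges)


# ---- independent brute-force oracles for the bipartite metrics ----

def brute_clustering(G: nx.Graph, u) -> float:
    """Literal enumeration of the pairwise-overlap clustering definition."""
    nu = {v for v in G if G.has_edge(u, v)}
    second = {
        w
        for w in G
        if w != u and any(G.has_edge(w, v) for v in nu)
    }
    if not second:
        return float("nan")
    import math

    total = math.fsum(
        len(nu & {v for v in G if G.has_edge(w, v)})
        / len(nu | {v for v in G if G.has_edge(w, v)})
        for w in second
    )
    return total / len(second)


def brute_redundancy(G: nx.Graph, u) -> float:
    """Literal enumeration of the redundancy definition over neighbor pairs."""
    from itertools import combinations

    nu = [v for v in G if G.has_edge(u, v)]
    k = len(nu)
    if k < 2:
        return float("nan")
    covered = 0
    for w1, w2 in combinations(nu, 2):
        if any(
            up != u and G.has_edge(up, w1) and G.has_edge(up, w2) for up in G
        ):
            covered += 1
    return covered / (k * (k - 1) / 2)
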