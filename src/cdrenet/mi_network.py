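"""Mutual-information network inference for miR-gene pairs.

Every miR profile is scored against every gene profile with a plug-in
mutual-information estimate on equal-frequency-binned data, the all-pairs MI
distribution is thresholded at a high quantile (default 0.99741, i.e. the
top 0.259% of pairs), and the surviving pairs become the edges of an
undirected bipartite graph. Edges are semantically directed miR -> gene
(miRs regulate genes, not vice versa), but all topology metrics computed
downstream are undirected, so the graph is stored undirected and the
direction is carried as an edge attribute in GML exports.

Estimator choices (configurable): equal-frequency binning with
``ceil(sqrt(n_samples))`` bins capped at 20; plug-in (maximum-likelihood)
joint-histogram estimate in bits; no bias correction. The plug-in bias is
shared by every pair at fixed n and bin count, so the quantile filter —
which only ranks pairs — is insensitive to it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    ConfigurationError,
    DomainError,
    ParseError,
    PreconditionError,
    StructuralError,
)
from .preprocessing import ExpressionMatrix

log = logging.getLogger("cdrenet")

DEFAULT_QUANTILE = 0.99741
MAX_BINS = 20

# chunk of miR rows per joint-histogram matmul; bounds peak memory
_CHUNK = 16


def auto_bins(n_samples: int) -> int:
    """Default bin count: ceil(sqrt(n)) capped at 20."""
    return min(MAX_BINS, math.ceil(math.sqrt(n_samples)))


def discretize(profile: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning into integer labels in [0, n_bins).

    Ties all receive the bin of their lowest rank (rank method "min"), so the
    labelling is deterministic and a constant profile maps entirely to bin 0.
    """
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    ranks = rankdata(profile, method="min").astype(np.int64) - 1
    return (ranks * n_bins) // n


def _entropy_bits(counts: np.ndarray) -> float:
    """Entropy of a count vector in bits, with order-independent summation."""
    c = np.sort(counts[counts > 0]).astype(float)
    n = c.sum()
    p = c / n
    return float(-(p * np.log2(p)).sum())


def binned_entropy(x: np.ndarray) -> float:
    """Entropy (bits) of a vector of integer bin labels."""
    x = np.asarray(x, dtype=np.int64)
    return _entropy_bits(np.bincount(x))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (bits) between two equal-length vectors of bin labels.

    Computed as H(x) + H(y) - H(x, y) on the empirical histograms, which is
    algebraically the usual sum of p*log2(p/(p_x p_y)) over the joint table.
    Entropy terms sum sorted probabilities, so the result is exactly
    symmetric in its arguments, and MI(x, x) equals the binned entropy of x
    exactly.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DomainError("need at least 2 paired observations")
    by = int(y.max()) + 1
    joint = np.bincount(x * by + y)
    mi = _entropy_bits(np.bincount(x)) + _entropy_bits(np.bincount(y)) - _entropy_bits(joint)
    return max(mi, 0.0)


@dataclass
class MIResult:
    """All-pairs miR-gene mutual information, prior to edge filtering."""

    mir_ids: list[str]
    gene_ids: list[str]
    mir_index: np.ndarray  # per-pair index into mir_ids
    gene_index: np.ndarray
    mi: np.ndarray  # bits, nonnegative
    n_bins: int
    n_samples: int
    estimator: str = "plugin-equal-frequency"

    def __len__(self) -> int:
        return self.mi.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mir_id": np.asarray(self.mir_ids, dtype=object)[self.mir_index],
                "gene_id": np.asarray(self.gene_ids, dtype=object)[self.gene_index],
                "mi": self.mi,
            }
        )


def all_pairs_mi(
    mir: ExpressionMatrix, gene: ExpressionMatrix, n_bins: int | None = None
) -> MIResult:
    """Plug-in MI for every (miR, gene) pair of two sample-aligned matrices.

    The joint histograms for all pairs are accumulated through one-hot
    matrix products, chunked over miRs to bound memory; per-pair values agree
    with :func:`mutual_information` to floating tolerance. Zero-variance
    features land entirely in one bin and therefore score MI = 0 against
    everything; they are counted in the log, never an error.
    """
    if mir.sample_ids != gene.sample_ids:
        raise PreconditionError(
            "matrices are not sample-aligned; call align_samples first"
        )
    n = len(mir.sample_ids)
    if n_bins is None:
        n_bins = auto_bins(n)
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")

    xm = mir.values.to_numpy()
    xg = gene.values.to_numpy()
    n_flat_m = int((xm.std(axis=1) == 0).sum())
    n_flat_g = int((xg.std(axis=1) == 0).sum())
    if n_flat_m or n_flat_g:
        log.warning(
            "zero-variance features: %d miR, %d gene (their MI is 0 by definition)",
            n_flat_m, n_flat_g,
        )

    mb = np.stack([discretize(row, n_bins) for row in xm])  # (n_mirs, n)
    gb = np.stack([discretize(row, n_bins) for row in xg])  # (n_genes, n)
    n_mirs, n_genes = mb.shape[0], gb.shape[0]

    h_mir = np.array([binned_entropy(row) for row in mb])
    h_gene = np.array([binned_entropy(row) for row in gb])

    # one-hot encodings; float32 keeps counts exact for n < 2**24
    eye = np.eye(n_bins, dtype=np.float32)
    gh = eye[gb].transpose(0, 2, 1).reshape(n_genes * n_bins, n)  # (G*B, n)

    mi = np.empty((n_mirs, n_genes))
    with np.errstate(divide="ignore", invalid="ignore"):
        for start in range(0, n_mirs, _CHUNK):
            stop = min(start + _CHUNK, n_mirs)
            mh = eye[mb[start:stop]].transpose(0, 2, 1).reshape(-1, n)  # (c*B, n)
            counts = (mh @ gh.T).astype(np.float64)
            counts = counts.reshape(stop - start, n_bins, n_genes, n_bins)
            p = counts / n
            logp = np.zeros_like(p)
            np.log2(p, out=logp, where=counts > 0)
            h_joint = -(p * logp).sum(axis=(1, 3))  # (chunk, n_genes)
            mi[start:stop] = h_mir[start:stop, None] + h_gene[None, :] - h_joint
    np.maximum(mi, 0.0, out=mi)

    mir_index, gene_index = np.divmod(np.arange(n_mirs * n_genes), n_genes)
    result = MIResult(
        mir_ids=list(mir.feature_ids),
        gene_ids=list(gene.feature_ids),
        mir_index=mir_index,
        gene_index=gene_index,
        mi=mi.ravel(),
        n_bins=n_bins,
        n_samples=n,
    )
    log.info(
        "scored %d miR x %d gene pairs (%d bins, %d samples)",
        n_mirs, n_genes, n_bins, n,
    )
    return result


def percentile_filter(
    result: MIResult, quantile: float = DEFAULT_QUANTILE
) -> list[tuple[str, str, float]]:
    """Keep the top (1 - quantile) fraction of pairs by MI; ties retained.

    The cutoff is the m-th largest MI value with m = floor((1 - quantile) * N);
    every pair with MI >= cutoff is kept, so with distinct values exactly m
    edges survive and ties at the cutoff are all retained (deterministic).
    Returned edges are sorted by descending MI, then IDs.
    """
    if not (0.0 < quantile < 1.0):
        raise ConfigurationError(f"quantile must lie in (0, 1), got {quantile}")
    n = len(result)
    if n == 0:
        raise DomainError("MI result is empty")
    # epsilon guards float rounding so real-arithmetic floor((1-q)n) is kept
    m = int(math.floor((1.0 - quantile) * n + 1e-9))
    if m == 0:
        log.info("percentile filter at %.5f retained 0 of %d pairs", quantile, n)
        return []
    cutoff = np.partition(result.mi, n - m)[n - m]
    keep = np.flatnonzero(result.mi >= cutoff)
    mir_arr = np.asarray(result.mir_ids, dtype=object)
    gene_arr = np.asarray(result.gene_ids, dtype=object)
    edges = [
        (str(mir_arr[result.mir_index[i]]), str(gene_arr[result.gene_index[i]]),
         float(result.mi[i]))
        for i in keep
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    log.info(
        "percentile filter at %.5f retained %d of %d pairs (cutoff %.4f bits)",
        quantile, len(edges), n, cutoff,
    )
    return edges


def build_bipartite_network(
    edges: list[tuple[str, str, float]], lfc: pd.Series | None = None
) -> nx.Graph:
    """Assemble the undirected bipartite graph from retained (miR, gene) edges.

    Node sets are exactly the endpoints of the retained edges; isolated
    features never enter the graph. Node attributes: ``feature_class``
    ("mir"/"gene"), ``bipartite`` (0/1), and ``lfc`` where available.
    """
    G = nx.Graph(edge_direction="mir->gene")
    seen_as = {}
    for m, g, w in edges:
        for node, cls in ((m, "mir"), (g, "gene")):
            prev = seen_as.setdefault(node, cls)
            if prev != cls:
                raise StructuralError(
                    f"node {node!r} appears as both {prev} and {cls}"
                )
        G.add_node(m, feature_class="mir", bipartite=0)
        G.add_node(g, feature_class="gene", bipartite=1)
        G.add_edge(m, g, weight=float(w))
    if lfc is not None:
        for node in G.nodes:
            if node in lfc.index and np.isfinite(lfc.loc[node]):
                G.nodes[node]["lfc"] = float(lfc.loc[node])
    return G


def mir_nodes(G: nx.Graph) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True) if d.get("feature_class") == "mir")


def gene_nodes(G: nx.Graph) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True) if d.get("feature_class") == "gene")


def _check_bipartite(G: nx.Graph) -> None:
    for u, v in G.edges:
        cu = G.nodes[u].get("feature_class")
        cv = G.nodes[v].get("feature_class")
        if cu not in ("mir", "gene") or cv not in ("mir", "gene"):
            raise StructuralError(f"edge ({u}, {v}): missing/unknown feature_class")
        if cu == cv:
            raise StructuralError(f"edge ({u}, {v}) joins two {cu} nodes")


def write_gml(G: nx.Graph, path: str | Path) -> None:
    """Export to GML: node class and LFC attributes, MI as edge ``value``.

    Weights are rounded to 6 decimals; each edge carries ``directed 1`` to
    record the miR -> gene regulatory direction the undirected graph elides.
    """
    _check_bipartite(G)
    out = nx.Graph(**G.graph)
    for node, data in G.nodes(data=True):
        attrs = {"feature_class": data["feature_class"]}
        if "lfc" in data and np.isfinite(data["lfc"]):
            attrs["lfc"] = round(float(data["lfc"]), 6)
        out.add_node(node, **attrs)
    for u, v, data in G.edges(data=True):
        out.add_edge(u, v, value=round(float(data.get("weight", 1.0)), 6), directed=1)
    nx.write_gml(out, path)


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML network written by :func:`write_gml`, enforcing bipartiteness."""
    try:
        raw = nx.read_gml(path)
    except Exception as exc:
        raise ParseError(f"cannot parse GML {path}: {exc}") from exc
    G = nx.Graph(**{k: v for k, v in raw.graph.items()})
    for node, data in raw.nodes(data=True):
        cls = data.get("feature_class")
        attrs = {"feature_class": cls, "bipartite": 0 if cls == "mir" else 1}
        if "lfc" in data:
            attrs["lfc"] = float(data["lfc"])
        G.add_node(str(node), **attrs)
    for u, v, data in raw.edges(data=True):
        G.add_edge(str(u), str(v), weight=float(data.get("value", data.get("weight", 1.0))))
    _check_bipartite(G)
    return G
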