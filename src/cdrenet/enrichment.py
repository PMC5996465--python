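"""Over-representation analysis (ORA) of gene sets against an annotation
catalog, with Benjamini-Hochberg adjustment.

For a query of n genes drawn from a universe of N, overlapping a category of
K genes in k, the enrichment p-value is the hypergeometric upper tail
P(X >= k). Categories are size-filtered to [5, 2000] genes (after universe
restriction) before testing, p-values are BH-adjusted across all tested
categories, and results are returned sorted by adjusted then raw p-value.
The catalog's gene universe defaults to all genes annotated in the catalog;
callers may first restrict it to the measured genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParseError

log = logging.getLogger("cdrenet")


@dataclass
class AnnotationCatalog:
    """Annotation categories (GMT-style): id -> (description, gene set)."""

    categories: dict[str, tuple[str, frozenset]]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set = set()
            for _, genes in self.categories.values():
                u |= genes
            self.universe = frozenset(u)
        for cid, (_, genes) in self.categories.items():
            if not genes <= self.universe:
                raise DomainError(f"category {cid!r} has genes outside the universe")

    def __len__(self) -> int:
        return len(self.categories)

    def restrict_universe(self, measured) -> "AnnotationCatalog":
        """Intersect the universe (and every category) with a measured gene set."""
        measured = frozenset(measured)
        new_universe = self.universe & measured
        cats = {
            cid: (desc, genes & new_universe)
            for cid, (desc, genes) in self.categories.items()
        }
        return AnnotationCatalog(cats, new_universe)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid in sorted(self.categories):
                desc, genes = self.categories[cid]
                fh.write("\t".join([cid, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> AnnotationCatalog:
    """Read a GMT file: one category per line, id <tab> description <tab> genes."""
    cats: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            cid, desc, genes = parts[0], parts[1], parts[2:]
            if cid in cats:
                raise ParseError(f"{path}:{lineno}: duplicate category ID {cid!r}")
            cats[cid] = (desc, frozenset(genes))
    return AnnotationCatalog(cats)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for overlap k, category K, query n, universe N."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise DomainError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query,
    catalog: AnnotationCatalog,
    min_size: int = 5,
    max_size: int = 2000,
    top: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set against a catalog.

    Only categories whose universe-restricted size lies in
    [min_size, max_size] are tested; BH adjustment runs across all tested
    categories. The result is sorted by (adjusted p, raw p, category ID) and
    truncated to ``top`` rows when given (pass None for the full table).
    Invariant to the input order of the query.
    """
    query = set(query)
    in_universe = query & catalog.universe
    dropped = len(query) - len(in_universe)
    if dropped:
        log.info("ora: %d query gene(s) outside the universe, dropped", dropped)
    if not in_universe:
        raise DomainError("query is empty after universe intersection")
    n = len(in_universe)
    N = len(catalog.universe)
    rows = []
    for cid in sorted(catalog.categories):
        desc, genes = catalog.categories[cid]
        K = len(genes)
        if not (min_size <= K <= max_size):
            continue
        overlap = sorted(in_universe & genes)
        k = len(overlap)
        rows.append(
            {
                "category_id": cid,
                "description": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_p(k, K, n, N),
                "genes": ";".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows, columns=["category_id", "description", "k", "K", "n", "N",
                       "p_value", "genes"]
    )
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
    df = df[["category_id", "description", "k", "K", "n", "N", "p_value",
             "adjusted_p", "genes"]]
    df = df.sort_values(
        ["adjusted_p", "p_value", "category_id"], kind="stable"
    ).reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df
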