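"""Commodore-miR classification on the degree-redundancy plane.

A *Commodore* miR (Cdre-miR) is a miR node that is simultaneously highly
connected (degree above a threshold, default 100) and nonredundant
(redundancy coefficient below a threshold, default 0.5): removing it would
disconnect a gene neighborhood for which no other miR compensates. The
degree-redundancy plane is partitioned into four quadrants by the two
thresholds; miRs whose redundancy is undefined (degree < 2) are excluded
from the plane and can never be Commodores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError

log = logging.getLogger("cdrenet")

Q_COMMODORE = "commodore"
Q_HIGH_HIGH = "high-degree/high-redundancy"
Q_LOW_LOW = "low-degree/low-redundancy"
Q_LOW_HIGH = "low-degree/high-redundancy"
Q_EXCLUDED = "excluded"


@dataclass
class CdreReport:
    """Quadrant assignment for every miR plus the Commodore list."""

    degree_min: int
    redundancy_max: float
    strict: bool
    table: pd.DataFrame  # node_id, degree, redundancy, quadrant
    commodores: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def classify_mirs(
    metrics: pd.DataFrame,
    degree_min: int = 100,
    redundancy_max: float = 0.5,
    strict: bool = True,
) -> CdreReport:
    """Label each miR with its degree-redundancy quadrant.

    With ``strict`` (default) a Commodore requires degree > degree_min and
    redundancy < redundancy_max; the non-strict variant uses >= / <=. miRs
    with undefined redundancy are labeled "excluded". Raising redundancy_max
    or lowering degree_min can only add Commodores, never remove one.
    """
    mirs = metrics[metrics["node_class"] == "mir"]
    rows = []
    for _, r in mirs.iterrows():
        k = int(r["degree"])
        rc = float(r["redundancy"])
        if not np.isfinite(rc):
            quadrant = Q_EXCLUDED
        else:
            high_deg = k > degree_min if strict else k >= degree_min
            low_red = rc < redundancy_max if strict else rc <= redundancy_max
            quadrant = (
                Q_COMMODORE if (high_deg and low_red)
                else Q_HIGH_HIGH if high_deg
                else Q_LOW_LOW if low_red
                else Q_LOW_HIGH
            )
        rows.append(
            {"node_id": r["node_id"], "degree": k, "redundancy": rc,
             "quadrant": quadrant}
        )
    table = pd.DataFrame(rows, columns=["node_id", "degree", "redundancy", "quadrant"])
    commodores = sorted(table.loc[table["quadrant"] == Q_COMMODORE, "node_id"])
    log.info(
        "classified %d miRs (degree > %d, redundancy < %.2f): %d commodore(s)%s",
        len(table), degree_min, redundancy_max, len(commodores),
        f" {commodores}" if commodores else "",
    )
    return CdreReport(
        degree_min=degree_min,
        redundancy_max=redundancy_max,
        strict=strict,
        table=table,
        commodores=commodores,
    )


def extract_neighborhoods(G: nx.Graph, commodores) -> dict[str, set[str]]:
    """First gene neighbors of each Commodore; sizes equal their degrees."""
    out: dict[str, set[str]] = {}
    for m in commodores:
        if m not in G or G.nodes[m].get("feature_class") != "mir":
            raise DomainError(f"{m!r} is not a miR node of the network")
        out[m] = set(G[m])
    return out


def neighborhood_intersections(neighborhoods: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise shared-gene table over all unordered Commodore pairs.

    Columns: the pair, shared-gene count, the count as a percentage of each
    neighborhood's size, and the sorted shared gene IDs (semicolon-joined).
    Fewer than two neighborhoods yield an empty table.
    """
    rows = []
    for a, b in combinations(sorted(neighborhoods), 2):
        shared = neighborhoods[a] & neighborhoods[b]
        rows.append(
            {
                "mir_a": a,
                "mir_b": b,
                "n_shared": len(shared),
                "pct_of_a": 100.0 * len(shared) / len(neighborhoods[a])
                if neighborhoods[a] else 0.0,
                "pct_of_b": 100.0 * len(shared) / len(neighborhoods[b])
                if neighborhoods[b] else 0.0,
                "shared_genes": ";".join(sorted(shared)),
            }
        )
    return pd.DataFrame(
        rows, columns=["mir_a", "mir_b", "n_shared", "pct_of_a", "pct_of_b",
                       "shared_genes"]
    )
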